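"""Right-censored maximum-likelihood fitting of the five parametric
time-to-event families, with optional covariates and AIC-based selection.

The log-likelihood is the standard right-censored one,
``sum_events log f(t) + sum_censored log S(t)``, maximised over an
unconstrained reparameterisation (log of positivity-constrained parameters,
identity for the lognormal location). Covariates enter through a log-linear
link on the scale-like parameter, the same convention the sampling side
uses. The coefficient covariance comes from the inverse observed
information (finite-difference Hessian at the optimum) on the unconstrained
scale, ready for multivariate-normal PSA draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dists import (FAMILIES, N_PARAMS, TTEModel, aic, from_unconstrained,
                    to_unconstrained)


class FitError(RuntimeError):
    """Raised when a family cannot be fitted to the sample."""


@dataclass
class SurvivalSample:
    """Right-censored durations with optional per-subject covariates."""

    durations: np.ndarray
    events: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.durations.shape != self.events.shape:
            raise ValueError("durations and event flags differ in length")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be strictly positive")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
            if len(self.covariates) != len(self.durations):
                raise ValueError("covariate rows do not match durations")

    @property
    def n(self) -> int:
        return len(self.durations)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalSample":
        cov_cols = [c for c in frame.columns if c not in ("duration_days", "event")]
        return cls(frame["duration_days"].to_numpy(),
                   frame["event"].to_numpy().astype(bool),
                   frame[cov_cols] if cov_cols else None)

    @classmethod
    def from_csv(cls, path) -> "SurvivalSample":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class FittedTTE:
    """A fitted family with its likelihood, AIC and coefficient covariance."""

    model: TTEModel
    loglik: float
    aic: float
    n: int
    n_events: int
    covariate_names: list = field(default_factory=list)
    vcov_full: np.ndarray | None = None  # base params + covariate betas

    @property
    def k(self) -> int:
        return N_PARAMS[self.model.family] + len(self.covariate_names)

    def report(self) -> dict:
        return {
            "family": self.model.family,
            "params": [float(p) for p in self.model.params],
            "covariate_links": dict(self.model.covariate_links),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
            "vcov": (np.asarray(self.vcov_full).tolist()
                     if self.vcov_full is not None else None),
        }


def _log_sf_pdf(family: str, base: np.ndarray, lp: np.ndarray, t: np.ndarray):
    """Vectorised (log S(t), log f(t)) under the covariate link."""
    if family == "exponential":
        rate = base[0] * np.exp(-lp)
        logsf = -rate * t
        logpdf = np.log(rate) + logsf
    elif family == "weibull":
        shape, scale = base
        scale = scale * np.exp(lp)
        z = t / scale
        logsf = -(z ** shape)
        logpdf = np.log(shape / scale) + (shape - 1.0) * np.log(z) + logsf
    elif family == "lognormal":
        mu, sigma = base
        z = (np.log(t) - (mu + lp)) / sigma
        logsf = stats.norm.logsf(z)
        logpdf = stats.norm.logpdf(z) - np.log(t * sigma)
    elif family == "loglogistic":
        shape, scale = base
        scale = scale * np.exp(lp)
        logz = shape * (np.log(t) - np.log(scale))
        logsf = -np.logaddexp(0.0, logz)
        logpdf = (np.log(shape / scale) + (shape - 1.0)
                  * (np.log(t) - np.log(scale)) + 2.0 * logsf)
    elif family == "gompertz":
        shape, rate = base
        rate = rate * np.exp(-lp)
        logh = np.log(rate) + shape * t
        logsf = -(rate / max(shape, 1e-12)) * np.expm1(shape * t) \
            if shape > 1e-12 else -rate * t
        logpdf = logh + logsf
    else:  # pragma: no cover
        raise ValueError(f"unknown family {family!r}")
    return logsf, logpdf


def _neg_loglik(theta, family, t, e, X):
    k0 = N_PARAMS[family]
    try:
        base = np.asarray(from_unconstrained(family, theta[:k0]))
    except (ValueError, FloatingPointError):
        return np.inf
    lp = X @ theta[k0:] if X is not None else np.zeros_like(t)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        logsf, logpdf = _log_sf_pdf(family, base, lp, t)
        ll = np.sum(np.where(e, logpdf, logsf))
    return np.inf if not np.isfinite(ll) else -ll


def _init_theta(family: str, sample: SurvivalSample) -> np.ndarray:
    """Method-of-moments starting values from the uncensored durations."""
    obs = sample.durations[sample.events]
    if obs.size == 0:
        obs = sample.durations
    m = float(np.mean(obs))
    s = float(np.std(obs, ddof=1)) if obs.size > 1 else m
    s = max(s, 1e-3 * m)
    total_time = float(sample.durations.sum())
    rate = max(sample.n_events, 1) / total_time
    logt = np.log(obs)
    mu, sig = float(np.mean(logt)), max(float(np.std(logt)), 1e-3)
    if family == "exponential":
        base = (rate,)
    elif family == "weibull":
        cv = s / m
        shape = max(cv ** -1.086, 0.1)  # Garcia's moment approximation
        base = (shape, m / math.gamma(1.0 + 1.0 / shape))
    elif family == "lognormal":
        base = (mu, sig)
    elif family == "loglogistic":
        base = (max(math.pi / (math.sqrt(3.0) * sig), 0.1), math.exp(mu))
    else:  # gompertz
        base = (1e-4, rate)
    return to_unconstrained(family, base)


def _numeric_hessian(f, x, rel_step=1e-4):
    n = len(x)
    h = np.maximum(np.abs(x), 1.0) * rel_step
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H, f0


def fit_tte(data: SurvivalSample, family: str,
            covariate_spec: list | None = None) -> FittedTTE:
    """Maximum-likelihood fit of one family to a right-censored sample."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    k0 = N_PARAMS[family]
    covariate_spec = list(covariate_spec or [])
    k = k0 + len(covariate_spec)
    if data.n_events == 0:
        raise FitError("all observations are censored; nothing to fit")
    if data.n_events < k:
        raise FitError(
            f"only {data.n_events} events for {k} parameters ({family}); "
            "the fit would sit on the boundary")
    if covariate_spec:
        if data.covariates is None:
            raise FitError("covariate_spec given but the sample has no covariates")
        X = data.covariates[covariate_spec].to_numpy(dtype=float)
    else:
        X = None

    t, e = data.durations, data.events
    theta0 = np.concatenate([_init_theta(family, data), np.zeros(len(covariate_spec))])
    nll = lambda th: _neg_loglik(th, family, t, e, X)

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 4000, "maxfev": 8000})
    res2 = optimize.minimize(nll, res.x, method="BFGS",
                             options={"gtol": 1e-8, "maxiter": 500})
    best = res2 if res2.fun <= res.fun else res
    if not np.isfinite(best.fun):
        raise FitError(f"{family} fit diverged (final objective {best.fun})")
    if not (res.success or res2.success):
        raise FitError(f"{family} fit did not converge: {best.message}")

    theta = best.x
    loglik = -float(best.fun)
    H, _ = _numeric_hessian(nll, theta)
    H = 0.5 * (H + H.T)
    try:
        vcov = np.linalg.pinv(H)
        vcov = 0.5 * (vcov + vcov.T)
        w, V = np.linalg.eigh(vcov)
        vcov = (V * np.clip(w, 0.0, None)) @ V.T  # project onto PSD cone
    except np.linalg.LinAlgError:
        vcov = None

    base = from_unconstrained(family, theta[:k0])
    links = dict(zip(covariate_spec, theta[k0:]))
    model = TTEModel(family=family, params=base, covariate_links=links,
                     vcov=vcov[:k0, :k0] if vcov is not None else None)
    return FittedTTE(model=model, loglik=loglik, aic=aic(loglik, k),
                     n=data.n, n_events=data.n_events,
                     covariate_names=covariate_spec, vcov_full=vcov)


def select_best_family(data: SurvivalSample, families=FAMILIES,
                       covariate_spec: list | None = None) -> FittedTTE:
    """Fit every family and return the minimum-AIC fit.

    Ties (within 1e-9) are broken toward fewer parameters, then by the
    canonical family order.
    """
    families = list(families)
    fits, errors = [], []
    for order, family in enumerate(families):
        try:
            fits.append((order, fit_tte(data, family, covariate_spec)))
        except (FitError, ValueError) as exc:
            errors.append(f"{family}: {exc}")
    if not fits:
        raise FitError("no family could be fitted: " + "; ".join(errors))
    fits.sort(key=lambda of: (round(of[1].aic / 1e-9) * 1e-9, of[1].k, of[0]))
    return fits[0][1]
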