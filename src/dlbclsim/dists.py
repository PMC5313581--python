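"""Probability kernel: parametric time-to-event families, Beta/Dirichlet
sampling, AIC, and life-table background mortality.

Time-to-event parameterisations (internal time unit: days)
----------------------------------------------------------
family       params              S(t)                                inverse CDF t(u), u~U(0,1)
exponential  (rate,)             exp(-rate*t)                        -log(1-u)/rate
weibull      (shape, scale)      exp(-(t/scale)^shape)               scale*(-log(1-u))^(1/shape)
lognormal    (mu, sigma)         1 - Phi((log t - mu)/sigma)         exp(mu + sigma*Phi^-1(u))
loglogistic  (shape, scale)      1/(1 + (t/scale)^shape)             scale*(u/(1-u))^(1/shape)
gompertz     (shape, rate)       exp(-(rate/shape)*(e^(shape*t)-1))  log(1 - shape*log(1-u)/rate)/shape

The Gompertz hazard is h(t) = rate*exp(shape*t); shape = 0 degenerates to the
exponential and negative shape is rejected (S would plateau above zero).
Covariates act through a log-linear accelerated-failure-time style link on the
scale-like parameter (rate is divided by exp(lp), scale multiplied, lognormal
mu shifted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz")

#: number of base (covariate-free) parameters per family
N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
}

DAYS_PER_YEAR = 365.25


@dataclass
class TTEModel:
    """A parametric time-to-event law.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : tuple of float
        Family-specific parameter vector, see the module docstring.
    covariate_links : dict, optional
        Map covariate name -> coefficient entering a linear predictor that
        accelerates/decelerates the scale-like parameter.
    vcov : ndarray, optional
        Covariance matrix of the (transformed, see :mod:`dlbclsim.survfit`)
        coefficient vector, used for probabilistic sensitivity draws.
    """

    family: str
    params: tuple
    covariate_links: dict = field(default_factory=dict)
    vcov: np.ndarray | None = None
    time_unit: str = "days"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown time-to-event family {self.family!r}")
        self.params = tuple(float(p) for p in self.params)
        if len(self.params) != N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} expects {N_PARAMS[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        _validate_params(self.family, self.params)

    def linear_predictor(self, covariates: dict | None) -> float:
        if not self.covariate_links:
            return 0.0
        covariates = covariates or {}
        lp = 0.0
        for name, beta in self.covariate_links.items():
            if name not in covariates:
                raise KeyError(f"covariate {name!r} required by model but not supplied")
            lp += beta * float(covariates[name])
        return lp

    def effective_params(self, covariates: dict | None = None) -> tuple:
        """Parameters after applying the covariate link."""
        lp = self.linear_predictor(covariates)
        if lp == 0.0:
            return self.params
        fam, p = self.family, self.params
        if fam == "exponential":
            return (p[0] * math.exp(-lp),)
        if fam in ("weibull", "loglogistic"):
            return (p[0], p[1] * math.exp(lp))
        if fam == "lognormal":
            return (p[0] + lp, p[1])
        # gompertz: rate divided by exp(lp) (proportional-hazards style)
        return (p[0], p[1] * math.exp(-lp))

    def mean(self, covariates: dict | None = None) -> float:
        """Analytic mean where finite, else numerically integrated S(t)."""
        fam = self.family
        p = self.effective_params(covariates)
        if fam == "exponential":
            return 1.0 / p[0]
        if fam == "weibull":
            return p[1] * math.gamma(1.0 + 1.0 / p[0])
        if fam == "lognormal":
            return math.exp(p[0] + p[1] ** 2 / 2.0)
        if fam == "loglogistic":
            if p[0] <= 1.0:
                return math.inf
            b = math.pi / p[0]
            return p[1] * b / math.sin(b)
        from scipy.integrate import quad

        return quad(lambda t: tte_survival(self, t, covariates), 0, np.inf,
                    limit=200)[0]


def _validate_params(family: str, params: tuple) -> None:
    if any(not math.isfinite(p) for p in params):
        raise ValueError(f"{family} parameters must be finite: {params}")
    if family == "exponential":
        if params[0] <= 0:
            raise ValueError("exponential rate must be > 0")
    elif family in ("weibull", "loglogistic"):
        if params[0] <= 0 or params[1] <= 0:
            raise ValueError(f"{family} shape and scale must be > 0")
    elif family == "lognormal":
        if params[1] <= 0:
            raise ValueError("lognormal sigma must be > 0")
    elif family == "gompertz":
        if params[0] < 0:
            raise ValueError("gompertz shape must be >= 0 (S must vanish at infinity)")
        if params[1] <= 0:
            raise ValueError("gompertz rate must be > 0")


def tte_survival(model: TTEModel, t, covariates: dict | None = None):
    """Survival function S(t) of a time-to-event law; vectorised in ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival function requires t >= 0")
    fam = model.family
    p = model.effective_params(covariates)
    if fam == "exponential":
        out = np.exp(-p[0] * t)
    elif fam == "weibull":
        out = np.exp(-((t / p[1]) ** p[0]))
    elif fam == "lognormal":
        with np.errstate(divide="ignore"):
            out = stats.norm.sf((np.log(np.maximum(t, 1e-300)) - p[0]) / p[1])
        out = np.where(t == 0, 1.0, out)
    elif fam == "loglogistic":
        out = 1.0 / (1.0 + (t / p[1]) ** p[0])
    else:  # gompertz
        shape, rate = p
        if shape == 0.0:
            out = np.exp(-rate * t)
        else:
            out = np.exp(-(rate / shape) * np.expm1(shape * t))
    return out if out.ndim else float(out)


def tte_quantile(model: TTEModel, u, covariates: dict | None = None):
    """Inverse CDF: the time t with P(T <= t) = u."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("quantile level must lie in [0, 1)")
    fam = model.family
    p = model.effective_params(covariates)
    if fam == "exponential":
        out = -np.log1p(-u) / p[0]
    elif fam == "weibull":
        out = p[1] * (-np.log1p(-u)) ** (1.0 / p[0])
    elif fam == "lognormal":
        out = np.exp(p[0] + p[1] * stats.norm.ppf(u))
        out = np.where(u == 0, 0.0, out)
    elif fam == "loglogistic":
        with np.errstate(divide="ignore"):
            out = p[1] * (u / (1.0 - u)) ** (1.0 / p[0])
        out = np.where(u == 0, 0.0, out)
    else:  # gompertz
        shape, rate = p
        if shape == 0.0:
            out = -np.log1p(-u) / rate
        else:
            out = np.log1p(-shape * np.log1p(-u) / rate) / shape
    return out if out.ndim else float(out)


def sample_tte(model: TTEModel, covariates: dict | None = None, *,
               rng=None, seed=None, size=None):
    """Inverse-CDF draw(s) from a time-to-event law.

    Exactly one of ``rng`` (a numpy Generator) or ``seed`` must be given; the
    same seed always yields the same draw.
    """
    rng = _resolve_rng(rng, seed)
    u = rng.random(size) if size is not None else rng.random()
    return tte_quantile(model, u, covariates)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*loglik."""
    if k < 0:
        raise ValueError("parameter count k must be >= 0")
    return 2.0 * k - 2.0 * loglik


def sample_beta(alpha: float, beta: float, *, rng=None, seed=None) -> float:
    """Beta draw; a zero hyperparameter gives the corresponding point mass."""
    if alpha < 0 or beta < 0:
        raise ValueError("Beta hyperparameters must be non-negative")
    if alpha == 0 and beta == 0:
        raise ValueError("Beta(0, 0) is undefined")
    if alpha == 0:
        return 0.0
    if beta == 0:
        return 1.0
    rng = _resolve_rng(rng, seed)
    return float(rng.beta(alpha, beta))


def sample_dirichlet(alphas, *, rng=None, seed=None) -> np.ndarray:
    """Dirichlet draw on the simplex; zero-alpha components are fixed at 0."""
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas < 0):
        raise ValueError("Dirichlet hyperparameters must be non-negative")
    if np.all(alphas == 0):
        raise ValueError("all-zero Dirichlet is undefined")
    rng = _resolve_rng(rng, seed)
    out = np.zeros_like(alphas)
    pos = alphas > 0
    if pos.sum() == 1:
        out[pos] = 1.0
        return out
    out[pos] = rng.dirichlet(alphas[pos])
    return out


def sample_background_death_age(life_table, current_age: float, sex: str, *,
                                rng=None, seed=None) -> float:
    """Age at death from annual life-table probabilities qx.

    Sequential Bernoulli trials over whole years of age starting at the
    current (possibly fractional) age; the fractional time of death within the
    death year is drawn uniformly. Returns an age strictly greater than
    ``current_age`` and never beyond the terminal table age + 1.
    """
    rng = _resolve_rng(rng, seed)
    age = int(math.floor(current_age))
    qx = life_table.qx_vector(sex)
    min_age, max_age = life_table.age_range()
    if age < min_age or age > max_age:
        raise ValueError(f"age {current_age} outside life table range "
                         f"[{min_age}, {max_age}]")
    for a in range(age, max_age + 1):
        q = qx[a - min_age]
        if a == age:
            # partial first year: death prob scaled by the remaining fraction
            frac = current_age - age
            if rng.random() < q * (1.0 - frac):
                return current_age + rng.random() * (a + 1 - current_age)
        elif rng.random() < q:
            return a + rng.random()
    return max_age + rng.random()  # terminal qx=1 should make this unreachable


def _resolve_rng(rng, seed):
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError("supply either rng or seed; hidden global state is not used")
    return np.random.default_rng(seed)


def to_unconstrained(family: str, params) -> np.ndarray:
    """Map native parameters to the unconstrained scale used for vcov/PSA.

    Positivity-constrained parameters are log-transformed; the lognormal
    location mu is already unconstrained and passes through unchanged.
    """
    params = np.asarray(params, dtype=float)
    out = np.log(np.maximum(params, 1e-300))
    if family == "lognormal":
        out[0] = params[0]
    return out


def from_unconstrained(family: str, theta) -> tuple:
    theta = np.asarray(theta, dtype=float)
    params = np.exp(theta)
    if family == "lognormal":
        params[0] = theta[0]
    return tuple(params)


def perturb_tte_model(model: TTEModel, rng) -> TTEModel:
    """Multivariate-normal draw of the model's coefficients for PSA.

    The draw is on the unconstrained scale (see :func:`to_unconstrained`)
    with the stored ``vcov``. Models without a ``vcov`` are returned
    unchanged.
    """
    if model.vcov is None:
        return model
    theta = to_unconstrained(model.family, model.params)
    drawn = rng.multivariate_normal(theta, np.asarray(model.vcov, dtype=float))
    return replace(model, params=from_unconstrained(model.family, drawn),
                   vcov=model.vcov)
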