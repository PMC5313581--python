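"""Internal-validation utilities: Kaplan-Meier curves and cost capture.

The model is checked by comparing its simulated survival against the
product-limit estimate from (synthetic) registry follow-up, and its mean
simulated cost against an empirical reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter


@dataclass
class KMCurve:
    """Right-continuous product-limit step function."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def at(self, t) -> np.ndarray:
        """S(t) evaluated by step lookup; S = 1 before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return out if out.ndim else float(out)


def km_curve(durations, event_flags) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    durations = np.asarray(durations, dtype=float)
    event_flags = np.asarray(event_flags, dtype=bool)
    if durations.size == 0:
        raise ValueError("cannot estimate a survival curve from no subjects")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=event_flags)
    table = kmf.event_table
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = table["at_risk"].reindex(times).to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, n_at_risk=at_risk)


def km_sup_distance(a: KMCurve, b: KMCurve, t_max: float | None = None) -> float:
    """Sup-norm distance between two KM curves on a shared time grid."""
    grid = np.union1d(a.times, b.times)
    if t_max is not None:
        grid = grid[grid <= t_max]
    return float(np.max(np.abs(a.at(grid) - b.at(grid))))


def cost_capture_ratio(simulated_mean: float, reference_mean: float) -> float:
    """Fraction of an empirical reference cost captured by the simulation."""
    if reference_mean <= 0:
        raise ValueError("reference mean cost must be positive")
    return simulated_mean / reference_mean
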