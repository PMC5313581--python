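"""Phase-stamped cost and survival accounting along a trajectory.

Every cash flow is booked at its event time and discounted there at the
annual rate (3.5% by default); a discrete-event model has no cycles, so no
half-cycle correction applies. Life-days are accumulated both undiscounted
and as the analytic integral of the discount factor over alive time, since
both economic and health outcomes are discounted.

Costing phases mirror the published breakdown: diagnosis, each treatment
line (second line split by ASCT), follow-up during first/second response,
and end-of-life care split by whether the patient was ever treated. Phase
support bundles and one-off extras are booked at the phase start; chemotherapy
is booked per cycle at evenly spaced times across the time in treatment;
follow-up visits follow a quarterly-then-annual schedule that stops at
response exit, cure, or the horizon. Cured patients accrue no further
disease-related cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dists import DAYS_PER_YEAR
from .engine import Trajectory
from .params import ModelParameters

PHASES = ("diagnosis", "line1", "line2", "line2_asct", "line3",
          "followup_resp1", "followup_resp2", "eol_untreated", "eol_treated")


def discount_factor(t_years: float, annual_rate: float) -> float:
    """Present-value factor (1 + r)^(-t) for a cash flow t years out."""
    if t_years < 0:
        raise ValueError("cannot discount a cash flow at negative time")
    if annual_rate < 0:
        raise ValueError("annual discount rate must be >= 0")
    return (1.0 + annual_rate) ** (-t_years)


def discounted_person_days(t_days: float, annual_rate: float) -> float:
    """Integral of the discount factor over [0, t] days of alive time."""
    if t_days < 0:
        raise ValueError("alive time must be >= 0")
    if annual_rate == 0.0:
        return t_days
    log1r = math.log1p(annual_rate)
    t_years = t_days / DAYS_PER_YEAR
    return DAYS_PER_YEAR * (1.0 - (1.0 + annual_rate) ** (-t_years)) / log1r


def regimen_course_cost(regimen: str, n_cycles: int,
                        params: ModelParameters) -> float:
    """Undiscounted cost of a full chemotherapy course."""
    if n_cycles < 0:
        raise ValueError("cycle count must be >= 0")
    try:
        item = params.regimens[regimen]
    except KeyError:
        raise KeyError(f"unknown regimen {regimen!r}") from None
    return params.unit_cost(item) * n_cycles


@dataclass
class LedgerEntry:
    phase: str
    time_days: float
    cost_gbp: float
    cost_gbp_discounted: float


@dataclass
class CostLedger:
    """Per-patient phase-stamped costs and survival accumulators."""

    patient_id: int
    entries: list = field(default_factory=list)
    phase_durations: dict = field(default_factory=dict)
    life_days: float = 0.0
    life_days_discounted: float = 0.0
    treated: bool = False
    age_at_diagnosis: float = float("nan")
    had_asct: bool = False
    max_line: int = 0

    def book(self, phase: str, time_days: float, amount: float, rate: float):
        disc = amount * discount_factor(time_days / DAYS_PER_YEAR, rate)
        self.entries.append(LedgerEntry(phase, time_days, amount, disc))

    def phase_cost(self, phase: str, discounted: bool = True) -> float:
        return sum((e.cost_gbp_discounted if discounted else e.cost_gbp)
                   for e in self.entries if e.phase == phase)

    def total_cost(self, discounted: bool = True) -> float:
        return sum((e.cost_gbp_discounted if discounted else e.cost_gbp)
                   for e in self.entries)

    def phases_visited(self) -> set:
        return {e.phase for e in self.entries}


def _bundle_cost(params: ModelParameters, bundle_name: str) -> float:
    try:
        items = params.phase_bundles[bundle_name]
    except KeyError:
        raise KeyError(f"no costing bundle configured for {bundle_name!r}") from None
    return sum(params.unit_cost(item) * qty for item, qty in items)


def _followup_visit_offsets(end_days: float, params: ModelParameters):
    """Visit offsets (days since response start) under the follow-up schedule."""
    fu = params.followup
    q = float(fu["quarterly_interval_days"])
    q_until = float(fu["quarterly_years"]) * DAYS_PER_YEAR
    annual = float(fu["annual_interval_days"])
    offsets = []
    t = q
    while t <= min(end_days, q_until) + 1e-9:
        offsets.append(t)
        t += q
    t = q_until + annual
    while t <= end_days + 1e-9:
        offsets.append(t)
        t += annual
    return offsets


def cost_trajectory(traj: Trajectory, params: ModelParameters) -> CostLedger:
    """Accumulate all phase costs and (discounted) life-days for one patient."""
    rate = params.discount_rate_annual
    horizon = traj.horizon_days
    ledger = CostLedger(patient_id=traj.patient_id, treated=traj.treated,
                        age_at_diagnosis=traj.attrs.age_at_diagnosis,
                        had_asct=traj.had_asct, max_line=traj.max_line)
    cure_days = params.cure_threshold_years * DAYS_PER_YEAR
    visit_cost = params.unit_cost(params.followup["visit_item"])

    for ev in traj.events:
        t0 = ev.time_days
        if ev.state == "diagnosis":
            ledger.book("diagnosis", t0, _bundle_cost(params, "diagnosis"), rate)
        elif ev.state == "treatment_start":
            line = min(ev.detail["line"], 3)
            asct = bool(ev.detail.get("asct"))
            phase = "line2_asct" if (line == 2 and asct) else f"line{line}"
            bundle = "line2_asct_support" if (line == 2 and asct) \
                else f"line{line}_support"
            ledger.book(phase, t0, _bundle_cost(params, bundle), rate)
            for item, qty in ev.detail.get("extras", []):
                ledger.book(phase, t0, params.unit_cost(item) * qty, rate)
            n_cycles = ev.detail["cycles"]
            dur = ev.detail["duration_days"]
            per_cycle = regimen_course_cost(ev.detail["regimen"], 1, params)
            for i in range(n_cycles):
                t_cycle = t0 + (dur * i / n_cycles if n_cycles else 0.0)
                if t_cycle <= horizon:
                    ledger.book(phase, t_cycle, per_cycle, rate)
            observed_end = min(t0 + dur, horizon)
            ledger.phase_durations[phase] = (
                ledger.phase_durations.get(phase, 0.0) + (observed_end - t0))
        elif ev.state == "response_start":
            number = ev.detail["number"]
            phase = f"followup_resp{number}"
            end = min(ev.detail["planned_exit_days"], cure_days, horizon - t0)
            for off in _followup_visit_offsets(end, params):
                ledger.book(phase, t0 + off, visit_cost, rate)
            if phase not in ledger.phases_visited():
                # phase is "visited" even when the response is too short for
                # any scheduled visit; book an explicit zero entry
                ledger.book(phase, t0, 0.0, rate)
            if traj.cured and ev.detail["planned_exit_days"] >= cure_days:
                # remission ran into cure: time in response lasts until death
                # or the horizon, although costs stopped at the cure threshold
                dur_resp = max(0.0, traj.life_days - t0)
            else:
                dur_resp = max(0.0, min(ev.detail["planned_exit_days"],
                                        horizon - t0))
            ledger.phase_durations[phase] = (
                ledger.phase_durations.get(phase, 0.0) + dur_resp)
        elif ev.state == "eol_start":
            phase = ("eol_treated" if ev.detail["treated_before"]
                     else "eol_untreated")
            ledger.book(phase, t0, _bundle_cost(params, phase), rate)
            observed = min(ev.detail["duration_days"], horizon - t0)
            ledger.phase_durations[phase] = (
                ledger.phase_durations.get(phase, 0.0) + observed)

    ledger.life_days = traj.life_days
    ledger.life_days_discounted = discounted_person_days(traj.life_days, rate)
    return ledger


def ledgers_to_frame(ledgers) -> pd.DataFrame:
    rows = []
    for led in ledgers:
        for e in led.entries:
            rows.append({"patient_id": led.patient_id, "phase": e.phase,
                         "time_days": e.time_days, "cost_gbp": e.cost_gbp,
                         "cost_gbp_discounted": e.cost_gbp_discounted})
    return pd.DataFrame(rows, columns=["patient_id", "phase", "time_days",
                                       "cost_gbp", "cost_gbp_discounted"])


def summarize_ledgers(ledgers, discounted: bool = True) -> pd.DataFrame:
    """Per-phase mean cost and duration over the patients visiting each phase.

    Intervals here are patient-level normal-approximation 95% bands
    (``ci_source`` column flags this); probabilistic-sensitivity intervals
    are computed across replicate runs in :mod:`dlbclsim.analyses`.
    """
    ledgers = list(ledgers)
    if not ledgers:
        raise ValueError("need at least one ledger to summarise")
    rows = []
    for phase in PHASES:
        costs = [led.phase_cost(phase, discounted) for led in ledgers
                 if phase in led.phases_visited()]
        if not costs:
            continue  # a phase nobody visited is absent, not zero
        durations = [led.phase_durations.get(phase) for led in ledgers
                     if phase in led.phases_visited()
                     and led.phase_durations.get(phase) is not None]
        costs = np.asarray(costs)
        mean = float(costs.mean())
        se = float(costs.std(ddof=1) / math.sqrt(len(costs))) if len(costs) > 1 else 0.0
        rows.append({
            "phase": phase, "n": len(costs), "mean_cost_gbp": mean,
            "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se,
            "mean_duration_days": float(np.mean(durations)) if durations else np.nan,
            "ci_source": "patient_se",
        })
    return pd.DataFrame(rows)
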