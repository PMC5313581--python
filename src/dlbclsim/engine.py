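"""Discrete-event pathway engine.

Each simulated patient is generated with fixed attributes (age at diagnosis,
sex, diagnostic category) and walked event-by-event through the treatment
pathway: an initial decision between curative-intent chemotherapy and
palliative management; up to three (or more) chemotherapy lines with
per-line outcomes (died during treatment / response / no response);
response periods ending in relapse, death in remission, or cure once
remission has lasted the cure threshold (5 years by default); re-treatment
decisions for refractory and relapsed disease; and end-of-life care. Lines
beyond the third reuse the third-line behaviour. After cure, mortality
reverts to the general-population life table and no further disease-related
events occur.

Event clocks advance by sampled inter-event times (days since diagnosis);
there are no fixed cycles. Every patient gets an independent,
counter-derived random stream so cohort results do not depend on iteration
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dists import DAYS_PER_YEAR, sample_background_death_age, tte_quantile
from .params import ModelParameters

HORIZONS = ("5y", "15y", "lifetime")

#: hard cap on treatment lines, a guard against pathological configurations
MAX_LINES = 12

DIAGNOSTIC_CATEGORIES = (
    "stage_ia", "cns_involvement", "standard", "died_before_diagnosis")


@dataclass(frozen=True)
class PatientAttributes:
    age_at_diagnosis: float
    sex: str
    diagnostic_category: str

    def __post_init__(self):
        if self.diagnostic_category not in DIAGNOSTIC_CATEGORIES:
            raise ValueError(
                f"unknown diagnostic category {self.diagnostic_category!r}")


@dataclass
class EventRecord:
    time_days: float
    state: str
    detail: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Ordered event history of one simulated patient, horizon-truncated."""

    patient_id: int
    attrs: PatientAttributes
    events: list
    horizon_days: float

    @property
    def death_time(self):
        for ev in self.events:
            if ev.state == "death":
                return ev.time_days
        return None

    @property
    def alive_at_horizon(self) -> bool:
        return self.death_time is None

    @property
    def life_days(self) -> float:
        t = self.death_time
        return self.horizon_days if t is None else t

    @property
    def treated(self) -> bool:
        return any(ev.state == "treatment_start" for ev in self.events)

    @property
    def max_line(self) -> int:
        lines = [ev.detail["line"] for ev in self.events
                 if ev.state == "treatment_start"]
        return max(lines) if lines else 0

    @property
    def had_asct(self) -> bool:
        return any(ev.state == "treatment_start" and ev.detail.get("asct")
                   for ev in self.events)

    @property
    def cured(self) -> bool:
        return any(ev.state == "cure" for ev in self.events)

    def states(self) -> list:
        return [ev.state for ev in self.events]


@dataclass
class EngineConfig:
    horizon: str = "lifetime"
    n: int = 4880
    seed: int = 0

    def __post_init__(self):
        if self.horizon not in HORIZONS:
            raise ValueError(f"horizon must be one of {HORIZONS}")


def horizon_days(horizon: str, attrs: PatientAttributes,
                 params: ModelParameters) -> float:
    if horizon == "5y":
        return 5.0 * DAYS_PER_YEAR
    if horizon == "15y":
        return 15.0 * DAYS_PER_YEAR
    return max(0.0, (params.max_age_years - attrs.age_at_diagnosis)) * DAYS_PER_YEAR


def _categorical(rng, p: np.ndarray) -> int:
    return int(np.searchsorted(np.cumsum(p), rng.random() * p.sum(), side="right"))


def decide(node_name: str, attrs: PatientAttributes, params: ModelParameters,
           rng) -> str:
    """Draw an outcome label from an age-banded decision node."""
    node = params.decision_nodes[node_name]
    p = node.prob_vector(attrs.age_at_diagnosis)
    return node.outcome_labels[_categorical(rng, p)]


def generate_patient(params: ModelParameters, rng_or_seed) -> PatientAttributes:
    """Fixed covariates: scaled-Beta age, age-banded sex and diagnostic group."""
    rng = _as_rng(rng_or_seed)
    lo, hi = params.age_range_years
    age = lo + (hi - lo) * rng.beta(*params.age_beta)
    sex_node = params.decision_nodes["sex"]
    sex = sex_node.outcome_labels[_categorical(rng, sex_node.prob_vector(age))]
    cat_node = params.decision_nodes["diagnostic_category"]
    cat = cat_node.outcome_labels[_categorical(rng, cat_node.prob_vector(age))]
    return PatientAttributes(age_at_diagnosis=age, sex=sex, diagnostic_category=cat)


def _draw_time(params: ModelParameters, transition: str, rng) -> float:
    try:
        model = params.tte_models[transition]
    except KeyError:
        raise KeyError(f"no time-to-event model for transition {transition!r}") from None
    return float(tte_quantile(model, rng.random()))


def _choose_regimen(params: ModelParameters, line: int, category: str, rng):
    choices = params.regimen_choices(line, category)
    probs = np.array([c["p"] for c in choices])
    chosen = choices[_categorical(rng, probs)]
    cyc_counts = sorted(chosen["cycles"])
    cyc_probs = np.array([chosen["cycles"][c] for c in cyc_counts], dtype=float)
    n_cycles = int(cyc_counts[_categorical(rng, cyc_probs)])
    extras = [(e["item"], float(e["qty"])) for e in chosen.get("extras", [])]
    return chosen["regimen"], n_cycles, extras


def simulate_patient(attrs: PatientAttributes, params: ModelParameters,
                     config: EngineConfig, rng_or_seed,
                     patient_id: int = 0) -> Trajectory:
    """Walk one patient through the pathway; returns a truncated trajectory."""
    rng = _as_rng(rng_or_seed)
    hdays = horizon_days(config.horizon, attrs, params)
    events = [EventRecord(0.0, "diagnosis", {"category": attrs.diagnostic_category})]
    cure_days = params.cure_threshold_years * DAYS_PER_YEAR

    def finish():
        events.sort(key=lambda ev: ev.time_days)
        kept, terminated = [], False
        for ev in events:
            if ev.time_days > hdays + 1e-9:
                break
            kept.append(ev)
            if ev.state == "death":
                terminated = True
                break
        if not terminated:
            kept.append(EventRecord(hdays, "alive_at_horizon", {}))
        return Trajectory(patient_id=patient_id, attrs=attrs, events=kept,
                          horizon_days=hdays)

    if attrs.diagnostic_category == "died_before_diagnosis":
        events.append(EventRecord(0.0, "death", {"cause": "died_before_diagnosis"}))
        return finish()

    if decide("initial_treatment", attrs, params, rng) == "not_treated":
        dur = _draw_time(params, "eol_untreated", rng)
        events.append(EventRecord(0.0, "eol_start",
                                  {"treated_before": False, "duration_days": dur}))
        events.append(EventRecord(dur, "death", {"cause": "end_of_life"}))
        return finish()

    t = _draw_time(params, "diagnosis_to_treatment", rng)
    line = 1
    response_number = 0

    def end_of_life_treated(t0: float):
        dur = _draw_time(params, "eol_treated", rng)
        events.append(EventRecord(t0, "eol_start",
                                  {"treated_before": True, "duration_days": dur}))
        events.append(EventRecord(t0 + dur, "death", {"cause": "end_of_life"}))

    while True:
        line_key = min(line, 3)
        regimen, n_cycles, extras = _choose_regimen(
            params, line, attrs.diagnostic_category if line == 1 else "standard", rng)
        asct = (line == 2 and
                decide("asct_line2", attrs, params, rng) == "asct")
        transition = ("treatment_line2_asct" if asct
                      else f"treatment_line{line_key}")
        dur = _draw_time(params, transition, rng)
        events.append(EventRecord(t, "treatment_start", {
            "line": line, "regimen": regimen, "cycles": n_cycles,
            "asct": asct, "duration_days": dur, "extras": extras}))
        t += dur
        events.append(EventRecord(t, "treatment_end", {"line": line}))

        outcome = decide(f"outcome_line{line_key}", attrs, params, rng)
        if outcome == "died_during_treatment":
            events.append(EventRecord(t, "death", {"cause": "died_during_treatment"}))
            break

        if outcome == "response":
            response_number = min(response_number + 1, 2)
            exit_transition = ("first_response_exit" if response_number == 1
                               else "second_response_exit")
            exit_after = _draw_time(params, exit_transition, rng)
            events.append(EventRecord(t, "response_start", {
                "number": response_number, "line": line,
                "planned_exit_days": exit_after}))
            if exit_after >= cure_days:
                t_cure = t + cure_days
                events.append(EventRecord(t_cure, "cure", {}))
                age_at_cure = attrs.age_at_diagnosis + t_cure / DAYS_PER_YEAR
                age_at_cure = min(age_at_cure, params.life_table.age_range()[1])
                death_age = sample_background_death_age(
                    params.life_table, age_at_cure, attrs.sex, rng=rng)
                t_death = t_cure + (death_age - age_at_cure) * DAYS_PER_YEAR
                events.append(EventRecord(t_death, "death",
                                          {"cause": "background"}))
                break
            t += exit_after
            exit_node = f"exit_type_resp{response_number}"
            events.append(EventRecord(t, "response_end",
                                      {"number": response_number}))
            if decide(exit_node, attrs, params, rng) == "death_in_remission":
                events.append(EventRecord(t, "death",
                                          {"cause": "death_in_remission"}))
                break
            events.append(EventRecord(t, "relapse", {"after_line": line}))
            if decide(f"relapse_line{line_key}", attrs, params, rng) == "treated":
                line += 1
            else:
                end_of_life_treated(t)
                break
        else:  # no response: refractory disease
            events.append(EventRecord(t, "refractory", {"after_line": line}))
            if decide(f"refractory_line{line_key}", attrs, params, rng) == "treated":
                line += 1
            else:
                end_of_life_treated(t)
                break

        if line > MAX_LINES:
            end_of_life_treated(t)
            break

    return finish()


def patient_stream(master_seed: int, index: int) -> np.random.Generator:
    """Counter-based per-patient stream: independent of iteration order."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), index)))


def run_cohort(n: int, params: ModelParameters, config: EngineConfig,
               seed: int | None = None) -> list:
    """Simulate ``n`` independent patients; reproducible under the seed."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    seed = config.seed if seed is None else seed
    out = []
    for i in range(n):
        rng = patient_stream(seed, i)
        attrs = generate_patient(params, rng)
        out.append(simulate_patient(attrs, params, config, rng, patient_id=i))
    return out


def trajectories_to_frame(trajectories) -> "pd.DataFrame":
    """Tidy export: one row per event."""
    import pandas as pd

    rows = []
    for traj in trajectories:
        for ev in traj.events:
            rows.append({
                "patient_id": traj.patient_id,
                "event_time_days": ev.time_days,
                "state": ev.state,
                "detail": ";".join(f"{k}={v}" for k, v in sorted(ev.detail.items())
                                   if k != "extras"),
            })
    return pd.DataFrame(rows, columns=["patient_id", "event_time_days",
                                       "state", "detail"])


def _as_rng(rng_or_seed):
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)
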