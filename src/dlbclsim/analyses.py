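"""Top-level experiments: incidence-cohort horizon analyses, age subgroups,
probabilistic sensitivity analysis, prevalence-based annual national cost,
and cost per life-year gained.

An incidence analysis follows one annual diagnosis cohort (UK expected
incidence 4880 by default) over a 5-year, 15-year or lifetime-to-age-100
horizon and stratifies exactly as the published breakdown: everyone;
treated with curative intent; first-line only; second-line-plus with and
without ASCT; not treated. The prevalence analysis staggers annual incident
cohorts, discards a burn-in period, and books every cash flow in the
calendar year it occurs, so the reported figure is the annual national
spend on existing plus newly diagnosed patients.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .costing import cost_trajectory
from .dists import DAYS_PER_YEAR
from .engine import EngineConfig, run_cohort
from .params import ModelParameters, draw_psa_parameters

STRATA = ("total", "treated", "first_line_only", "second_line_asct",
          "second_line_no_asct", "not_treated")


def _stratum_mask(ledgers, stratum: str) -> np.ndarray:
    if stratum == "total":
        return np.ones(len(ledgers), dtype=bool)
    if stratum == "treated":
        return np.array([led.treated for led in ledgers])
    if stratum == "not_treated":
        return np.array([not led.treated for led in ledgers])
    if stratum == "first_line_only":
        return np.array([led.treated and led.max_line == 1 for led in ledgers])
    if stratum == "second_line_asct":
        return np.array([led.max_line >= 2 and led.had_asct for led in ledgers])
    if stratum == "second_line_no_asct":
        return np.array([led.max_line >= 2 and not led.had_asct
                         for led in ledgers])
    raise ValueError(f"unknown stratum {stratum!r}")


def _summarise(ledgers, mask, stratum, horizon, discounted=True) -> dict:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return {"stratum": stratum, "horizon": horizon, "n": 0,
                "mean_cost": np.nan, "cost_ci_low": np.nan,
                "cost_ci_high": np.nan, "mean_life_days": np.nan,
                "life_days_ci_low": np.nan, "life_days_ci_high": np.nan,
                "mean_life_days_undiscounted": np.nan, "ci_source": "patient_se"}
    costs = np.array([ledgers[i].total_cost(discounted) for i in idx])
    days = np.array([ledgers[i].life_days_discounted if discounted
                     else ledgers[i].life_days for i in idx])
    days_raw = np.array([ledgers[i].life_days for i in idx])

    def ci(x):
        m = float(x.mean())
        se = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
        return m, m - 1.96 * se, m + 1.96 * se

    mc, mcl, mch = ci(costs)
    md, mdl, mdh = ci(days)
    return {"stratum": stratum, "horizon": horizon, "n": int(idx.size),
            "mean_cost": mc, "cost_ci_low": mcl, "cost_ci_high": mch,
            "mean_life_days": md, "life_days_ci_low": mdl,
            "life_days_ci_high": mdh,
            "mean_life_days_undiscounted": float(days_raw.mean()),
            "ci_source": "patient_se"}


def cohort_ledgers(params: ModelParameters, horizon: str, n: int, seed: int):
    config = EngineConfig(horizon=horizon, n=n, seed=seed)
    trajectories = run_cohort(n, params, config)
    return trajectories, [cost_trajectory(t, params) for t in trajectories]


def incidence_analysis(params: ModelParameters, horizon: str = "lifetime",
                       n: int = 4880, seed: int = 0,
                       discounted: bool = True) -> pd.DataFrame:
    """One diagnosis-year cohort, stratified by pathway reached."""
    _, ledgers = cohort_ledgers(params, horizon, n, seed)
    rows = [_summarise(ledgers, _stratum_mask(ledgers, s), s, horizon, discounted)
            for s in STRATA]
    return pd.DataFrame(rows)


def subgroup_by_age(params: ModelParameters, cut: float = 70.0,
                    horizon: str = "lifetime", n: int = 4880,
                    seed: int = 0) -> pd.DataFrame:
    """Overall / treated / untreated outcomes split at an age cut."""
    _, ledgers = cohort_ledgers(params, horizon, n, seed)
    young = np.array([led.age_at_diagnosis < cut for led in ledgers])
    rows = []
    for stratum in ("total", "treated", "not_treated"):
        base = _stratum_mask(ledgers, stratum)
        for label, age_mask in ((f"under_{cut:g}", young),
                                (f"over_{cut:g}", ~young)):
            row = _summarise(ledgers, base & age_mask, stratum, horizon)
            row["age_group"] = label
            rows.append(row)
    return pd.DataFrame(rows)


def run_psa(params: ModelParameters, iterations: int = 500, n: int = 4880,
            horizon: str = "lifetime", seed: int = 0) -> pd.DataFrame:
    """Percentile intervals over repeated runs with parameters redrawn.

    Each iteration draws one parameter set from the Beta/Dirichlet and
    multivariate-normal uncertainty distributions, simulates a fresh cohort,
    and records stratum means; the 2.5th/97.5th percentiles across
    iterations form the interval. Per-iteration seeds derive from the master
    seed, so a fixed master seed reproduces the intervals exactly.
    """
    if iterations < 1:
        raise ValueError("need at least one PSA iteration")
    master = np.random.SeedSequence(seed)
    children = master.spawn(iterations)
    per_iter = {s: {"cost": [], "days": []} for s in STRATA}
    for child in children:
        draw_ss, cohort_ss = child.spawn(2)
        drawn = draw_psa_parameters(params, np.random.default_rng(draw_ss))
        cohort_seed = int(cohort_ss.generate_state(1)[0] % (2 ** 31))
        _, ledgers = cohort_ledgers(drawn, horizon, n, cohort_seed)
        for s in STRATA:
            mask = _stratum_mask(ledgers, s)
            if mask.any():
                idx = np.flatnonzero(mask)
                per_iter[s]["cost"].append(
                    float(np.mean([ledgers[i].total_cost() for i in idx])))
                per_iter[s]["days"].append(
                    float(np.mean([ledgers[i].life_days_discounted for i in idx])))
    rows = []
    for s in STRATA:
        cost = np.asarray(per_iter[s]["cost"])
        days = np.asarray(per_iter[s]["days"])
        if cost.size == 0:
            continue
        rows.append({
            "stratum": s, "horizon": horizon, "iterations": int(cost.size),
            "mean_cost": float(cost.mean()),
            "cost_ci_low": float(np.percentile(cost, 2.5)),
            "cost_ci_high": float(np.percentile(cost, 97.5)),
            "mean_life_days": float(days.mean()),
            "life_days_ci_low": float(np.percentile(days, 2.5)),
            "life_days_ci_high": float(np.percentile(days, 97.5)),
            "ci_source": "psa_percentile",
        })
    return pd.DataFrame(rows)


def prevalence_analysis(params: ModelParameters, annual_n: int = 4880,
                        burn_in_years: int = 10, collect_years: int = 5,
                        seed: int = 0, sim_annual_n: int | None = None) -> dict:
    """Annual national cost after a burn-in of staggered incident cohorts.

    One cohort of ``annual_n`` patients is diagnosed per simulated year,
    with diagnoses spread uniformly across the year. Every discounted cash
    flow is booked in the calendar year it occurs; totals are collected for
    the ``collect_years`` years after ``burn_in_years``. ``sim_annual_n``
    simulates a smaller cohort per year and rescales totals linearly (the
    model is linear in cohort size).
    """
    m = sim_annual_n or annual_n
    scale = annual_n / m
    n_years = burn_in_years + collect_years
    totals = np.zeros(n_years + 120)  # spill room for late cash flows
    for year in range(n_years):
        cohort_seed = int(np.random.SeedSequence((seed, year)).generate_state(1)[0]
                          % (2 ** 31))
        _, ledgers = cohort_ledgers(params, "lifetime", m, cohort_seed)
        for led in ledgers:
            offset = (led.patient_id + 0.5) / m  # stagger within the year
            for entry in led.entries:
                cal = year + offset + entry.time_days / DAYS_PER_YEAR
                idx = int(cal)
                if idx < len(totals):
                    totals[idx] += entry.cost_gbp_discounted * scale
    window = totals[burn_in_years:n_years]
    return {
        "annual_totals_gbp": window.tolist(),
        "mean_annual_gbp": float(window.mean()),
        "lower_gbp": float(window.min()),
        "upper_gbp": float(window.max()),
        "burn_in_years": burn_in_years,
        "collect_years": collect_years,
        "annual_n": annual_n,
        "sim_annual_n": m,
    }


def cost_per_lyg(treated: dict, comparator: dict) -> float:
    """Incremental cost per life-year gained between two strata summaries.

    Returns NaN when the life-year difference is (numerically) zero, since
    the ratio is then undefined.
    """
    dc = float(treated["mean_cost"]) - float(comparator["mean_cost"])
    dy = (float(treated["mean_life_days"])
          - float(comparator["mean_life_days"])) / DAYS_PER_YEAR
    if abs(dy) < 1e-12:
        return float("nan")
    return dc / dy
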