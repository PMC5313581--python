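"""Incidence, subgroup, PSA and prevalence analyses plus cost-per-LYG."""

import math

import numpy as np
import pytest

from dlbclsim import (cost_per_lyg, incidence_analysis, prevalence_analysis,
                      run_psa, subgroup_by_age)


@pytest.fixture(scope="module")
def lifetime_result(params):
    return incidence_analysis(params, "lifetime", n=1200, seed=30)


def _row(frame, stratum):
    return frame[frame.stratum == stratum].iloc[0]


class TestIncidence:
    def test_strata_additivity(self, lifetime_result):
        r = lifetime_result
        assert (_row(r, "treated").n + _row(r, "not_treated").n
                == _row(r, "total").n)
        assert (_row(r, "first_line_only").n + _row(r, "second_line_asct").n
                + _row(r, "second_line_no_asct").n == _row(r, "treated").n)

    def test_treated_costs_dominate_untreated(self, lifetime_result):
        assert (_row(lifetime_result, "treated").mean_cost
                > _row(lifetime_result, "not_treated").mean_cost)
        assert (_row(lifetime_result, "treated").mean_life_days
                > _row(lifetime_result, "not_treated").mean_life_days)

    def test_horizon_monotonicity(self, params):
        """Same seed, growing horizon: costs and life-days never shrink.

        The 15-year window strictly contains the 5-year one for every
        patient, so those comparisons are exact. The lifetime horizon caps
        at age 100, which for patients diagnosed after 85 is *shorter* than
        15 years; the lifetime comparison therefore holds in aggregate (a
        large survival gain, near-identical cost) rather than path-by-path.
        """
        results = {h: incidence_analysis(params, h, n=500, seed=31)
                   for h in ("5y", "15y", "lifetime")}
        for stratum in ("total", "treated"):
            cost = {h: _row(results[h], stratum).mean_cost for h in results}
            days = {h: _row(results[h], stratum).mean_life_days for h in results}
            assert cost["5y"] <= cost["15y"] + 1e-9
            assert days["5y"] <= days["15y"] + 1e-9
            assert days["lifetime"] > days["15y"]
            assert cost["lifetime"] == pytest.approx(cost["15y"], rel=0.01)

    def test_cost_insensitive_to_long_horizons(self, params):
        """Treatment concludes early, so 15-year and lifetime costs agree."""
        r15 = incidence_analysis(params, "15y", n=800, seed=32)
        rlife = incidence_analysis(params, "lifetime", n=800, seed=32)
        assert (_row(rlife, "total").mean_cost
                == pytest.approx(_row(r15, "total").mean_cost, rel=0.01))


class TestSubgroups:
    def test_age_gradient_in_treated_patients(self, params):
        r = subgroup_by_age(params, cut=70.0, horizon="lifetime", n=1200,
                            seed=33)
        treated = r[r.stratum == "treated"].set_index("age_group")
        assert (treated.loc["under_70"].mean_life_days
                > treated.loc["over_70"].mean_life_days)
        untreated = r[r.stratum == "not_treated"].set_index("age_group")
        treated_gap = (treated.loc["under_70"].mean_life_days
                       - treated.loc["over_70"].mean_life_days)
        untreated_gap = abs(untreated.loc["under_70"].mean_life_days
                            - untreated.loc["over_70"].mean_life_days)
        assert untreated_gap / treated_gap < 1.0

    def test_degenerate_cut_handled(self, params):
        r = subgroup_by_age(params, cut=18.0, horizon="5y", n=150, seed=34)
        young_total = r[(r.stratum == "total")
                        & (r.age_group == "under_18")].iloc[0]
        assert young_total.n == 0
        assert math.isnan(young_total.mean_cost)


class TestPSA:
    def test_single_iteration_degenerate_interval(self, params):
        r = run_psa(params, iterations=1, n=120, horizon="lifetime", seed=35)
        total = _row(r, "total")
        assert total.cost_ci_low == pytest.approx(total.mean_cost)
        assert total.cost_ci_high == pytest.approx(total.mean_cost)

    def test_master_seed_determinism(self, params):
        a = run_psa(params, iterations=3, n=100, horizon="lifetime", seed=36)
        b = run_psa(params, iterations=3, n=100, horizon="lifetime", seed=36)
        assert a.equals(b)

    def test_intervals_cover_base_case_in_most_strata(self, params):
        psa = run_psa(params, iterations=12, n=500, horizon="lifetime", seed=37)
        base = incidence_analysis(params, "lifetime", n=500, seed=38)
        covered = 0
        checked = 0
        for stratum in psa.stratum:
            p = _row(psa, stratum)
            b = _row(base, stratum)
            if b.n < 20:
                continue
            checked += 1
            if p.cost_ci_low <= b.mean_cost <= p.cost_ci_high:
                covered += 1
        assert checked >= 4
        assert covered >= checked - 1


class TestPrevalence:
    def test_steady_state_renewal_identity(self, params):
        """Post-burn-in annual cost ~ incidence x mean lifetime cost."""
        m = 500
        prev = prevalence_analysis(params, annual_n=m, burn_in_years=10,
                                   collect_years=3, seed=39, sim_annual_n=m)
        lifetime = incidence_analysis(params, "lifetime", n=3000, seed=40)
        expected = m * _row(lifetime, "total").mean_cost
        assert prev["mean_annual_gbp"] == pytest.approx(expected, rel=0.05)

    def test_linear_rescaling(self, params):
        small = prevalence_analysis(params, annual_n=200, burn_in_years=3,
                                    collect_years=2, seed=41, sim_annual_n=200)
        scaled = prevalence_analysis(params, annual_n=2000, burn_in_years=3,
                                     collect_years=2, seed=41, sim_annual_n=200)
        assert scaled["mean_annual_gbp"] == pytest.approx(
            10 * small["mean_annual_gbp"], rel=1e-9)


class TestCostPerLYG:
    def test_published_style_arithmetic(self):
        """Ratio from rounded stratum means lands near £1537 per LYG."""
        treated = {"mean_cost": 22122.0, "mean_life_days": 4589.0}
        comparator = {"mean_cost": 2930.0, "mean_life_days": 30.0}
        ratio = cost_per_lyg(treated, comparator)
        assert ratio == pytest.approx(1537.4, abs=1.0)

    def test_identical_strata_undefined(self):
        row = {"mean_cost": 100.0, "mean_life_days": 365.25}
        assert math.isnan(cost_per_lyg(row, row))

    def test_homogeneity(self):
        a = {"mean_cost": 20000.0, "mean_life_days": 4000.0}
        b = {"mean_cost": 3000.0, "mean_life_days": 100.0}
        a2 = {"mean_cost": 37000.0, "mean_life_days": 4000.0}
        assert cost_per_lyg(a2, b) == pytest.approx(
            2 * cost_per_lyg(a, b), rel=1e-12)
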