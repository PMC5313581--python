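"""Pathway engine: patient generation, decisions, trajectories, cohorts."""

import numpy as np
import pytest
from scipy import stats

from dlbclsim import (EngineConfig, PatientAttributes, decide,
                      default_parameters, generate_patient, run_cohort,
                      simulate_patient)
from dlbclsim.dists import DAYS_PER_YEAR
from dlbclsim.params import ConfigurationError


def _cfg(horizon="lifetime", n=1, seed=0):
    return EngineConfig(horizon=horizon, n=n, seed=seed)


class TestPatientGeneration:
    def test_population_statistics(self, params):
        rng = np.random.default_rng(21)
        patients = [generate_patient(params, rng) for _ in range(20_000)]
        ages = np.array([p.age_at_diagnosis for p in patients])
        assert abs(ages.mean() - 67.8) < 1.5
        band = [p for p in patients if 60 <= p.age_at_diagnosis < 70]
        male = np.mean([p.sex == "male" for p in band])
        assert male == pytest.approx(0.50, abs=0.02)

    def test_fixed_seed_reproduces_patient(self, params):
        a = generate_patient(params, 99)
        b = generate_patient(params, 99)
        assert a == b

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            PatientAttributes(60.0, "male", "mystery")


class TestDecisions:
    def test_certain_node_ignores_seed(self, params):
        attrs = PatientAttributes(85.0, "female", "standard")
        for seed in range(10):
            rng = np.random.default_rng(seed)
            assert decide("relapse_line1", attrs, params, rng) == "treated"
            assert decide("refractory_line3", attrs, params, rng) == "not_treated"

    def test_initial_decision_rate(self, params):
        attrs = PatientAttributes(30.0, "male", "standard")
        rng = np.random.default_rng(22)
        treated = np.mean([decide("initial_treatment", attrs, params, rng)
                           == "treated" for _ in range(5000)])
        assert treated == pytest.approx(0.94, abs=0.02)

    def test_age_outside_bands_is_config_error(self, params):
        attrs = PatientAttributes(17.0, "male", "standard")
        with pytest.raises(ConfigurationError):
            decide("initial_treatment", attrs, params,
                   np.random.default_rng(0))


class TestTrajectories:
    def test_untreated_path_is_palliative_only(self, params):
        attrs = PatientAttributes(90.0, "female", "standard")
        # find a seed where the initial decision lands on palliation
        for seed in range(50):
            traj = simulate_patient(attrs, params, _cfg(), seed)
            if not traj.treated:
                break
        states = traj.states()
        assert states[0] == "diagnosis"
        assert "eol_start" in states and "death" in states
        assert "treatment_start" not in states

    def test_cure_requires_five_years_and_ends_disease_events(self, params):
        cure_days = params.cure_threshold_years * DAYS_PER_YEAR
        cured = None
        for seed in range(200):
            attrs = generate_patient(params, seed)
            traj = simulate_patient(attrs, params, _cfg(), seed)
            if traj.cured:
                cured = traj
                break
        assert cured is not None
        t_cure = next(ev.time_days for ev in cured.events if ev.state == "cure")
        t_resp = next(ev.time_days for ev in cured.events
                      if ev.state == "response_start")
        assert t_cure - t_resp == pytest.approx(cure_days)
        after = [ev for ev in cured.events if ev.time_days > t_cure]
        assert all(ev.state in ("death", "alive_at_horizon") for ev in after)
        death = cured.events[-1]
        assert death.state != "death" or death.detail["cause"] == "background"

    def test_died_before_diagnosis_gets_no_pathway(self, params):
        attrs = PatientAttributes(75.0, "male", "died_before_diagnosis")
        traj = simulate_patient(attrs, params, _cfg(), 1)
        assert traj.states() == ["diagnosis", "death"]
        assert traj.life_days == 0.0

    def test_five_year_horizon_truncates(self, params):
        for seed in range(40):
            attrs = generate_patient(params, seed)
            traj = simulate_patient(attrs, params, _cfg("5y"), seed)
            assert all(ev.time_days <= 5 * DAYS_PER_YEAR + 1e-6
                       for ev in traj.events)

    def test_times_nondecreasing_single_terminal(self, lifetime_cohort):
        for traj in lifetime_cohort[0]:
            times = [ev.time_days for ev in traj.events]
            assert all(b >= a - 1e-9 for a, b in zip(times, times[1:]))
            terminal = [ev for ev in traj.events
                        if ev.state in ("death", "alive_at_horizon")]
            assert len(terminal) == 1
            assert traj.events[-1] is terminal[0]


class TestCohorts:
    def test_reproducible_and_order_independent(self, params):
        a = run_cohort(50, params, _cfg(seed=5))
        b = run_cohort(50, params, _cfg(seed=5))
        assert [t.life_days for t in a] == [t.life_days for t in b]
        bigger = run_cohort(80, params, _cfg(seed=5))
        assert [t.life_days for t in bigger[:50]] == [t.life_days for t in a]

    def test_single_patient_cohort(self, params):
        assert len(run_cohort(1, params, _cfg(seed=1))) == 1

    def test_conservation(self, lifetime_cohort):
        trajectories = lifetime_cohort[0]
        dead = sum(not t.alive_at_horizon for t in trajectories)
        alive = sum(t.alive_at_horizon for t in trajectories)
        assert dead + alive == len(trajectories)

    def test_curative_fraction_matches_band_mixture(self, params):
        """Cohort treated share vs the analytic mixture over age bands."""
        n = 4000
        trajectories = run_cohort(n, params, _cfg(seed=6))
        a, b = params.age_beta
        lo, hi = params.age_range_years
        init = params.decision_nodes["initial_treatment"]
        diag = params.decision_nodes["diagnostic_category"]
        expected = 0.0
        for band in init.bands:
            blo, bhi = band.ages
            mass = (stats.beta.cdf((min(bhi, hi) - lo) / (hi - lo), a, b)
                    - stats.beta.cdf((max(blo, lo) - lo) / (hi - lo), a, b))
            mid = (blo + min(bhi, hi)) / 2
            p_alive = 1.0 - diag.prob_vector(mid)[3]  # not died-before-diagnosis
            expected += mass * p_alive * band.p[0]
        observed = np.mean([t.treated for t in trajectories])
        se = np.sqrt(expected * (1 - expected) / n)
        # band-midpoint approximation of the category mix adds a small bias
        assert abs(observed - expected) < 2 * se + 0.01

    def test_palliative_override_gives_eol_survival(self, params):
        from dlbclsim import load_parameters

        override = {"decision_nodes": {"initial_treatment": {
            "outcomes": ["treated", "not_treated"],
            "bands": [{"ages": [18, 101], "p": [0.0, 1.0], "alphas": [0, 1]}],
        }}}
        palliative = load_parameters(override)
        trajectories = run_cohort(800, palliative, _cfg(seed=7))
        assert not any(t.treated for t in trajectories)
        eol = [t.life_days for t in trajectories
               if t.attrs.diagnostic_category != "died_before_diagnosis"]
        expected_mean = palliative.tte_models["eol_untreated"].mean()
        assert np.mean(eol) == pytest.approx(expected_mean, rel=0.10)
        # palliation for everyone can only shorten mean survival
        base = run_cohort(800, params, _cfg(seed=7))
        assert np.mean(eol) < np.mean([t.life_days for t in base])

    def test_disabling_cure_shortens_survival(self, params):
        import copy

        no_cure = copy.copy(params)
        no_cure.cure_threshold_years = 1e6
        base = run_cohort(600, params, _cfg(seed=8))
        capped = run_cohort(600, no_cure, _cfg(seed=8))
        assert (np.mean([t.life_days for t in capped])
                <= np.mean([t.life_days for t in base]))
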