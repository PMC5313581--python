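"""Time-to-event families, Beta/Dirichlet sampling, AIC, life-table draws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlbclsim import (TTEModel, aic, sample_background_death_age, sample_beta,
                      sample_dirichlet, sample_tte, tte_survival)
from dlbclsim.dists import FAMILIES, tte_quantile
from dlbclsim.params import LifeTable
import pandas as pd

EXAMPLE_MODELS = {
    "exponential": TTEModel("exponential", (0.01,)),
    "weibull": TTEModel("weibull", (1.5, 120.0)),
    "lognormal": TTEModel("lognormal", (4.0, 0.8)),
    "loglogistic": TTEModel("loglogistic", (2.0, 90.0)),
    "gompertz": TTEModel("gompertz", (0.01, 0.002)),
}


class TestSurvival:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_survival_starts_at_one(self, family):
        assert tte_survival(EXAMPLE_MODELS[family], 0.0) == pytest.approx(1.0)

    def test_exponential_closed_form(self):
        model = TTEModel("exponential", (0.01,))
        assert tte_survival(model, 100.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_weibull_shape_one_nests_exponential(self):
        wei = TTEModel("weibull", (1.0, 100.0))
        expo = TTEModel("exponential", (0.01,))
        for t in (0.0, 1.0, 10.0, 100.0, 1000.0):
            assert tte_survival(wei, t) == pytest.approx(tte_survival(expo, t),
                                                         abs=1e-9)

    def test_loglogistic_median_at_scale(self):
        model = TTEModel("loglogistic", (2.5, 64.0))
        assert tte_survival(model, 64.0) == pytest.approx(0.5, abs=1e-9)

    def test_lognormal_median_at_exp_mu(self):
        model = TTEModel("lognormal", (4.0, 0.8))
        assert tte_survival(model, math.exp(4.0)) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_monotone_nonincreasing(self, family):
        t = np.linspace(0, 2000, 400)
        s = tte_survival(EXAMPLE_MODELS[family], t)
        assert np.all(np.diff(s) <= 1e-15)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            tte_survival(EXAMPLE_MODELS["weibull"], -1.0)

    def test_gompertz_negative_shape_rejected(self):
        with pytest.raises(ValueError):
            TTEModel("gompertz", (-0.01, 0.002))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(u=st.floats(min_value=1e-6, max_value=1 - 1e-9),
           family=st.sampled_from(FAMILIES))
    def test_quantile_inverts_survival(self, u, family):
        """Probability-integral transform: S(F^-1(u)) == 1 - u."""
        model = EXAMPLE_MODELS[family]
        t = tte_quantile(model, u)
        assert tte_survival(model, t) == pytest.approx(1.0 - u, rel=1e-7)

    def test_covariate_link_accelerates(self):
        model = TTEModel("weibull", (1.5, 100.0), covariate_links={"age": 0.02})
        young = model.effective_params({"age": -10.0})
        old = model.effective_params({"age": 10.0})
        assert young[1] < old[1]


class TestSampling:
    def test_seed_determinism(self):
        model = EXAMPLE_MODELS["lognormal"]
        assert sample_tte(model, seed=42) == sample_tte(model, seed=42)

    def test_exponential_mean(self):
        model = TTEModel("exponential", (0.01,))
        draws = sample_tte(model, seed=1, size=100_000)
        assert np.mean(draws) == pytest.approx(100.0, rel=0.02)

    def test_lognormal_median(self):
        model = TTEModel("lognormal", (4.0, 0.8))
        draws = sample_tte(model, seed=2, size=100_000)
        assert np.median(draws) == pytest.approx(math.exp(4.0), rel=0.02)

    def test_beta_moments(self):
        rng = np.random.default_rng(3)
        draws = [sample_beta(9, 7, rng=rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(9 / 16, abs=0.01)

    def test_beta_degenerate_and_invalid(self):
        assert sample_beta(0, 6, seed=1) == 0.0
        assert sample_beta(2, 0, seed=1) == 1.0
        with pytest.raises(ValueError):
            sample_beta(0, 0, seed=1)

    def test_dirichlet_simplex_and_zero_components(self):
        rng = np.random.default_rng(4)
        draw = sample_dirichlet([2, 0, 16, 2], rng=rng)
        assert draw.sum() == pytest.approx(1.0, abs=1e-12)
        assert draw[1] == 0.0

    def test_hidden_global_state_refused(self):
        with pytest.raises(ValueError):
            sample_tte(EXAMPLE_MODELS["weibull"])


class TestAIC:
    def test_closed_form(self):
        assert aic(-100.0, 2) == 204.0
        assert aic(0.0, 0) == 0.0

    def test_extra_parameter_costs_two(self):
        assert aic(-50.0, 3) - aic(-50.0, 2) == 2.0


def _toy_table(qx_male):
    rows = []
    for sex in ("male", "female"):
        for age, q in enumerate(qx_male):
            rows.append({"age": age, "sex": sex, "qx": q})
    return LifeTable(pd.DataFrame(rows))


class TestLifeTableDraws:
    def test_certain_death_within_a_year(self):
        table = _toy_table([0.0] * 60 + [1.0] * 41)
        age = sample_background_death_age(table, 60.0, "male", seed=1)
        assert 60.0 < age < 61.0

    def test_survival_to_terminal_age(self):
        table = _toy_table([0.0] * 100 + [1.0])
        age = sample_background_death_age(table, 50.0, "female", seed=2)
        assert 100.0 <= age < 101.0

    def test_expected_remaining_life_matches_table(self, params):
        table = params.life_table
        rng = np.random.default_rng(5)
        draws = [sample_background_death_age(table, 70.0, "male", rng=rng)
                 for _ in range(30_000)]
        expected = table.life_expectancy(70, "male")
        assert np.mean(draws) - 70.0 == pytest.approx(expected, rel=0.02)

    def test_age_outside_table_rejected(self, params):
        with pytest.raises(ValueError):
            sample_background_death_age(params.life_table, 150.0, "male", seed=1)
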