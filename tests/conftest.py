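import pytest

from dlbclsim import EngineConfig, cost_trajectory, default_parameters, run_cohort


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def lifetime_cohort(params):
    """A moderate lifetime-horizon cohort shared across read-only tests."""
    config = EngineConfig(horizon="lifetime", n=600, seed=11)
    trajectories = run_cohort(600, params, config)
    ledgers = [cost_trajectory(t, params) for t in trajectories]
    return trajectories, ledgers
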