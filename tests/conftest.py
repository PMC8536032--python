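import pytest
from hypothesis import HealthCheck, settings

import urbansd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return urbansd.default_parameters()


@pytest.fixture(scope="session")
def clock():
    return urbansd.SimClock()


@pytest.fixture(scope="session")
def scenario_runs(clock):
    """Full 2000-2050 monthly trajectories for the three preset scenarios."""
    return {n: urbansd.simulate(scenario=n, clock=clock) for n in (0, 1, 2)}
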