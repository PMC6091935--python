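import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "rrtvalid",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("rrtvalid")

from rrtvalid import SimulationConfig, default_catalogue, simulate_survey


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def survey_30k():
    """One medium synthetic survey shared across read-only tests."""
    return simulate_survey(SimulationConfig(n=30_000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
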