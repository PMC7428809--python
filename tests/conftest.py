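import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cryptsim.params import SimulationParams

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params() -> SimulationParams:
    """Baseline parameters."""
    return SimulationParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def quiet_params() -> SimulationParams:
    """Small tissue with all mutation processes switched off."""
    return SimulationParams(mutation_rate=0.0, tsg_mutation_rate=0.0,
                            grid_rows=2, grid_cols=2, max_days=500.0)
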