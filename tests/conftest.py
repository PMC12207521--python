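import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from egtlab.repeated_pd import PDParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def pd_params() -> PDParams:
    """Standard repeated-PD study conditions: R=3, S=0, T=4, P=1, delta=0.9."""
    return PDParams(R=3.0, S=0.0, T=4.0, P=1.0, delta=0.9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
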