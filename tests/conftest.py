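import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from omeflux.simcell import SimConfig, Species, straight_cell

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def geometry():
    """Straight 4 um x 0.5 um rod cell."""
    return straight_cell(4.0, 0.5)


@pytest.fixture
def reporter():
    return Species("reporter", d_free=0.02)


@pytest.fixture
def config():
    return SimConfig(rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
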