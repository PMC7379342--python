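import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from artifact.bench import CouplingModel, make_coupling_filters
from artifact.signals import MultichannelSignal

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS = 12000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_pair(rng):
    """Aligned white-noise stimulus/recording pair (dimensionless)."""
    K = 4096
    X = MultichannelSignal(rng.standard_normal((K, 2)), fs=FS)
    Y = MultichannelSignal(rng.standard_normal((K, 2)), fs=FS)
    return X, Y


@pytest.fixture(scope="session")
def siso_coupling():
    """A fixed 40-tap single-pair ground-truth coupling kernel."""
    return make_coupling_filters(1, 1, 40, CouplingModel(kind="random_fir", seed=2), fs=FS)
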