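import numpy as np
import pytest

from nwirecal.geometry import default_phantom
from nwirecal.simulate import NoiseConfig, default_truth_state, make_dataset


@pytest.fixture(scope="session")
def phantom():
    return default_phantom()


@pytest.fixture(scope="session")
def truth_state():
    return default_truth_state()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """30 zero-noise frames, seed 1 — the closure workhorse."""
    return make_dataset(n_frames=30, noise=NoiseConfig.noiseless(), seed=1)


@pytest.fixture(scope="session")
def noisy_dataset():
    """A default-noise dataset reused by detection and solver tests."""
    return make_dataset(n_frames=10, noise=NoiseConfig(), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
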