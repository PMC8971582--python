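import numpy as np
import pytest

from becseg.synthdata import PHANTOM_PRESETS, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless 128x128 core+annulus phantom with its truth mask."""
    return make_phantom(PHANTOM_PRESETS["default"])


@pytest.fixture(scope="session")
def noisy_phantom():
    """128x128 phantom with Gaussian pixel noise sd 0.3, seed 42."""
    return make_phantom(PHANTOM_PRESETS["noisy"])


@pytest.fixture(scope="session")
def small_noisy_phantom():
    """64x64 noisy phantom used where many segmentations are run."""
    return make_phantom(PHANTOM_PRESETS["small-noisy"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
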