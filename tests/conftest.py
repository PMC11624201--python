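import numpy as np
import pytest

from ischclock.io_preprocess import ImageVolume, LesionMask
from ischclock.phantom import PhantomSpec, generate_ncct_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with a programmed 15% relative-intensity deficit
    at 24 h (uptake_rate chosen so uptake * A(24h) = 0.15)."""
    spec = PhantomSpec(true_age=24.0, uptake_rate=0.15 / 3.2188758,
                       noise_sd=0.0, texture_amp=0.0, seed=7)
    vol, mask, age = generate_ncct_phantom(spec)
    return spec, vol, mask, age


@pytest.fixture
def toy_volume():
    """Deterministic 8x8x2 two-texture toy for texture-feature oracles."""
    rng = np.random.default_rng(5)
    data = rng.integers(20, 60, size=(8, 8, 2)).astype(float)
    vol = ImageVolume(data, (1.0, 1.0, 1.0))
    mask = LesionMask(np.ones((8, 8, 2), bool), (1.0, 1.0, 1.0))
    return vol, mask
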