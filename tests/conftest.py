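import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_uint8(rng):
    """A reproducible 8-bit test image with two intensity populations."""
    img = rng.integers(0, 80, size=(48, 48)).astype(np.uint8)
    img[10:20, 10:20] = rng.integers(150, 255, size=(10, 10))
    return img
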