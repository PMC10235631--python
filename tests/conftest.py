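import numpy as np
import pytest

from osteotex.image import GrayImage
from osteotex.synth import fbm_surface


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_image():
    """Linear ramp along columns: a smooth surface with FD 2."""
    x = np.linspace(0.0, 0.8, 128)
    return np.tile(x, (128, 1))


@pytest.fixture
def random_image(rng):
    return rng.uniform(0.0, 1.0, size=(64, 64))


@pytest.fixture
def fbm_half():
    return fbm_surface(128, 0.5, seed=7)


@pytest.fixture
def textured_gray(rng):
    """Mid-gray texture fixture, comfortably inside [0, 1]."""
    pix = 0.5 + 0.15 * rng.standard_normal((128, 128))
    return GrayImage(np.clip(pix, 0.0, 1.0))
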