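import numpy as np
import pytest

from specgp.cube import HyperspectralCube
from specgp.images import GrayscaleImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """8x8x10 random reflectance cube with an all-true ROI."""
    data = rng.random((8, 8, 10))
    wavelengths = np.linspace(400.0, 900.0, 10)
    return HyperspectralCube(data, wavelengths)


@pytest.fixture
def gray(rng):
    """16x16 random grayscale image, all-true ROI."""
    vals = rng.random((16, 16))
    return GrayscaleImage(vals, np.ones((16, 16), dtype=bool))


def make_cube(data, wavelengths=None, mask=None):
    data = np.asarray(data, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(data.shape[2], dtype=float) * 3.0 + 400.0
    return HyperspectralCube(data, wavelengths, mask)
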