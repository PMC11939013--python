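import numpy as np
import pytest

from casdn import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A 32x32 smooth-ish random gray image."""
    from scipy import ndimage as ndi

    img = ndi.gaussian_filter(rng.random((32, 32)), 1.0, mode="reflect")
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)


@pytest.fixture
def disk_image():
    """A bright disk (radius 10) on a flat dark background, 64x64."""
    rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    img = np.where(np.hypot(rr - 32, cc - 32) <= 10, 0.9, 0.1)
    return img.astype(np.float64)


@pytest.fixture
def small_phantom():
    """One 64x64 phantom with a single small lesion and its exact mask."""
    spec = PhantomSpec(height=64, width=64, radius_range=(6.0, 10.0), seed=7)
    return generate_phantom(spec)


def random_mask(rng, shape=(32, 32), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)
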