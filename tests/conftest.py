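import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A 64×64 random RGB tile (uint8)."""
    return rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)


@pytest.fixture
def disk_tile():
    """Dark disk (radius 30) on a light background, RGB uint8."""
    size, r = 128, 30
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= r * r
    img = np.full((size, size, 3), 230, dtype=np.uint8)
    img[mask] = (60, 50, 90)
    return img, mask, r
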