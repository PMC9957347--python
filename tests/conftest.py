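import numpy as np
import pytest

from p2c.synthetic import add_salt_pepper


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_textured_image(seed: int, shape=(64, 64)) -> np.ndarray:
    """A smooth mid-range test image with no 0/255 pixels (clean of impulses)."""
    g = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = 128 + 60 * np.sin(yy / 7.0) * np.cos(xx / 5.0) + g.normal(0, 5, shape)
    return np.clip(img, 1, 254).astype(np.uint8)


def noisy_pair(seed: int, p: float, shape=(64, 64)):
    """(clean, impulse-corrupted) image pair for filter evaluation."""
    clean = make_textured_image(seed, shape)
    noisy = add_salt_pepper(clean, p, np.random.default_rng(seed + 1000))
    return clean, noisy
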