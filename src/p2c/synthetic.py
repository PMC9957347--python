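"""Seeded two-class synthetic data: textured grayscale images and features.

The image generator emulates the statistical properties a desk-scale stand-in
for a private two-class MRI collection needs: a balanced two-class design
(the reference design is 200 images per class), classes distinguished by
blob-texture statistics (blob radius and brightness), intensities confined to
a narrow sub-range so contrast enhancement has something to stretch, and
salt-and-pepper impulse noise at a configurable pixel fraction.  It is a
texture model, not an MRI physics simulator: no bias fields, no Rician noise,
no anatomy.

The feature generator produces two spherical Gaussian classes with means
``+/- delta/2`` along a random unit direction — the classic setting in which
the Bayes error is Phi(-delta/(2*sigma)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BlobClassParams", "ImageGenConfig", "FeatureGenConfig",
           "make_images", "add_salt_pepper", "make_features",
           "null_image_config"]


@dataclass(frozen=True)
class BlobClassParams:
    """Texture statistics for one class's Gaussian blobs."""

    blob_radius_mean: float = 5.0
    blob_radius_sd: float = 1.0
    intensity_mean: float = 0.8
    intensity_sd: float = 0.05
    n_blobs: int = 6

    def __post_init__(self):
        if self.blob_radius_sd < 0 or self.intensity_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.blob_radius_mean <= 0 or self.n_blobs < 1:
            raise ValueError("blob radius and count must be positive")


@dataclass(frozen=True)
class ImageGenConfig:
    """Two-class image generator settings.

    ``contrast_window`` is the 8-bit sub-range the clean image occupies
    (low contrast by construction); ``impulse_noise_fraction`` is the total
    probability a pixel is replaced by salt (255) or pepper (0), split evenly.
    """

    n_per_class: int = 200
    size: tuple[int, int] = (64, 64)
    class_a: BlobClassParams = field(default_factory=lambda: BlobClassParams(
        blob_radius_mean=4.0, blob_radius_sd=0.8, intensity_mean=0.9,
        intensity_sd=0.05, n_blobs=8))
    class_b: BlobClassParams = field(default_factory=lambda: BlobClassParams(
        blob_radius_mean=9.0, blob_radius_sd=1.5, intensity_mean=0.45,
        intensity_sd=0.05, n_blobs=4))
    impulse_noise_fraction: float = 0.1
    contrast_window: tuple[int, int] = (90, 170)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.impulse_noise_fraction <= 0.5:
            raise ValueError("impulse_noise_fraction must be in [0, 0.5]")
        lo, hi = self.contrast_window
        if not 0 <= lo < hi <= 255:
            raise ValueError("contrast_window must be an increasing sub-range of [0, 255]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")


def null_image_config(**kwargs) -> ImageGenConfig:
    """Config with identical class statistics: no signal, 50% Bayes accuracy."""
    params = BlobClassParams(blob_radius_mean=6.0, blob_radius_sd=1.0,
                             intensity_mean=0.7, intensity_sd=0.05, n_blobs=6)
    return ImageGenConfig(class_a=params, class_b=params, **kwargs)


def _render_class_image(rng: np.random.Generator, h: int, w: int,
                        p: BlobClassParams) -> np.ndarray:
    canvas = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(p.n_blobs):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        radius = max(1.0, rng.normal(p.blob_radius_mean, p.blob_radius_sd))
        amp = np.clip(rng.normal(p.intensity_mean, p.intensity_sd), 0.0, 1.0)
        canvas += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * radius ** 2))
    return np.clip(canvas, 0.0, 1.0)


def make_images(cfg: ImageGenConfig = ImageGenConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Generate a balanced two-class image stack.

    Returns ``(images, labels)``: a ``(2*n_per_class, h, w)`` uint8 array and
    an array of string labels ``classA``/``classB``.  Clean intensities lie
    inside ``contrast_window``; impulse noise is applied afterwards.
    Deterministic per seed.
    """
    h, w = cfg.size
    for name, p in (("class_a", cfg.class_a), ("class_b", cfg.class_b)):
        if 2.0 * p.blob_radius_mean > min(h, w):
            raise ValueError(
                f"{name} blob diameter {2 * p.blob_radius_mean:.0f} exceeds the "
                f"{h}x{w} image"
            )
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.contrast_window
    images, labels = [], []
    for label, params in (("classA", cfg.class_a), ("classB", cfg.class_b)):
        for _ in range(cfg.n_per_class):
            canvas = _render_class_image(rng, h, w, params)
            img = np.round(lo + canvas * (hi - lo)).astype(np.uint8)
            img = add_salt_pepper(img, cfg.impulse_noise_fraction, rng)
            images.append(img)
            labels.append(label)
    return np.stack(images), np.asarray(labels)


def add_salt_pepper(image: np.ndarray, p: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Replace each pixel by 255 w.p. p/2 and by 0 w.p. p/2, independently."""
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"impulse fraction must be in [0, 0.5], got {p}")
    out = np.asarray(image).copy()
    if p == 0.0:
        return out
    u = rng.random(out.shape)
    out[u < p / 2.0] = 255
    out[(u >= p / 2.0) & (u < p)] = 0
    return out


@dataclass(frozen=True)
class FeatureGenConfig:
    """Two spherical Gaussian classes separated by ``delta`` along a random axis."""

    n: int = 200
    d: int = 10
    delta: float = 6.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n % 2:
            raise ValueError("n must be even (balanced classes)")
        if self.d < 1 or self.sigma <= 0 or self.delta < 0:
            raise ValueError("invalid feature generator settings")


def make_features(cfg: FeatureGenConfig = FeatureGenConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Balanced Gaussian feature classes with labels in {-1, +1}."""
    rng = np.random.default_rng(cfg.seed)
    e = rng.standard_normal(cfg.d)
    e /= np.linalg.norm(e)
    half = cfg.n // 2
    X = np.vstack([
        -cfg.delta / 2.0 * e + cfg.sigma * rng.standard_normal((half, cfg.d)),
        +cfg.delta / 2.0 * e + cfg.sigma * rng.standard_normal((half, cfg.d)),
    ])
    y = np.concatenate([-np.ones(half), np.ones(half)]).astype(int)
    perm = rng.permutation(cfg.n)
    return X[perm], y[perm]
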