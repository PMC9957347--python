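"""Impulse-noise removal and contrast enhancement for grayscale images.

Two-stage pre-processing used ahead of feature extraction:

1. A *decision-based* adaptive median filter (AMF).  Only pixels whose value
   equals the salt (255) or pepper (0) extreme are treated as corrupted; each
   corrupted pixel is replaced by the median of the *non-extreme* values in the
   smallest centered window (growing from ``initial_window`` up to
   ``max_window``) that contains at least one non-extreme neighbor.  Undamaged
   pixels pass through untouched, which is what distinguishes this filter from
   a plain median filter that degrades clean structure and edges.

2. CLAHE (contrast-limited adaptive histogram equalization).  The image is
   divided into a grid of tiles, each tile's histogram is clipped at a limit
   and the clipped excess redistributed uniformly over all bins, a CDF-based
   intensity mapping is built per tile, and pixels are remapped with bilinear
   interpolation between the four surrounding tile mappings.

All processing happens on the 8-bit scale [0, 255]; float images in [0, 1]
are rescaled in and back out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["AMFConfig", "CLAHEConfig", "adaptive_median_filter", "clahe", "psnr"]


@dataclass(frozen=True)
class AMFConfig:
    """Settings for the decision-based adaptive median filter.

    ``initial_window`` and ``max_window`` are odd window side lengths; the
    window grows (3, 5, 7, ...) while the whole neighborhood is itself
    extreme-valued.  ``salt_value``/``pepper_value`` are the impulse
    intensities on the 8-bit scale.
    """

    initial_window: int = 3
    max_window: int = 7
    salt_value: int = 255
    pepper_value: int = 0


@dataclass(frozen=True)
class CLAHEConfig:
    """CLAHE settings.

    ``clip_limit`` is a *relative* limit: the per-bin clip is
    ``clip_limit * (pixels per tile)``.  ``numpy.inf`` disables clipping, in
    which case a single-tile configuration reduces to plain global histogram
    equalization.
    """

    tiles_y: int = 8
    tiles_x: int = 8
    clip_limit: float = 0.01
    n_bins: int = 256


def _as_u8(image: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return (uint8 view of the image, was_float flag)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {image.shape}")
    if image.dtype.kind == "f":
        lo, hi = float(image.min()), float(image.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError("float images must lie in [0, 1]")
        return np.round(image * 255.0).astype(np.uint8), True
    if image.min() < 0 or image.max() > 255:
        raise ValueError("integer images must lie in [0, 255]")
    return image.astype(np.uint8), False


def _restore(u8: np.ndarray, was_float: bool) -> np.ndarray:
    return u8.astype(np.float64) / 255.0 if was_float else u8


def _check_window(w: int, name: str) -> None:
    if w < 3 or w % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 3, got {w}")


def adaptive_median_filter(image: np.ndarray, cfg: AMFConfig = AMFConfig()) -> np.ndarray:
    """Remove salt-and-pepper impulses, preserving undamaged pixels.

    Pixels equal to ``cfg.salt_value`` or ``cfg.pepper_value`` are replaced by
    the lower median of the non-extreme values in the smallest window (from
    ``cfg.initial_window`` growing to ``cfg.max_window``) that contains any.
    If even the maximal window holds only extremes, the pixel is kept and a
    warning is logged.
    """
    u8, was_float = _as_u8(image)
    h, w = u8.shape
    if h < 3 or w < 3:
        raise ValueError(f"image must be at least 3x3 for filtering, got {h}x{w}")
    _check_window(cfg.initial_window, "initial_window")
    _check_window(cfg.max_window, "max_window")
    if cfg.max_window < cfg.initial_window:
        raise ValueError("max_window must be >= initial_window")
    if cfg.max_window > h:
        raise ValueError(f"max_window {cfg.max_window} exceeds image height {h}")
    if cfg.max_window > w:
        raise ValueError(f"max_window {cfg.max_window} exceeds image width {w}")

    salt, pepper = cfg.salt_value, cfg.pepper_value
    corrupted = (u8 == salt) | (u8 == pepper)
    if not corrupted.any():
        return _restore(u8.copy(), was_float)

    pad = cfg.max_window // 2
    padded = np.pad(u8, pad, mode="reflect")
    out = u8.copy()
    n_stuck = 0
    for i, j in np.argwhere(corrupted):
        pi, pj = i + pad, j + pad
        replaced = False
        for win in range(cfg.initial_window, cfg.max_window + 1, 2):
            r = win // 2
            neigh = padded[pi - r : pi + r + 1, pj - r : pj + r + 1].ravel()
            good = neigh[(neigh != salt) & (neigh != pepper)]
            if good.size:
                # lower-median convention for even counts
                out[i, j] = np.sort(good)[(good.size - 1) // 2]
                replaced = True
                break
        if not replaced:
            n_stuck += 1
    if n_stuck:
        logger.warning(
            "adaptive_median_filter: %d pixel(s) had no non-extreme neighbor "
            "within the maximal %dx%d window and were left unchanged",
            n_stuck, cfg.max_window, cfg.max_window,
        )
    return _restore(out, was_float)


def _tile_mapping(tile: np.ndarray, cfg: CLAHEConfig) -> np.ndarray:
    """Build the clipped-histogram CDF lookup table for one tile."""
    n_bins = cfg.n_bins
    levels = np.floor(tile.astype(np.float64) * n_bins / 256.0).astype(np.intp)
    hist = np.bincount(levels.ravel(), minlength=n_bins).astype(np.float64)
    n_px = tile.size
    identity = np.round(np.arange(n_bins) * 256.0 / n_bins).clip(0, 255)

    if np.count_nonzero(hist) <= 1:
        return identity  # constant tile: equalization is undefined, keep as-is

    if np.isfinite(cfg.clip_limit):
        limit = cfg.clip_limit * n_px
        excess = np.clip(hist - limit, 0.0, None).sum()
        hist = np.minimum(hist, limit)
        hist += excess / n_bins  # uniform redistribution of clipped mass

    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom <= 0:
        return identity
    return np.round((cdf - cdf_min) / denom * 255.0).clip(0, 255)


def clahe(image: np.ndarray, cfg: CLAHEConfig = CLAHEConfig()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile histograms are clipped at ``clip_limit * tile_pixels`` per bin
    with the excess spread uniformly over all bins; the per-tile CDF mappings
    are blended bilinearly at tile boundaries.  Output stays on the input's
    declared intensity scale.
    """
    u8, was_float = _as_u8(image)
    h, w = u8.shape
    ty, tx = cfg.tiles_y, cfg.tiles_x
    if ty < 1 or tx < 1:
        raise ValueError("tile counts must be positive")
    if cfg.n_bins < 2 or cfg.n_bins > 256:
        raise ValueError("n_bins must be in [2, 256]")
    if cfg.clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    if h < ty or w < tx:
        raise ValueError(f"image {h}x{w} smaller than the {ty}x{tx} tile grid")

    tile_h = int(np.ceil(h / ty))
    tile_w = int(np.ceil(w / tx))
    ph, pw = tile_h * ty, tile_w * tx
    padded = np.pad(u8, ((0, ph - h), (0, pw - w)), mode="reflect")

    maps = np.empty((ty, tx, cfg.n_bins))
    for iy in range(ty):
        for ix in range(tx):
            tile = padded[iy * tile_h : (iy + 1) * tile_h, ix * tile_w : (ix + 1) * tile_w]
            maps[iy, ix] = _tile_mapping(tile, cfg)

    # fractional tile coordinates of every pixel, clamped so edge pixels use
    # their nearest tile mapping only
    fy = np.clip((np.arange(h) + 0.5) / tile_h - 0.5, 0, ty - 1)
    fx = np.clip((np.arange(w) + 0.5) / tile_w - 0.5, 0, tx - 1)
    y0 = np.floor(fy).astype(np.intp)
    x0 = np.floor(fx).astype(np.intp)
    y1 = np.minimum(y0 + 1, ty - 1)
    x1 = np.minimum(x0 + 1, tx - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]

    lv = np.floor(u8.astype(np.float64) * cfg.n_bins / 256.0).astype(np.intp)
    m00 = maps[y0[:, None], x0[None, :], lv]
    m01 = maps[y0[:, None], x1[None, :], lv]
    m10 = maps[y1[:, None], x0[None, :], lv]
    m11 = maps[y1[:, None], x1[None, :], lv]
    blended = (1 - wy) * ((1 - wx) * m00 + wx * m01) + wy * ((1 - wx) * m10 + wx * m11)
    out = np.round(blended).clip(0, 255).astype(np.uint8)
    return _restore(out, was_float)


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; ``numpy.inf`` for identical images.

    The peak is 255 for integer images and 1.0 for float images; both inputs
    must share a shape and scale.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if (a.dtype.kind == "f") != (b.dtype.kind == "f"):
        raise ValueError("images must share an intensity scale (both float or both integer)")
    peak = 1.0 if a.dtype.kind == "f" else 255.0
    mse = float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak * peak / mse)
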