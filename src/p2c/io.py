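"""File I/O: PNG/JPEG image directories with CSV manifests, feature CSVs,
and an optional single-slice NIfTI reader."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["read_image_dir", "write_image_dir", "read_features_csv",
           "write_features_csv", "read_nifti_slice"]


def read_image_dir(image_dir, manifest) -> tuple[np.ndarray, np.ndarray]:
    """Load grayscale images listed in a ``filename,label`` CSV manifest."""
    df = pd.read_csv(manifest)
    if not {"filename", "label"} <= set(df.columns):
        raise ValueError("manifest must have 'filename' and 'label' columns")
    root = Path(image_dir)
    images = []
    for fname in df["filename"]:
        img = np.asarray(iio.imread(root / fname))
        if img.ndim == 3:  # collapse RGB(A) to luminance
            img = np.round(img[..., :3].mean(axis=-1)).astype(np.uint8)
        images.append(img)
    return np.stack(images), df["label"].to_numpy()


def write_image_dir(image_dir, images, labels) -> Path:
    """Write PNGs plus a ``labels.csv`` manifest; returns the manifest path."""
    root = Path(image_dir)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(images, labels)):
        fname = f"img_{i:05d}.png"
        iio.imwrite(root / fname, np.asarray(img, dtype=np.uint8))
        rows.append({"filename": fname, "label": label})
    manifest = root / "labels.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_features_csv(path, X: np.ndarray, y: np.ndarray) -> None:
    """Feature matrix + label column as headed CSV (f0..f{d-1}, label)."""
    X = np.atleast_2d(np.asarray(X))
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["label"] = np.asarray(y)
    df.to_csv(path, index=False)


def read_features_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature CSV must contain a 'label' column")
    y = df.pop("label").to_numpy()
    return df.to_numpy(dtype=np.float64), y


def read_nifti_slice(path, slice_index: int) -> np.ndarray:
    """One axial slice of a .nii/.nii.gz volume, rescaled to uint8 [0, 255]."""
    import nibabel as nib  # optional dependency

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim < 3:
        raise ValueError("NIfTI volume must be at least 3D")
    if not 0 <= slice_index < vol.shape[2]:
        raise ValueError(f"slice {slice_index} out of range [0, {vol.shape[2]})")
    sl = vol[:, :, slice_index].astype(np.float64)
    lo, hi = sl.min(), sl.max()
    if hi > lo:
        sl = (sl - lo) / (hi - lo) * 255.0
    else:
        sl = np.zeros_like(sl)
    return np.round(sl).astype(np.uint8)
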