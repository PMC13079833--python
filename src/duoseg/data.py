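"""Dataset reading, resizing and target encoding.

Supports paired PNG files (8-bit grayscale image + integer label map) and
NIfTI volumes decomposed into 2-D axial slices.  Images are normalized to
[0, 1] by per-image min–max (a constant image maps to all zeros); labels are
passed through unchanged as integers.  The coordinate convention is
row-major, origin at the top-left, 0-based.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, ShapeError

__all__ = ["load_pair", "resize_pair", "one_hot", "load_manifest"]


def _minmax(img: np.ndarray) -> np.ndarray:
    img = img.astype(np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _read_image(path: Path, slice_index: int | None) -> np.ndarray:
    if path.suffix == ".png":
        return np.asarray(Image.open(path).convert("F"))
    if path.name.endswith((".nii", ".nii.gz")):
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 2:
            return np.asarray(vol, dtype=np.float32)
        if slice_index is None:
            raise ConfigurationError(f"{path.name} is a volume; a slice index is required")
        if not 0 <= slice_index < vol.shape[-1]:
            raise IndexError(
                f"slice index {slice_index} out of range for volume with "
                f"{vol.shape[-1]} slices"
            )
        return np.asarray(vol[..., slice_index], dtype=np.float32)
    raise ConfigurationError(f"unsupported image format: {path.name}")


def load_pair(
    image_path: str | Path,
    label_path: str | Path,
    slice_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Load an (image, labels) pair; image min–max-normalized to [0, 1]."""
    image_path, label_path = Path(image_path), Path(label_path)
    for p in (image_path, label_path):
        if not p.exists():
            raise FileNotFoundError(f"no such file: {p}")
    image = _minmax(_read_image(image_path, slice_index))
    raw = _read_image(label_path, slice_index)
    labels = np.rint(raw).astype(np.int64)
    if not np.allclose(raw, labels, atol=1e-6):
        raise ValueError(f"label map {label_path.name} contains non-integer values")
    if image.shape != labels.shape:
        raise ShapeError(
            f"image shape {image.shape} != label shape {labels.shape}"
        )
    return image, labels


def resize_pair(
    image: np.ndarray, labels: np.ndarray, target_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resize to (target, target): image bilinearly, labels nearest-neighbour.

    Nearest-neighbour label resizing can only preserve or shrink the label
    set, never invent new labels.
    """
    if target_size % 32:
        raise ConfigurationError(f"target size {target_size} not divisible by 32")
    img = _sk_resize(
        np.asarray(image, dtype=np.float32),
        (target_size, target_size),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    ).astype(np.float32)
    lab = _sk_resize(
        np.asarray(labels),
        (target_size, target_size),
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    ).astype(np.asarray(labels).dtype)
    return img, lab


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(K, H, W) indicator encoding; channels sum to 1 at every pixel."""
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() >= num_classes:
        raise ValueError(
            f"labels outside [0, {num_classes}): found {int(lab.min())}..{int(lab.max())}"
        )
    out = np.zeros((num_classes,) + lab.shape, dtype=np.float32)
    for k in range(num_classes):
        out[k] = lab == k
    return out


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read a tab-separated dataset manifest and verify the files exist.

    If a ``group`` column is present (e.g. subject ids for subject-wise
    cross-validation), no group may straddle two splits — slices of one
    subject must never appear in both train and test.
    """
    path = Path(manifest_path)
    df = pd.read_csv(path, sep="\t")
    for col in ("image", "label", "split"):
        if col not in df.columns:
            raise ConfigurationError(f"manifest lacks required column {col!r}")
    base = path.parent
    for _, row in df.iterrows():
        for col in ("image", "label"):
            if not (base / row[col]).exists():
                raise FileNotFoundError(f"manifest references missing file {row[col]}")
    if "group" in df.columns:
        splits_per_group = df.groupby("group")["split"].nunique()
        bad = splits_per_group[splits_per_group > 1]
        if len(bad):
            raise ConfigurationError(
                f"group(s) {sorted(bad.index.tolist())} appear in more than one split"
            )
    return df
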