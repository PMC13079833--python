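"""Segmentation metrics: Dice overlap and (95th-percentile) Hausdorff distance.

Conventions, stated once and used everywhere:

* Dice of two empty masks is 1.0 (perfect agreement on absence).
* Hausdorff distances are undefined when either mask is empty; such cases
  carry a not-applicable sentinel (``nan``) and are excluded from means
  rather than counted as 0 — batch evaluation never raises on them.
* Class means are over *foreground* classes only, and a class absent from
  both prediction and ground truth is excluded from every mean.
* Distances are in pixels unless a physical pixel ``spacing`` is supplied.

The 95th-percentile variant takes the 95th percentile of each directed
boundary-distance distribution before the final max of the two directions,
so HD95 <= HD always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = ["CaseMetrics", "dice_coefficient", "hausdorff_distance", "evaluate_case"]

NOT_APPLICABLE = float("nan")


def _as_bool(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    return arr.astype(bool)


def dice_coefficient(pred_mask, gt_mask) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = _as_bool(pred_mask, "pred")
    b = _as_bool(gt_mask, "gt")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary pixels (pixels of the mask with a neighbour
    outside it; the image border counts as outside)."""
    edge = mask & ~binary_erosion(mask, border_value=0)
    return np.argwhere(edge)


def hausdorff_distance(
    pred_mask,
    gt_mask,
    percentile: float = 100,
    spacing: tuple[float, float] | None = None,
) -> float:
    """Symmetric (percentile-)Hausdorff distance between mask boundaries.

    Returns ``nan`` (not applicable) when either mask is empty.
    """
    a = _as_bool(pred_mask, "pred")
    b = _as_bool(gt_mask, "gt")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        return NOT_APPLICABLE
    pa = _boundary_points(a).astype(float)
    pb = _boundary_points(b).astype(float)
    if spacing is not None:
        pa = pa * np.asarray(spacing, dtype=float)
        pb = pb * np.asarray(spacing, dtype=float)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if percentile >= 100:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


@dataclass
class CaseMetrics:
    """Per-class and aggregated metrics for one image (foreground classes).

    Arrays are indexed by foreground class ``k - 1`` for ``k = 1..K-1``;
    not-applicable entries are ``nan`` and excluded from the means.
    """

    dice: np.ndarray
    hausdorff: np.ndarray
    hausdorff95: np.ndarray
    applicable: np.ndarray = field(repr=False)

    @property
    def mean_dice(self) -> float:
        vals = self.dice[self.applicable]
        return float(vals.mean()) if vals.size else NOT_APPLICABLE

    @property
    def mean_hausdorff(self) -> float:
        vals = self.hausdorff[~np.isnan(self.hausdorff)]
        return float(vals.mean()) if vals.size else NOT_APPLICABLE

    @property
    def mean_hausdorff95(self) -> float:
        vals = self.hausdorff95[~np.isnan(self.hausdorff95)]
        return float(vals.mean()) if vals.size else NOT_APPLICABLE


def evaluate_case(
    pred_labels,
    gt_labels,
    num_classes: int,
    spacing: tuple[float, float] | None = None,
) -> CaseMetrics:
    """Per-class Dice / Hausdorff for an integer label map pair.

    Labels must lie in ``[0, num_classes)``; class 0 is background and is not
    scored.  A class present in neither map is marked not-applicable.
    """
    pred = np.asarray(pred_labels)
    gt = np.asarray(gt_labels)
    if pred.shape != gt.shape:
        raise ValueError(f"label map shapes differ: {pred.shape} vs {gt.shape}")
    for name, arr in (("prediction", pred), ("ground truth", gt)):
        bad = arr[(arr < 0) | (arr >= num_classes)]
        if bad.size:
            raise ValueError(
                f"{name} contains out-of-range label {int(bad.flat[0])} "
                f"(valid range is 0..{num_classes - 1})"
            )
    kf = num_classes - 1
    dice = np.full(kf, NOT_APPLICABLE)
    hd = np.full(kf, NOT_APPLICABLE)
    hd95 = np.full(kf, NOT_APPLICABLE)
    applicable = np.zeros(kf, dtype=bool)
    for k in range(1, num_classes):
        pm = pred == k
        gm = gt == k
        if not pm.any() and not gm.any():
            continue  # absent from both: not applicable, excluded from means
        applicable[k - 1] = True
        dice[k - 1] = dice_coefficient(pm, gm)
        hd[k - 1] = hausdorff_distance(pm, gm, 100, spacing)
        hd95[k - 1] = hausdorff_distance(pm, gm, 95, spacing)
    return CaseMetrics(dice=dice, hausdorff=hd, hausdorff95=hd95, applicable=applicable)
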