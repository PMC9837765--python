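"""Per-frame segmentation metrics: Dice, Sensitivity, Balanced Accuracy,
Rand Error Index, 95% Hausdorff distance, Average Surface Distance.

Overlap metrics come from the pixel confusion counts; the Rand error index
is computed in closed form from the 2x2 joint contingency (validated in the
test suite against an all-pairs enumeration); surface distances use exact
Euclidean distance transforms over 4-connected boundary pixels, with the
frame border treated as background.

Distances are reported in pixels by default; pass a physical ``spacing``
(mm per axis) for millimetre units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

METRICS = ("Sensitivity", "BA", "DS", "HD", "ASD", "REI")

#: Direction of improvement per metric (True = higher is better).
HIGHER_IS_BETTER = {
    "Sensitivity": True, "BA": True, "DS": True,
    "HD": False, "ASD": False, "REI": False,
}


class EmptyMaskError(ValueError):
    """A surface-distance operand has no foreground pixels."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(c: ConfusionCounts) -> dict[str, float]:
    """DS, Sensitivity and BA from confusion counts.

    Both masks empty -> DS = 1 and Sensitivity/BA are omitted (batch runs
    on phantoms hit empty slices).  Empty ground truth against a non-empty
    prediction leaves Sensitivity undefined and raises.
    """
    out: dict[str, float] = {}
    gt_empty = (c.tp + c.fn) == 0
    pred_empty = (c.tp + c.fp) == 0
    if gt_empty and pred_empty:
        return {"DS": 1.0}
    if gt_empty:
        raise ValueError("Sensitivity undefined: empty ground truth, non-empty prediction")
    out["DS"] = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    sens = c.tp / (c.tp + c.fn)
    out["Sensitivity"] = sens
    if c.tn + c.fp > 0:
        out["BA"] = (sens + c.tn / (c.tn + c.fp)) / 2
    return out


def rand_error_index(pred: np.ndarray, gt: np.ndarray) -> float:
    """1 - Rand index over all unordered pixel pairs, in closed form.

    The Rand index is the fraction of pixel pairs on which the two binary
    labelings agree (placed together in both, or apart in both); the
    closed form uses only the 2x2 contingency of the two labelings and is
    O(n) in the pixel count.
    """
    c = confusion_counts(pred, gt)
    n = c.total
    if n < 2:
        raise ValueError("rand_error_index needs >= 2 pixels")

    def comb2(x: np.ndarray | int) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    nij = np.array([[c.tn, c.fn], [c.fp, c.tp]], dtype=float)  # rows: pred, cols: gt
    sum_ij = comb2(nij).sum()
    sum_a = comb2(nij.sum(axis=1)).sum()  # pred marginals
    sum_b = comb2(nij.sum(axis=0)).sum()  # gt marginals
    total = comb2(n)
    agreements = total + 2 * sum_ij - sum_a - sum_b
    return float(1.0 - agreements / total)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor.

    The frame border counts as background, so foreground touching the
    border is part of the boundary.
    """
    mask = _as_binary(mask, "mask")
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~interior


def surface_distances(
    pred: np.ndarray,
    gt: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> dict[str, float]:
    """95% Hausdorff distance and average surface distance between two masks.

    Directed distances are Euclidean nearest-boundary distances (exact
    distance transform, anisotropic ``spacing`` honored); the two directed
    sets are pooled, HD95 is the 95th percentile of the pooled set
    (linear interpolation) and ASD its mean.  Empty masks raise
    :class:`EmptyMaskError` rather than returning infinity.
    """
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if not pred.any() or not gt.any():
        raise EmptyMaskError("surface distances undefined for empty masks")
    pb = boundary_pixels(pred)
    gb = boundary_pixels(gt)
    dt_to_g = ndimage.distance_transform_edt(~gb, sampling=spacing)
    dt_to_p = ndimage.distance_transform_edt(~pb, sampling=spacing)
    pooled = np.concatenate([dt_to_g[pb], dt_to_p[gb]])
    return {
        "HD": float(np.percentile(pooled, 95)),
        "ASD": float(pooled.mean()),
    }


def score_frame(
    pred: np.ndarray,
    gt: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> dict[str, float]:
    """All six metrics for one frame pair; distance metrics are omitted
    when either mask is empty."""
    out = overlap_metrics(confusion_counts(pred, gt))
    out["REI"] = rand_error_index(pred, gt)
    try:
        out.update(surface_distances(pred, gt, spacing))
    except EmptyMaskError:
        pass
    return out


def score_stack(
    preds: Iterable[np.ndarray],
    gts: Iterable[np.ndarray],
    spacing: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Long-format per-frame records (frame_id, metric, value)."""
    rows = []
    for k, (p, g) in enumerate(zip(preds, gts)):
        for metric, value in score_frame(p, g, spacing).items():
            rows.append({"frame_id": k, "metric": metric, "value": value})
    return pd.DataFrame(rows, columns=["frame_id", "metric", "value"])
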