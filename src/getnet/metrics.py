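"""Segmentation evaluation metrics and the soft Dice training loss.

Per evaluated region (WT, TC, ET) a case is scored with:

* Dice = 2TP / (2TP + FP + FN) — overlap between prediction and truth;
* sensitivity = TP / (TP + FN), specificity = TN / (TN + FP);
* HD95 — the 95th-percentile symmetric Hausdorff distance between the
  two segmentation boundaries, in millimetres.

Empty-mask conventions (the public leaderboards differ; these are fixed
here for reproducibility): when prediction and truth are both empty,
Dice is 1; when a ratio's denominator is zero (e.g. sensitivity with an
empty truth) the value is reported as ``nan`` (missing); HD95 with
either boundary empty is the ``nan`` sentinel, never a silent zero.

Boundary definition for HD95: mask voxels with at least one background
face-neighbour (6-connectivity, volume border counts as background).
Directed distances are taken between boundary voxel centres scaled by
the voxel spacing; HD95 is the maximum of the two directed 95th
percentiles (linear-interpolation percentile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from ._tensor import Tensor
from .bratsio import REGION_NAMES, RegionMask, SegmentationMask, labels_to_regions
from .errors import ValidationError

__all__ = [
    "ConfusionCounts",
    "RegionMetrics",
    "MetricReport",
    "confusion",
    "dice",
    "sensitivity",
    "specificity",
    "hd95",
    "soft_dice_loss",
    "evaluate_case",
    "reports_to_dataframe",
    "SOFT_DICE_EPS",
]

SOFT_DICE_EPS = 1e-5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Voxel-wise confusion counts of two binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN); 1 when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); nan when the truth is empty."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else float("nan")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); nan when there are no true negatives or false positives."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else float("nan")


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a background face-neighbour (6-connectivity)."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def hd95(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """95th-percentile symmetric Hausdorff distance between boundaries (mm).

    Returns ``nan`` when either mask is empty.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not pred.any() or not truth.any():
        return float("nan")
    sp = np.asarray(spacing, dtype=float)
    pts_p = np.argwhere(_boundary(pred)) * sp
    pts_t = np.argwhere(_boundary(truth)) * sp
    d_pt = cKDTree(pts_t).query(pts_p)[0]
    d_tp = cKDTree(pts_p).query(pts_t)[0]
    return float(max(np.percentile(d_pt, 95.0), np.percentile(d_tp, 95.0)))


def soft_dice_loss(probs, targets, eps: float = SOFT_DICE_EPS):
    """Mean soft Dice loss over the three region channels.

    ``probs`` holds per-voxel region probabilities (3, D, H, W) in
    [0, 1]; ``targets`` the binary region masks.  When ``probs`` is a
    :class:`~getnet._tensor.Tensor` the result is differentiable.
    """
    if isinstance(targets, RegionMask):
        targets = targets.regions
    t = np.asarray(targets, dtype=np.float64)
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {t.shape}")
    n_regions = t.shape[0]
    pf = p.reshape(n_regions, -1)
    tf = Tensor(t.reshape(n_regions, -1))
    inter = (pf * tf).sum(axis=1)
    denom = pf.sum(axis=1) + tf.sum(axis=1)
    per_region = (inter * 2.0 + eps) / (denom + eps)
    loss = 1.0 - per_region.mean()
    return loss if isinstance(probs, Tensor) else loss.item()


@dataclass(frozen=True)
class RegionMetrics:
    dice: float
    hd95: float  # nan sentinel when a boundary set is empty
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class MetricReport:
    """Per-region metrics for one case, keyed WT / TC / ET."""

    regions: dict[str, RegionMetrics]

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for name, m in self.regions.items():
            for metric in ("dice", "hd95", "sensitivity", "specificity"):
                row[f"{metric}_{name}"] = getattr(m, metric)
        return row


def evaluate_case(
    pred: SegmentationMask,
    truth: SegmentationMask,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> MetricReport:
    """Score one predicted label volume against the reference."""
    if pred.labels.shape != truth.labels.shape:
        raise ValidationError(
            f"grid mismatch: {pred.labels.shape} vs {truth.labels.shape}"
        )
    pred_regions = labels_to_regions(pred).regions
    truth_regions = labels_to_regions(truth).regions
    out = {}
    for i, name in enumerate(REGION_NAMES):
        c = confusion(pred_regions[i], truth_regions[i])
        out[name] = RegionMetrics(
            dice=dice(c),
            hd95=hd95(pred_regions[i], truth_regions[i], spacing),
            sensitivity=sensitivity(c),
            specificity=specificity(c),
        )
    return MetricReport(out)


def reports_to_dataframe(reports: dict[str, MetricReport]) -> pd.DataFrame:
    """Per-case rows plus a cohort-mean row (nan-aware means)."""
    df = pd.DataFrame({cid: r.as_row() for cid, r in reports.items()}).T
    df.index.name = "case"
    df.loc["mean"] = df.mean(skipna=True)
    return df
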