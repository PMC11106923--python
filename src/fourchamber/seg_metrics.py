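"""Multi-class segmentation overlap metrics: Dice, IoU, mDice, mIoU.

Per class i with predicted mask x_i and ground truth y_i:

    Dice_i = 2|x_i ∩ y_i| / (|x_i| + |y_i|)
    IoU_i  = |x_i ∩ y_i| / |x_i ∪ y_i|

mDice and mIoU average over the n *scored* classes.  A class empty in both
prediction and truth carries no information and is excluded from the mean
(relevant for structures that are variably visible, e.g. ribs); a class empty
in exactly one of the two scores 0.  Background is never scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_io import BinaryMask, LabelMap

__all__ = ["SegmentationScores", "dice", "iou", "evaluate"]


@dataclass(frozen=True)
class SegmentationScores:
    """Per-label (dice, iou) pairs plus their class means.

    ``per_label`` maps label name -> (dice, iou); labels excluded from scoring
    (empty in both maps) map to None.
    """

    per_label: dict[str, tuple[float, float] | None]
    mdice: float
    miou: float
    n_classes_scored: int


def _check_shapes(pred: BinaryMask, truth: BinaryMask) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")


def dice(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice coefficient 2|x∩y|/(|x|+|y|); 1.0 when both masks are empty."""
    _check_shapes(pred, truth)
    total = pred.count() + truth.count()
    if total == 0:
        return 1.0
    inter = int(np.logical_and(pred.grid, truth.grid).sum())
    return 2.0 * inter / total


def iou(pred: BinaryMask, truth: BinaryMask) -> float:
    """Jaccard index |X∩Y|/|X∪Y|; 1.0 when both masks are empty."""
    _check_shapes(pred, truth)
    union = int(np.logical_or(pred.grid, truth.grid).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(pred.grid, truth.grid).sum())
    return inter / union


def evaluate(
    pred: LabelMap, truth: LabelMap, labels: list[str] | None = None
) -> SegmentationScores:
    """Score a predicted label map against ground truth over named labels.

    ``labels`` defaults to all 15 scheme labels.  Classes empty in both maps
    are excluded from mDice/mIoU and reported as None.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.scheme.entries != truth.scheme.entries:
        raise ValueError("prediction and truth use different label schemes")
    if labels is None:
        labels = list(pred.scheme.names)
    if not labels:
        raise ValueError("label list must not be empty")

    # joint histogram over (pred, truth) ids gives all intersections at once
    n_ids = max(pred.scheme.ids) + 1
    joint = np.bincount(
        (pred.grid.astype(np.int64) * n_ids + truth.grid.astype(np.int64)).ravel(),
        minlength=n_ids * n_ids,
    ).reshape(n_ids, n_ids)
    pred_counts = joint.sum(axis=1)
    truth_counts = joint.sum(axis=0)

    per_label: dict[str, tuple[float, float] | None] = {}
    dices, ious = [], []
    for name in labels:
        lid = pred.scheme.id_of(name)
        p, t = int(pred_counts[lid]), int(truth_counts[lid])
        if p == 0 and t == 0:
            per_label[name] = None
            continue
        inter = int(joint[lid, lid])
        d = 2.0 * inter / (p + t)
        j = inter / (p + t - inter)
        per_label[name] = (d, j)
        dices.append(d)
        ious.append(j)
    if not dices:
        raise ValueError("no scorable labels: all requested labels empty in both maps")
    return SegmentationScores(
        per_label=per_label,
        mdice=float(np.mean(dices)),
        miou=float(np.mean(ious)),
        n_classes_scored=len(dices),
    )
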