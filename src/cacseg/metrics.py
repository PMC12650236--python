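"""Voxel-overlap segmentation metrics.

Dice = 2TP / (2TP + FP + FN), sensitivity (recall) = TP / (TP + FN),
specificity = TN / (TN + FP), all from an exact voxel confusion census.
Degenerate denominators follow explicit conventions: with both masks
empty, Dice and sensitivity are 1 (vacuous success); with an empty
reference and a non-empty prediction, Dice is 0 and sensitivity is
reported as 1 with ``degenerate=True``. Volume-level numbers pool counts
across slices (micro-average); a per-slice macro-average is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SegMetrics", "confusion_counts", "compute_metrics", "macro_average"]


@dataclass(frozen=True)
class SegMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    dice: float
    sensitivity: float
    specificity: float
    degenerate: bool = False

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    """Exact (TP, FP, TN, FN) voxel counts for two same-shape binary masks."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int(pred.size - tp - fp - fn)
    return tp, fp, tn, fn


def compute_metrics(pred: np.ndarray, gt: np.ndarray) -> SegMetrics:
    tp, fp, tn, fn = confusion_counts(pred, gt)
    degenerate = False
    if tp + fp + fn == 0:           # both masks empty
        dice = 1.0
    else:
        dice = 2.0 * tp / (2.0 * tp + fp + fn)
    if tp + fn == 0:                # empty reference
        sensitivity = 1.0
        degenerate = fp > 0
    else:
        sensitivity = tp / (tp + fn)
    specificity = 1.0 if tn + fp == 0 else tn / (tn + fp)
    return SegMetrics(tp=tp, fp=fp, tn=tn, fn=fn, dice=dice,
                      sensitivity=sensitivity, specificity=specificity,
                      degenerate=degenerate)


def macro_average(pred: np.ndarray, gt: np.ndarray) -> SegMetrics:
    """Mean of per-slice metrics over the leading axis."""
    per = [compute_metrics(p, g) for p, g in zip(pred, gt)]
    tp, fp, tn, fn = confusion_counts(pred, gt)
    return SegMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        dice=float(np.mean([m.dice for m in per])),
        sensitivity=float(np.mean([m.sensitivity for m in per])),
        specificity=float(np.mean([m.specificity for m in per])),
        degenerate=any(m.degenerate for m in per),
    )
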