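"""Evaluation metrics: classification accuracy and mean intersection-over-union.

mIoU is computed from confusion counts aggregated over every pixel of every
map in the dataset (dataset-level aggregation), then averaged over classes
with equal weight.  A class absent from both prediction and truth
(TP+FP+FN = 0) is excluded from the mean to avoid 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "accuracy", "mean_iou"]


@dataclass
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative accumulators."""

    n_classes: int
    tp: np.ndarray = field(default=None)
    fp: np.ndarray = field(default=None)
    fn: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.n_classes, dtype=np.int64))

    def update(self, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        if pred.shape != truth.shape:
            raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
        if pred.size and (pred.max() >= self.n_classes or truth.max() >= self.n_classes):
            raise ValueError("label >= number of classes")
        if pred.size and (pred.min() < 0 or truth.min() < 0):
            raise ValueError("negative label")
        for c in range(self.n_classes):
            p = pred == c
            t = truth == c
            self.tp[c] += int(np.sum(p & t))
            self.fp[c] += int(np.sum(p & ~t))
            self.fn[c] += int(np.sum(~p & t))
        return self

    def iou(self) -> np.ndarray:
        """Per-class IoU; NaN for classes absent from both prediction and truth."""
        denom = self.tp + self.fp + self.fn
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, self.tp / np.maximum(denom, 1), np.nan)

    def mean_iou(self) -> float:
        vals = self.iou()
        present = ~np.isnan(vals)
        if not present.any():
            raise ValueError("no class present in prediction or truth")
        return float(vals[present].mean())


def accuracy(predictions, truth) -> float:
    """Percentage of correctly classified samples (0..100)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("length mismatch")
    if predictions.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(predictions == truth))


def mean_iou(pred_maps, true_maps, n_classes: int) -> float:
    """Dataset-aggregated mean IoU over class-index maps."""
    counts = ConfusionCounts(n_classes)
    pred_maps = [pred_maps] if isinstance(pred_maps, np.ndarray) and np.ndim(pred_maps) == 2 else pred_maps
    true_maps = [true_maps] if isinstance(true_maps, np.ndarray) and np.ndim(true_maps) == 2 else true_maps
    if len(pred_maps) != len(true_maps):
        raise ValueError("different numbers of prediction and truth maps")
    for p, t in zip(pred_maps, true_maps):
        counts.update(np.asarray(p), np.asarray(t))
    return counts.mean_iou()
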