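"""Confusion-based metrics at patch and pixel granularity.

TPR = TP/(TP+FN), ACC = (TP+TN)/(TP+TN+FP+FN), Dice = 2TP/(2TP+FP+FN), and
the ground-truth cover ratio |truth ∩ mask| / |truth| (the fraction of
annotated positive pixels inside the predicted mask).  Metrics with a zero
denominator are undefined (None), never 0.

Pixel-level metrics treat a predicted patch footprint as uniformly positive
and unannotated pixels as negative ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    granularity: Literal["patch", "pixel"] = "pixel"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if other.granularity != self.granularity:
            raise ValueError("cannot pool counts of different granularity")
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.granularity,
        )


def confusion_counts(
    predicted: np.ndarray,
    truth: np.ndarray,
    granularity: Literal["patch", "pixel"] = "pixel",
) -> ConfusionCounts:
    """Exact integer confusion counts from aligned boolean arrays."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"misaligned inputs: predicted {predicted.shape} vs truth {truth.shape}"
        )
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())
    return ConfusionCounts(tp, fp, tn, fn, granularity)


def metrics(counts: ConfusionCounts) -> dict[str, Optional[float]]:
    """TPR, ACC and Dice from confusion counts; None on zero denominators."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    return {
        "tpr": tp / (tp + fn) if tp + fn else None,
        "acc": (tp + tn) / counts.total if counts.total else None,
        "dice": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None,
    }


def gt_cover(mask: np.ndarray, truth: np.ndarray) -> Optional[float]:
    """Fraction of ground-truth positive pixels covered by the mask."""
    mask = np.asarray(mask, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError(f"misaligned rasters: {mask.shape} vs {truth.shape}")
    n_truth = int(truth.sum())
    if n_truth == 0:
        return None
    return int((mask & truth).sum()) / n_truth
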