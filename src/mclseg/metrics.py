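"""Pixel-level evaluation metrics for binary tumor/normal segmentation.

Tumor is the positive class.  With pixel counts TP, TN, FP, FN:

    OA   = (TP + TN) / (TP + TN + FP + FN)
    AA   = (TP/(TP+FN) + TN/(FP+TN)) / 2
    MIoU = (TP/(TP+FP+FN) + TN/(FP+FN+TN)) / 2
    Dice = 2*TP / (2*TP + FP + FN)

Evaluation pools the confusion counts over all test pixels (micro average)
for the headline numbers and also reports per-scene values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "overall_accuracy",
    "average_accuracy",
    "mean_iou",
    "dice_coefficient",
    "metrics_row",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN between two binary masks (tumor = 1 = positive)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        bad = np.setdiff1d(np.unique(arr), [0, 1])
        if bad.size:
            raise ValueError(f"{name} mask contains non-binary values {bad.tolist()}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def overall_accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("no pixels to evaluate")
    return (c.tp + c.tn) / c.total


def _recall(hit: int, miss: int, false_assigned: int, cls: str) -> float:
    """Class recall; an absent truth class scores 1 unless pixels were falsely
    assigned to it, in which case 0 (degenerate-class convention, logged)."""
    if hit + miss == 0:
        value = 1.0 if false_assigned == 0 else 0.0
        logger.warning(
            "class %r absent from ground truth; recall defined as %g", cls, value
        )
        return value
    return hit / (hit + miss)


def average_accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("no pixels to evaluate")
    tumor = _recall(c.tp, c.fn, c.fp, "tumor")
    normal = _recall(c.tn, c.fp, c.fn, "normal")
    return 0.5 * (tumor + normal)


def mean_iou(c: ConfusionCounts) -> float:
    den_t = c.tp + c.fp + c.fn
    den_n = c.fp + c.fn + c.tn
    if den_t == 0 and den_n == 0:
        raise ValueError("empty image: both IoU denominators are zero")
    iou_t = c.tp / den_t if den_t else 1.0
    iou_n = c.tn / den_n if den_n else 1.0
    if den_t == 0 or den_n == 0:
        logger.warning("a class is entirely absent; its IoU defined as 1")
    return 0.5 * (iou_t + iou_n)


def dice_coefficient(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        logger.warning("no tumor in prediction or truth; Dice defined as 1")
        return 1.0
    return 2 * c.tp / den


def metrics_row(c: ConfusionCounts) -> dict[str, float]:
    """All four metrics of one counts object as a plain dict."""
    return {
        "OA": overall_accuracy(c),
        "AA": average_accuracy(c),
        "Dice": dice_coefficient(c),
        "MIoU": mean_iou(c),
    }


def evaluate(
    model,
    manifest,
    pca_model,
    *,
    split: str = "test",
    tile_size: int | None = None,
    overlap: float = 0.5,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Segment every scene of a manifest split and score it against its mask.

    Inference uses the primary decoder only.  Returns a DataFrame with one row
    per scene plus a final POOLED row whose counts are summed over all pixels
    before the metrics are computed; optionally written to ``out_csv``.
    """
    from . import hsi_io
    from .training import predict

    entries = [e for e in manifest.entries if e.split == split]
    if not entries:
        raise ValueError(f"manifest has no {split!r} entries")
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for entry in entries:
        if entry.mask_path is None:
            raise ValueError(f"scene {entry.scene_id!r} has no mask to score against")
        cube = hsi_io.read_cube(manifest.resolve(entry.cube_path))
        truth = hsi_io.read_mask(manifest.resolve(entry.mask_path))
        pred, _ = predict(model, cube, pca_model, tile_size=tile_size, overlap=overlap)
        c = confusion_counts(pred.data, truth.data)
        pooled = pooled + c
        rows.append({"scene_id": entry.scene_id, **metrics_row(c)})
    rows.append({"scene_id": "POOLED", **metrics_row(pooled)})
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
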