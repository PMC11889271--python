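"""Pixel-level segmentation metrics.

Each predicted/true mask pair is reduced to four confusion counts — TP
(lesion pixels found), FP (skin called lesion), FN (lesion missed), TN (skin
called skin) — from which the five standard measures are computed:

    sensitivity  = TP / (TP + FN)
    specificity  = TN / (TN + FP)
    accuracy     = (TP + TN) / (TP + TN + FP + FN)
    Dice         = 2 TP / (2 TP + FN + FP)
    Jaccard      = TP / (TP + FN + FP)

Dice and Jaccard obey DC = 2 JI / (1 + JI) exactly.  Degenerate denominators
(no positives in either mask) are defined as 1.0 — a prediction that finds
nothing when there is nothing to find is perfect; a positive-free truth with
false positives yields sensitivity 0 with a logged warning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion_counts", "accuracy",
    "sensitivity", "specificity", "jaccard", "dice", "compute_metrics",
    "evaluate_dataset", "write_report_csv",
]

METRIC_NAMES = ("acc", "sen", "spe", "ji", "dc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricReport:
    acc: float
    sen: float
    spe: float
    ji: float
    dc: float
    aggregation: str = "per_image_mean"
    n_images: int = 1

    def as_dict(self) -> Dict[str, float]:
        return {"acc": self.acc, "sen": self.sen, "spe": self.spe,
                "ji": self.ji, "dc": self.dc}


def _validate_mask(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} mask must be binary (0/1); found values {vals[:5]}")
    return arr.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between two aligned binary masks."""
    p = _validate_mask(pred, "predicted")
    t = _validate_mask(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, degenerate: float = 1.0) -> float:
    return num / den if den else degenerate


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate (a.k.a. recall). Undefined with no true lesions:
    1.0 if nothing was (wrongly) predicted, else 0.0 with a warning."""
    if c.tp + c.fn == 0:
        if c.fp:
            logger.warning("sensitivity undefined (no lesion pixels in truth) "
                           "with %d false positives; reporting 0.0", c.fp)
            return 0.0
        return 1.0
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp)


def jaccard(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn + c.fp)


def dice(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp)


def compute_metrics(c: ConfusionCounts) -> Dict[str, float]:
    return {"acc": accuracy(c), "sen": sensitivity(c), "spe": specificity(c),
            "ji": jaccard(c), "dc": dice(c)}


def evaluate_dataset(pred_masks: Sequence, truth_masks: Sequence,
                     aggregation: str = "per_image_mean") -> MetricReport:
    """Score a list of aligned mask pairs.

    ``per_image_mean`` averages each metric over images (every image counts
    equally, the usual challenge convention); ``global`` pools the confusion
    counts over all pixels first (large images dominate).
    """
    if aggregation not in ("per_image_mean", "global"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    preds, truths = list(pred_masks), list(truth_masks)
    if not preds:
        raise ValueError("evaluate_dataset: empty mask list")
    if len(preds) != len(truths):
        raise ValueError(f"{len(preds)} predictions vs {len(truths)} truths")
    counts = [confusion_counts(p, t) for p, t in zip(preds, truths)]
    if aggregation == "global":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        vals = compute_metrics(pooled)
    else:
        per_image = [compute_metrics(c) for c in counts]
        vals = {k: float(np.mean([m[k] for m in per_image])) for k in METRIC_NAMES}
    return MetricReport(**vals, aggregation=aggregation, n_images=len(preds))


def per_image_metrics(pred_masks: Sequence, truth_masks: Sequence) -> List[Dict[str, float]]:
    return [compute_metrics(confusion_counts(p, t))
            for p, t in zip(pred_masks, truth_masks)]


def write_report_csv(path, rows: Iterable[Dict[str, float]],
                     ids: Sequence[str] | None = None) -> None:
    """One row per image with the five metrics (plus an id column)."""
    rows = list(rows)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(rows))]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", *METRIC_NAMES])
        for rid, row in zip(ids, rows):
            writer.writerow([rid] + [f"{row[k]:.6f}" for k in METRIC_NAMES])
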