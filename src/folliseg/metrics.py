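"""Pixel-level segmentation evaluation: confusion counts, Recall/Precision/Jaccard/Dice.

GT denotes the ground-truth mask and SR the predicted segmentation result.
Scores follow the standard set definitions

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    dice      = 2 |GT ∩ SR| / (|GT| + |SR|)
    jaccard   = |GT ∩ SR| / |GT ∪ SR|

with the identity ``jaccard = dice / (2 - dice)`` wherever Dice is defined.

Degenerate conventions: if GT and SR are both empty every score is 1 (a
correct empty prediction); if exactly one is empty, dice = jaccard = 0 and
the ratio whose denominator vanishes (recall for empty GT, precision for
empty SR) is reported as NaN and excluded from aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "SegmentationScores",
    "confusion_counts",
    "scores",
    "scores_from_counts",
    "evaluate_dataset",
    "report_frame",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SegmentationScores:
    """The four scores; NaN marks an undefined ratio (see module docstring)."""

    recall: float
    precision: float
    dice: float
    jaccard: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _check_mask(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    return mask.astype(bool)


def confusion_counts(sr: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted mask against ground truth."""
    sr = _check_mask(sr, "SR")
    gt = _check_mask(gt, "GT")
    if sr.shape != gt.shape:
        raise ValueError(f"SR shape {sr.shape} != GT shape {gt.shape}")
    tp = int(np.sum(sr & gt))
    fp = int(np.sum(sr & ~gt))
    fn = int(np.sum(~sr & gt))
    tn = int(np.sum(~sr & ~gt))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def scores_from_counts(c: ConfusionCounts) -> SegmentationScores:
    """Scores from confusion counts, applying the degenerate conventions."""
    n_gt = c.tp + c.fn
    n_sr = c.tp + c.fp
    if n_gt == 0 and n_sr == 0:
        return SegmentationScores(recall=1.0, precision=1.0, dice=1.0, jaccard=1.0)
    recall = c.tp / n_gt if n_gt > 0 else float("nan")
    precision = c.tp / n_sr if n_sr > 0 else float("nan")
    dice = 2.0 * c.tp / (n_gt + n_sr)
    union = n_gt + n_sr - c.tp
    jaccard = c.tp / union
    return SegmentationScores(recall=recall, precision=precision,
                              dice=dice, jaccard=jaccard)


def scores(sr: np.ndarray, gt: np.ndarray) -> SegmentationScores:
    """Recall, precision, Dice and Jaccard of one predicted/ground-truth pair."""
    return scores_from_counts(confusion_counts(sr, gt))


def evaluate_dataset(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                     pooled: bool = False) -> SegmentationScores:
    """Aggregate scores over (SR, GT) pairs.

    Default aggregation is the unweighted mean of per-image scores (NaN
    entries from degenerate images are excluded per score).  With
    ``pooled=True`` the confusion counts are summed over all pairs first
    and the scores computed once on the pooled counts.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset needs at least one (SR, GT) pair")
    counts = [confusion_counts(sr, gt) for sr, gt in pairs]
    if pooled:
        total = ConfusionCounts(tp=sum(c.tp for c in counts),
                                fp=sum(c.fp for c in counts),
                                tn=sum(c.tn for c in counts),
                                fn=sum(c.fn for c in counts))
        return scores_from_counts(total)
    per_image = [scores_from_counts(c) for c in counts]
    agg = {}
    for name in ("recall", "precision", "dice", "jaccard"):
        vals = [v for s in per_image if not np.isnan(v := getattr(s, name))]
        agg[name] = float(np.mean(vals)) if vals else float("nan")
    return SegmentationScores(**agg)


def report_frame(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                 names: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-image score table in report column order (Recall, Precision, Jaccard, Dice)."""
    pairs = list(pairs)
    names = list(names) if names is not None else [str(i) for i in range(len(pairs))]
    rows = []
    for name, (sr, gt) in zip(names, pairs):
        s = scores(sr, gt)
        rows.append({"image": name, "Recall": s.recall, "Precision": s.precision,
                     "Jaccard": s.jaccard, "Dice": s.dice})
    return pd.DataFrame(rows)
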