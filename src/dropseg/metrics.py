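"""Confusion-matrix accounting, the six segmentation scores, and ROC/AUC.

Scores follow the standard pixel-by-pixel definitions:

    accuracy          = (TP + TN) / (TP + TN + FP + FN)
    balanced accuracy = (TP/P + TN/N) / 2
    precision         = TP / (TP + FP)
    recall            = TP / (TP + FN)
    Dice / F1         = 2 TP / (2 TP + FP + FN)
    Jaccard           = TP / (TP + FP + FN)

A score whose denominator is zero (e.g. precision when nothing is
predicted positive) is genuinely uninterpretable for that image; it is
reported as NaN, flagged, and excluded from cross-fold averages with the
exclusion counted, rather than silently coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import BinaryMask

METRIC_NAMES = (
    "accuracy",
    "balanced_accuracy",
    "precision",
    "recall",
    "dice",
    "jaccard",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel tallies from one predicted-vs-true mask comparison."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        """Condition positives: TP + FN."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Condition negatives: TN + FP."""
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The six scores for one comparison; NaN where undefined, with flags."""

    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    dice: float
    jaccard: float
    counts: ConfusionCounts
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Tally TP/TN/FP/FN between a predicted and a true mask, pixel by pixel."""
    p = pred.pixels
    t = truth.pixels
    if p.shape != t.shape:
        raise ValueError(f"mask dimensions differ: pred {p.shape} vs truth {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the six scores from confusion counts.

    Zero-denominator scores come back NaN and are listed in ``undefined``.
    """
    if c.total == 0:
        raise ValueError("cannot score an empty comparison (zero pixels)")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    accuracy = (tp + tn) / c.total
    recall = _ratio(tp, c.p)
    specificity = _ratio(tn, c.n)
    balanced = (
        (recall + specificity) / 2
        if not (math.isnan(recall) or math.isnan(specificity))
        else math.nan
    )
    precision = _ratio(tp, tp + fp)
    dice = _ratio(2 * tp, 2 * tp + fp + fn)
    jaccard = _ratio(tp, tp + fp + fn)
    values = {
        "accuracy": accuracy,
        "balanced_accuracy": balanced,
        "precision": precision,
        "recall": recall,
        "dice": dice,
        "jaccard": jaccard,
    }
    undefined = tuple(k for k, v in values.items() if math.isnan(v))
    return MetricsReport(counts=c, undefined=undefined, **values)


def score_masks(pred: BinaryMask, truth: BinaryMask) -> MetricsReport:
    """Convenience: confusion counts and the six scores in one call."""
    return compute_metrics(confusion_counts(pred, truth))


@dataclass(frozen=True)
class RocCurve:
    """An ROC sweep: (FPR, TPR) points over all distinct score thresholds.

    ``auc`` equals the probability that a random positive pixel outranks a
    random negative one, with ties counting one half (the Mann-Whitney
    convention).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores, truth) -> RocCurve:
    """Sweep an ROC curve over per-pixel scores against binary labels."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).ravel().astype(int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    classes = np.unique(truth)
    if classes.size < 2:
        raise ValueError(
            "ROC requires at least one positive and one negative label"
        )
    fpr, tpr, thr = _sk_roc_curve(truth, scores, drop_intermediate=False)
    auc = float(roc_auc_score(truth, scores))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def reports_to_frame(
    reports: list[MetricsReport], index: list | None = None
) -> pd.DataFrame:
    """Tabulate reports (one row each): six metrics + four counts + flags."""
    rows = []
    for r in reports:
        row = r.as_dict()
        row.update(
            tp=r.counts.tp, tn=r.counts.tn, fp=r.counts.fp, fn=r.counts.fn,
            undefined=";".join(r.undefined),
        )
        rows.append(row)
    return pd.DataFrame(rows, index=index)


def mean_defined(values) -> tuple[float, int]:
    """Mean over defined (non-NaN) entries and the count of excluded ones."""
    arr = np.asarray(values, dtype=np.float64)
    defined = arr[~np.isnan(arr)]
    excluded = int(arr.size - defined.size)
    mean = float(defined.mean()) if defined.size else math.nan
    return mean, excluded
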