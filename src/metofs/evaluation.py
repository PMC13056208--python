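"""Classification metrics, rank-based AUC and run aggregation.

Positive class is ASD (label 1).  Zero-denominator ratios are reported
as 0 with a warning rather than raising, so degenerate test splits do not
abort an experiment sweep.  The standard deviation everywhere uses the
population (1/n) convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger("metofs")

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "auc_rank",
    "aggregate_runs",
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


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    precision: float
    fscore: float
    auc: float = float("nan")
    n_features: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "fscore": self.fscore,
            "auc": self.auc,
            "n_features": self.n_features,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard binary confusion counts (positive class = 1)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity (recall of positives), precision, F-score."""
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    acc = _ratio(counts.tp + counts.tn, counts.total, "accuracy")
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    fscore = _ratio(2.0 * prec * sens, prec + sens, "fscore")
    return MetricsReport(accuracy=acc, sensitivity=sens, precision=prec, fscore=fscore)


def auc_rank(scores, y_true) -> float:
    """Probability that a random positive outscores a random negative.

    Tie-aware Mann-Whitney form (ties count 1/2), computed from midranks;
    equivalent to the all-pairs count.  Scores from a KNN are the
    positive-neighbor vote fractions (K+1 distinct levels).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(int)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    r_pos = ranks[y_true == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aggregate_runs(values, higher_is_better: bool = True) -> dict:
    """Mean / StD (1/n convention) / Best / Worst across repeated runs.

    For benefit metrics best = max; for costs (e.g. selected-feature
    counts) pass ``higher_is_better=False`` to swap best and worst.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to aggregate")
    mean = float(values.mean())
    std = float(values.std(ddof=0))
    hi, lo = float(values.max()), float(values.min())
    best, worst = (hi, lo) if higher_is_better else (lo, hi)
    return {"mean": mean, "std": std, "best": best, "worst": worst}
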