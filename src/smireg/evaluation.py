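"""Classifier performance metrics for up/down regulation prediction.

UP is the positive class.  Threshold metrics apply the strict > 0.5 call
rule to the upregulation probability; AUC is the rank statistic (the
probability a random UP outranks a random DOWN, ties counted half) and
AUCPR the area under the step-interpolated precision--recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .types import Label


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table with UP as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    acc: float = 0.0
    bacc: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    mcc: float = 0.0
    jaccard: float = 0.0
    auc: float | None = None
    aucpr: float | None = None
    #: names of metrics whose denominator was 0 (value reported as 0)
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {
            "acc": self.acc,
            "bacc": self.bacc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "jaccard": self.jaccard,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        if self.aucpr is not None:
            out["aucpr"] = self.aucpr
        return out


def _as_binary(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, Label):
            if lab is Label.UNKNOWN:
                raise ValueError("cannot evaluate against UNKNOWN labels")
            out.append(1 if lab is Label.UP else 0)
        else:
            out.append(int(lab))
    return np.asarray(out, dtype=int)


def confusion_counts(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion table at the given probability threshold (call UP iff >)."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if scores.shape[0] != y.shape[0]:
        raise ValueError(f"{scores.shape[0]} scores vs {y.shape[0]} labels")
    calls = scores > threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    tn = int(np.sum(~calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def threshold_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, balanced accuracy, precision, recall, F1, MCC, Jaccard.

    Metrics whose denominator is zero are reported as 0 and flagged on the
    report's ``degenerate`` list.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    deg: list[str] = []
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    acc = (tp + tn) / c.total
    tpr = _ratio(tp, tp + fn, "recall", deg)
    tnr = _ratio(tn, tn + fp, "specificity", deg)
    bacc = 0.5 * (tpr + tnr)
    precision = _ratio(tp, tp + fp, "precision", deg)
    recall = tpr
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", deg)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", deg)
    jaccard = _ratio(tp, tp + fp + fn, "jaccard", deg)
    return MetricReport(
        acc=acc, bacc=bacc, precision=precision, recall=recall,
        f1=f1, mcc=float(mcc), jaccard=jaccard, degenerate=deg,
    )


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney rank statistic with tie halving."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = int(y.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties at 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve, step interpolation.

    Equals sum over threshold steps of (recall increment x precision at the
    step), the conservative estimator.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.shape[0]:
        raise ValueError("AUCPR needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # collapse tied scores to one operating point (the last index of a tie run)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def rank_metrics(scores, labels) -> tuple[float, float]:
    """(AUC, AUCPR) for a batch of scores and UP/DOWN labels."""
    return roc_auc(scores, labels), pr_auc(scores, labels)


def evaluate(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Full metric report: threshold metrics at 0.5 plus AUC/AUCPR."""
    report = threshold_metrics(confusion_counts(scores, labels, threshold))
    y = _as_binary(labels)
    if 0 < y.sum() < y.shape[0]:
        report.auc, report.aucpr = rank_metrics(scores, labels)
    return report
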