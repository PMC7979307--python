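"""Confusion-matrix statistics and ROC/AUC for the binary nodule task.

Statistics follow the standard contingency definitions: accuracy is the
fraction of correct predictions, precision the fraction of predicted
positives that are real, recall (sensitivity, TPR) the fraction of real
positives found, specificity the fraction of real negatives kept, and F1
the harmonic mean of precision and recall.  Ratios with a zero denominator
are reported as NaN with an explicit flag rather than silently zero-filled,
so degenerate evaluations (e.g. a classifier that never predicts positive)
are loud.

AUC is computed by trapezoidal integration of the ROC curve over all score
thresholds, which coincides with the Mann-Whitney statistic
P(score_pos > score_neg) + 0.5 * P(tie); the test suite verifies the
identity against an exhaustive pairwise oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one sample is required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Counts at a decision threshold; a probability exactly at the
    threshold is called positive."""
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != probabilities.shape:
        raise ValueError("labels and probabilities must have equal length")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pred = probabilities >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def _ratio(num: int, den: int, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return float("nan")
    return num / den


@dataclass
class MetricsReport:
    """All contingency statistics plus (optionally) AUC.

    ``undefined`` lists every statistic whose denominator was zero; those
    fields hold NaN.
    """

    counts: ConfusionCounts
    threshold: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    fpr: float
    f1: float
    auc: float | None = None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "fpr": self.fpr,
            "f1": self.f1,
            "undefined": list(self.undefined),
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def metrics(counts: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Contingency statistics from raw counts (AUC needs scores; see
    :func:`roc_auc` / :func:`evaluate_predictions`)."""
    flags: list[str] = []
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    accuracy = (tp + tn) / counts.total
    precision = _ratio(tp, tp + fp, flags, "precision")
    recall = _ratio(tp, tp + fn, flags, "recall")
    specificity = _ratio(tn, tn + fp, flags, "specificity")
    fpr = _ratio(fp, fp + tn, flags, "fpr")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        flags.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        counts=counts,
        threshold=threshold,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        fpr=fpr,
        f1=f1,
        undefined=flags,
    )


def roc_auc(labels, scores) -> tuple[float, np.ndarray]:
    """AUC and the ROC point list ``[(fpr, tpr), ...]``.

    Thresholds sweep the distinct scores from +inf downward; tied scores
    enter the curve together, so the trapezoid over a tie block awards the
    half-credit the Mann-Whitney statistic prescribes.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to draw a ROC curve")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tie block
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), labels.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def evaluate_predictions(labels, probabilities,
                         threshold: float = 0.5) -> MetricsReport:
    """Full report (confusion statistics + AUC) from soft predictions."""
    counts = confusion(labels, probabilities, threshold)
    report = metrics(counts, threshold)
    labels = np.asarray(labels)
    if len(np.unique(labels)) == 2:
        report.auc = roc_auc(labels, probabilities)[0]
    else:
        report.undefined.append("auc")
    return report
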