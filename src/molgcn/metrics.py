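"""Confusion-matrix metrics, the F-alpha measure, ROC curve and AUC.

Everything here is computed from first principles (no scikit-learn):

    precision = TP / (TP + FP)          recall = TPR = TP / (TP + FN)
    FPR = FP / (FP + TN)
    F_alpha = (alpha^2 + 1) * precision * recall / (alpha^2 * precision + recall)

Precision, recall and F are reported as percentages; FPR/TPR/AUC as fractions.
Zero denominators yield 0 with a logged warning so that multi-run aggregation
never drops a run.  The ROC sweep predicts positive at ``score >= threshold``
for each distinct score in descending order (ties collapse to one threshold),
which makes the trapezoidal AUC exactly the pairwise probability that a
positive outscores a negative, ties counted one half.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), (0,0) .. (1,1)


@dataclass(frozen=True)
class MetricsReport:
    precision: float  # percent
    recall: float     # percent
    f1: float         # percent
    fpr: float        # fraction
    tpr: float        # fraction
    auc: float | None  # fraction; None when the test fold is single-class
    cm: ConfusionMatrix


def _check_binary(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr.astype(int)


def confusion(labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionMatrix:
    """Count TP/FP/TN/FN for binary labels and predictions."""
    y = _check_binary(labels, "labels")
    p = _check_binary(predicted_labels, "predicted_labels")
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    return ConfusionMatrix(
        TP=int(np.sum((y == 1) & (p == 1))),
        FP=int(np.sum((y == 0) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return num / den


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP), as a percentage."""
    return 100.0 * _ratio(cm.TP, cm.TP + cm.FP, "precision")


def recall(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN), as a percentage (equals TPR x 100)."""
    return 100.0 * _ratio(cm.TP, cm.TP + cm.FN, "recall")


def fpr(cm: ConfusionMatrix) -> float:
    """FP / (FP + TN), as a fraction."""
    return _ratio(cm.FP, cm.FP + cm.TN, "FPR")


def f_measure(precision_pct: float, recall_pct: float, alpha: float = 1.0) -> float:
    """Weighted harmonic mean of precision and recall (percent in, percent out).

    Larger alpha weights recall more heavily; alpha = 1 is the F1 score.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if precision_pct < 0 or recall_pct < 0:
        raise ValueError("precision and recall must be non-negative")
    denom = alpha ** 2 * precision_pct + recall_pct
    if denom == 0:
        logger.warning("F-measure undefined (precision + recall = 0); reporting 0")
        return 0.0
    return (alpha ** 2 + 1) * precision_pct * recall_pct / denom


def roc_curve(labels: Sequence[int], scores: Sequence[float]) -> ROCCurve:
    """Threshold sweep over descending distinct scores.

    Each point is the (FPR, TPR) of "predict positive iff score >= threshold";
    an infinite sentinel contributes the (0, 0) start and the lowest score
    yields (1, 1).  Requires both classes present.
    """
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative label")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < y.size:
        j = i
        while j < y.size and s_sorted[j] == s_sorted[i]:  # ties share a threshold
            tp += int(y_sorted[j] == 1)
            fp += int(y_sorted[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return ROCCurve(points=tuple(points))


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve over FPR in [0, 1]."""
    pts = np.asarray(roc.points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def evaluate(labels: Sequence[int], predicted_labels: Sequence[int],
             scores: Sequence[float] | None = None) -> MetricsReport:
    """Full report from hard predictions plus optional scores for ROC/AUC.

    When scores are given but the labels are single-class, AUC is recorded as
    None (undefined) instead of failing.
    """
    cm = confusion(labels, predicted_labels)
    p = precision(cm)
    r = recall(cm)
    area: float | None = None
    if scores is not None:
        try:
            area = auc(roc_curve(labels, scores))
        except ValueError:
            logger.warning("AUC undefined for single-class labels; recorded as missing")
    return MetricsReport(
        precision=p, recall=r, f1=f_measure(p, r, 1.0),
        fpr=fpr(cm), tpr=r / 100.0, auc=area, cm=cm,
    )


# ---------------------------------------------------------------------------
# report files

def _fmt(report_row: tuple[str, float, float, float, float | None]) -> list[str]:
    name, p, r, f1, area = report_row
    return [name, f"{p:.2f}", f"{r:.2f}", f"{f1:.2f}",
            "" if area is None else f"{area:.4f}"]


def write_report(rows: Iterable[tuple[str, float, float, float, float | None]],
                 path: str | Path) -> None:
    """CSV report: ``experiment,precision,recall,f1,auc`` rows.

    Percentages are rounded to two decimals and AUC to four, matching the
    print format used throughout.
    """
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["experiment", "precision", "recall", "f1", "auc"])
        for row in rows:
            writer.writerow(_fmt(row))


def read_report(path: str | Path) -> list[tuple[str, float, float, float, float | None]]:
    """Inverse of :func:`write_report`."""
    rows = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for name, p, r, f1, area in reader:
            rows.append((name, float(p), float(r), float(f1),
                         float(area) if area else None))
    return rows


def write_roc_points(roc: ROCCurve, path: str | Path) -> None:
    """ROC points as CSV ``fpr,tpr``."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr"])
        for x, y in roc.points:
            writer.writerow([f"{x:.6f}", f"{y:.6f}"])
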