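"""Per-fold classification metrics and cross-fold aggregation.

Atrial fibrillation (label 1) is the positive class.  Per-fold reports
carry accuracy, macro-averaged precision/recall/F1, rank-based AUC-ROC and
mean categorical cross-entropy; fold results are summarized as mean ±
sample standard deviation across the five folds, and confusion matrices
are aggregated by element-wise summation — valid because the subject-wise
folds have mutually exclusive test subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with AF (1) as the positive class."""

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

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    def as_array(self) -> np.ndarray:
        """2x2 array with true class on rows (SR first), predicted on columns."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def row_normalized(self) -> np.ndarray:
        """Per-true-class rates (true negative/positive rates on the diagonal)."""
        counts = self.as_array().astype(float)
        sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, counts / sums, np.nan)


@dataclass(frozen=True)
class MetricsReport:
    """One fold's metric set."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float | None
    loss: float | None = None


def compute_confusion(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionMatrix:
    """Count binary outcomes with AF (1) as positive."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def compute_metrics(
    cm: ConfusionMatrix,
    scores: Sequence[float] | None = None,
    true_labels: Sequence[int] | None = None,
    probs: np.ndarray | None = None,
) -> MetricsReport:
    """Derive the metric set of one fold.

    Precision, recall and F1 are computed per class and macro-averaged; on
    balanced test sets this makes them coincide with accuracy for any
    reasonably symmetric classifier.  AUC-ROC is the rank statistic over
    the AF probabilities (midrank ties); it needs ``scores`` aligned with
    ``true_labels`` and both classes present, otherwise it is reported as
    missing.  ``probs`` (full per-class probability rows) adds the mean
    categorical cross-entropy.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total

    # reconstruct a label stream consistent with the counts for sklearn
    t = np.concatenate(
        [np.ones(cm.tp + cm.fn, dtype=int), np.zeros(cm.tn + cm.fp, dtype=int)]
    )
    p = np.concatenate(
        [
            np.ones(cm.tp, dtype=int),
            np.zeros(cm.fn, dtype=int),
            np.zeros(cm.tn, dtype=int),
            np.ones(cm.fp, dtype=int),
        ]
    )
    precision, recall, f1, _ = precision_recall_fscore_support(
        t, p, average="macro", zero_division=0
    )

    auc: float | None = None
    loss: float | None = None
    if scores is not None and true_labels is not None:
        true_labels = np.asarray(true_labels, dtype=int)
        scores = np.asarray(scores, dtype=float)
        if len(np.unique(true_labels)) == 2:
            auc = float(roc_auc_score(true_labels, scores))
        if probs is not None:
            probs = np.asarray(probs, dtype=float)
            picked = np.clip(probs[np.arange(len(true_labels)), true_labels], 1e-7, 1.0)
            loss = float(-np.mean(np.log(picked)))
    return MetricsReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        auc_roc=auc,
        loss=loss,
    )


def aggregate_confusions(cms: Sequence[ConfusionMatrix]) -> ConfusionMatrix:
    """Element-wise sum of per-fold confusion matrices."""
    if not cms:
        raise ValueError("no confusion matrices to aggregate")
    out = cms[0]
    for cm in cms[1:]:
        out = out + cm
    return out


@dataclass(frozen=True)
class CrossValSummary:
    """Mean and sample standard deviation of each metric across folds."""

    n_folds: int
    mean: dict[str, float]
    std: dict[str, float]


def summarize_folds(reports: Sequence[MetricsReport]) -> CrossValSummary:
    """Mean ± sample standard deviation (ddof=1) across fold reports.

    Metrics that are missing in any fold (e.g., undefined AUC) are skipped.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 fold reports for a mean ± std summary")
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for f in fields(MetricsReport):
        values = [getattr(r, f.name) for r in reports]
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
            continue
        arr = np.asarray(values, dtype=float)
        mean[f.name] = float(arr.mean())
        std[f.name] = float(arr.std(ddof=1))
    return CrossValSummary(n_folds=len(reports), mean=mean, std=std)
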