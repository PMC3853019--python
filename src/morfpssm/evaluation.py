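"""Per-residue evaluation: confusion counts, CASP-style metrics, ROC/AUC.

Metrics follow the CASP10 conventions: sensitivity (TPR) = TP/(TP+FN),
specificity = TN/(TN+FP), FPR = 1 - specificity, accuracy =
(TP+TN)/total, and the balanced accuracy ACC = (sensitivity +
specificity)/2.  Evaluation pools residues over all proteins in a test set.
Metrics with a zero denominator are reported as absent (None) with a
warning rather than coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    """Scalar metrics plus the ROC polyline, recomputable from counts/scores."""

    counts: ConfusionCounts
    sensitivity: float | None = None
    specificity: float | None = None
    fpr: float | None = None
    accuracy: float | None = None
    balanced_accuracy: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "counts": {
                "TP": self.counts.tp,
                "TN": self.counts.tn,
                "FP": self.counts.fp,
                "FN": self.counts.fn,
            },
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fpr": self.fpr,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
            "roc_points": [[float(x), float(y)] for x, y in self.roc_points],
        }


def confusion(calls: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact confusion counts from aligned binary calls and labels."""
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if calls.shape != truth.shape:
        raise ValueError(
            f"misaligned inputs: {calls.shape} calls vs {truth.shape} labels"
        )
    return ConfusionCounts(
        tp=int(np.sum((calls == 1) & (truth == 1))),
        tn=int(np.sum((calls == 0) & (truth == 0))),
        fp=int(np.sum((calls == 1) & (truth == 0))),
        fn=int(np.sum((calls == 0) & (truth == 1))),
    )


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as absent")
        return None
    return num / den


def metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Scalar CASP-style metrics from confusion counts."""
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    report = EvaluationReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        fpr=None if spec is None else 1.0 - spec,
        accuracy=_ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        balanced_accuracy=(
            None if sens is None or spec is None else (sens + spec) / 2.0
        ),
    )
    return report


def roc_auc(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC polyline (one vertex per distinct score, ties grouped) and its AUC.

    The curve sweeps all score thresholds, is anchored at (0, 0) and (1, 1),
    and the AUC is the trapezoidal integral — equivalently the probability
    that a random positive outscores a random negative (ties counting 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must be aligned")
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(truth, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate(
    scores: np.ndarray, calls: np.ndarray, truth: np.ndarray
) -> EvaluationReport:
    """Full pooled per-residue report: counts, scalar metrics, ROC and AUC."""
    report = metrics(confusion(calls, truth))
    report.roc_points, report.auc = roc_auc(scores, truth)
    return report
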