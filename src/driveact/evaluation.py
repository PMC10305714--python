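"""Classification metrics, confusion matrices and report aggregation.

Metrics follow the usual count-based definitions: accuracy (as a percentage),
precision, recall and the F1 score (harmonic mean of precision and recall),
computed per class one-vs-rest from the confusion matrix, plus
support-weighted averages, a 4-way type-level collapse
(Crossroad / Parking / Roundabout / Secondary) and the binary
primary-vs-secondary accuracy.

The formulas are implemented directly from the counts on purpose (the test
suite checks them against scikit-learn and a brute-force pairwise counter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .jins_io import LABELS, TYPE_GROUPS, label_map

__all__ = [
    "MetricsCounts",
    "EvaluationReport",
    "accuracy",
    "precision_recall_f1",
    "f1_from_precision_recall",
    "confusion_matrix",
    "counts_from_confusion",
    "per_class_report",
    "weighted_average",
    "type_level_report",
    "binary_primary_secondary_accuracy",
    "evaluate_predictions",
    "pca_embed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsCounts:
    """One-vs-rest trial counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def accuracy(c: MetricsCounts) -> float:
    """``100 * (tp + tn) / (tp + tn + fp + fn)``, in percent."""
    if c.total == 0:
        raise ValueError("cannot compute accuracy of zero counts")
    return 100.0 * (c.tp + c.tn) / c.total


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean ``2PR / (P + R)``; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(c: MetricsCounts) -> tuple[float, float, float]:
    """Precision ``tp/(tp+fp)``, recall ``tp/(tp+fn)`` and their harmonic
    mean.  Zero denominators yield 0 by convention (logged)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics of zero counts")
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        logger.debug("zero denominator in precision/recall; returning 0 by convention")
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    return precision, recall, f1_from_precision_recall(precision, recall)


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = 16
) -> np.ndarray:
    """Count matrix with entry (i, j) = number of true-i samples predicted j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (y_true, y_pred), 1)
    return mat


def counts_from_confusion(confusion: np.ndarray, cls: int) -> MetricsCounts:
    """One-vs-rest counts for class *cls* derived from a confusion matrix."""
    confusion = np.asarray(confusion)
    tp = int(confusion[cls, cls])
    fp = int(confusion[:, cls].sum() - tp)
    fn = int(confusion[cls, :].sum() - tp)
    tn = int(confusion.sum() - tp - fp - fn)
    return MetricsCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def per_class_report(confusion: np.ndarray) -> dict[int, dict[str, float]]:
    out = {}
    for cls in range(confusion.shape[0]):
        c = counts_from_confusion(confusion, cls)
        p, r, f1 = precision_recall_f1(c)
        out[cls] = {
            "precision": p,
            "recall": r,
            "f1": f1,
            "support": int(np.asarray(confusion)[cls].sum()),
        }
    return out


def weighted_average(metrics: Sequence[float], supports: Sequence[float]) -> float:
    """Support-weighted arithmetic mean."""
    supports = np.asarray(supports, dtype=float)
    if np.any(supports < 0):
        raise ValueError("supports must be non-negative")
    total = supports.sum()
    if total == 0:
        raise ValueError("total support is zero")
    return float(np.dot(np.asarray(metrics, dtype=float), supports) / total)


def _collapse(confusion: np.ndarray, group_of: Sequence[int], n_groups: int) -> np.ndarray:
    out = np.zeros((n_groups, n_groups), dtype=int)
    for i in range(confusion.shape[0]):
        for j in range(confusion.shape[1]):
            out[group_of[i], group_of[j]] += confusion[i, j]
    return out


def type_level_report(confusion: np.ndarray) -> dict[str, dict[str, float]]:
    """Collapse the 16-class confusion to the 4 activity-type groups and score
    each group one-vs-rest (accuracy in percent, precision/recall/F1)."""
    confusion = np.asarray(confusion)
    if confusion.shape != (16, 16):
        raise ValueError("expected a 16x16 confusion matrix")
    group_index = {g: i for i, g in enumerate(TYPE_GROUPS)}
    group_of = [group_index[label_map(code).type_group] for code in range(16)]
    collapsed = _collapse(confusion, group_of, len(TYPE_GROUPS))
    out = {}
    for g, name in enumerate(TYPE_GROUPS):
        c = counts_from_confusion(collapsed, g)
        p, r, f1 = precision_recall_f1(c)
        out[name] = {
            "accuracy": accuracy(c) if c.total else 0.0,
            "precision": p,
            "recall": r,
            "f1": f1,
            "support": int(collapsed[g].sum()),
        }
    return out


def binary_primary_secondary_accuracy(confusion: np.ndarray) -> float:
    """Accuracy (percent) after collapsing classes to primary (0-11) vs
    secondary (12-15)."""
    confusion = np.asarray(confusion)
    group_of = [0 if label_map(code).is_primary else 1 for code in range(16)]
    collapsed = _collapse(confusion, group_of, 2)
    total = collapsed.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(collapsed) / total


@dataclass
class EvaluationReport:
    """Full evaluation output: confusion matrix, per-class and type-level
    metrics, weighted averages, overall and binary accuracy."""

    confusion: np.ndarray
    per_class: dict[int, dict[str, float]]
    weighted: dict[str, float]
    overall_accuracy: float
    type_level: dict[str, dict[str, float]]
    binary_primary_secondary: float

    def to_dict(self) -> dict:
        return {
            "confusion": np.asarray(self.confusion).tolist(),
            "per_class": {label_map(k).name: v for k, v in self.per_class.items()},
            "weighted": self.weighted,
            "overall_accuracy": self.overall_accuracy,
            "type_level": self.type_level,
            "binary_primary_secondary_accuracy": self.binary_primary_secondary,
        }

    def to_text(self) -> str:
        """Delimited tables mirroring the per-class and type-level layouts."""
        lines = ["Label\tActivity\tPrecision\tRecall\tF1 Score"]
        for code, m in sorted(self.per_class.items()):
            lines.append(
                f"{code}\t{label_map(code).name}\t{m['precision']:.2f}\t{m['recall']:.2f}\t{m['f1']:.2f}"
            )
        lines.append("")
        lines.append("Activity\tAccuracy [%]\tPrecision\tRecall\tF1 Score")
        for name, m in self.type_level.items():
            lines.append(
                f"{name}\t{m['accuracy']:.1f}\t{m['precision']:.2f}\t{m['recall']:.2f}\t{m['f1']:.2f}"
            )
        lines.append("")
        lines.append(f"Overall accuracy [%]\t{self.overall_accuracy:.1f}")
        lines.append(f"Binary primary/secondary accuracy [%]\t{self.binary_primary_secondary:.1f}")
        lines.append(
            "Weighted precision/recall/F1\t"
            f"{self.weighted['precision']:.2f}\t{self.weighted['recall']:.2f}\t{self.weighted['f1']:.2f}"
        )
        lines.append("")
        lines.append("Confusion matrix (rows = true, cols = predicted):")
        for row in np.asarray(self.confusion):
            lines.append("\t".join(str(v) for v in row))
        return "\n".join(lines)


def evaluate_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = 16
) -> EvaluationReport:
    """Build the full :class:`EvaluationReport` from label sequences."""
    confusion = confusion_matrix(y_true, y_pred, n_classes)
    per_class = per_class_report(confusion)
    supports = [per_class[c]["support"] for c in range(n_classes)]
    weighted = {
        key: weighted_average([per_class[c][key] for c in range(n_classes)], supports)
        for key in ("precision", "recall", "f1")
    }
    overall = 100.0 * np.trace(confusion) / confusion.sum()
    return EvaluationReport(
        confusion=confusion,
        per_class=per_class,
        weighted=weighted,
        overall_accuracy=float(overall),
        type_level=type_level_report(confusion) if n_classes == 16 else {},
        binary_primary_secondary=(
            binary_primary_secondary_accuracy(confusion) if n_classes == 16 else float("nan")
        ),
    )


def pca_embed(features: np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Project feature vectors onto the top *dims* principal components.

    Returns (coordinates, explained variances); variances are non-increasing.
    """
    features = np.asarray(features, dtype=float)
    if dims > features.shape[1]:
        raise ValueError(f"dims {dims} exceeds feature dimension {features.shape[1]}")
    if features.shape[0] < dims:
        raise ValueError("need at least `dims` samples")
    pca = PCA(n_components=dims)
    coords = pca.fit_transform(features)
    return coords, pca.explained_variance_
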