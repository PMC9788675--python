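"""Evaluation metrics: confusion matrix, accuracy, F1, Cohen's kappa.

Cohen's kappa corrects raw agreement for chance:
``kappa = (p_o - p_e) / (1 - p_e)`` where ``p_o`` is observed accuracy and
``p_e`` the agreement expected from the row/column marginals alone. It is
the headline statistic for the cough-vs-restricted-breathing task, whose
test set is imbalanced enough that raw accuracy flatters a trivial
classifier. F1 is support-weighted by default (macro available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class ConfusionMatrix:
    """Square count matrix; entry (i, j) = true class i predicted as j."""

    matrix: np.ndarray
    class_order: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.class_order)
        if self.matrix.shape != (k, k):
            raise ValidationError(
                "matrix: shape %r does not match %d classes" % (self.matrix.shape, k)
            )
        if np.min(self.matrix) < 0:
            raise ValidationError("matrix: entries must be >= 0")
        if self.matrix.sum() == 0:
            raise ValidationError("matrix: needs at least one positive entry")


@dataclass
class MetricsReport:
    accuracy: float
    weighted_f1: float
    cohens_kappa: float | None
    per_class_precision: dict
    per_class_recall: dict
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "weighted_f1": self.weighted_f1,
            "cohens_kappa": self.cohens_kappa,
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
            "n_test": self.n_test,
        }


def confusion(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    """Count matrix over ``class_order`` from paired label sequences."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("labels: sequences differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    mat = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValidationError(f"true label: unknown class {t!r}")
        if p not in index:
            raise ValidationError(f"predicted label: unknown class {p!r}")
        mat[index[t], index[p]] += 1
    return ConfusionMatrix(matrix=mat, class_order=tuple(class_order))


def metrics(cm: ConfusionMatrix, f1_average: str = "weighted") -> MetricsReport:
    """Accuracy, F1 and Cohen's kappa from a confusion matrix.

    Per-class F1 is ``2PR/(P+R)`` with the convention F1 = 0 when P+R = 0.
    Kappa is reported as None (missing, not an error) when the expected
    agreement ``p_e`` equals 1, which leaves it undefined.
    """
    if f1_average not in ("weighted", "macro"):
        raise ValidationError(f"f1_average: unsupported {f1_average!r}")
    m = cm.matrix.astype(np.float64)
    total = m.sum()
    row = m.sum(axis=1)  # true-class support
    col = m.sum(axis=0)  # predicted-class counts
    diag = np.diag(m)

    accuracy = float(diag.sum() / total)

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    if f1_average == "weighted":
        weighted_f1 = float((row / total) @ f1)
    else:
        weighted_f1 = float(np.mean(f1))

    p_o = accuracy
    p_e = float((row / total) @ (col / total))
    kappa = None if abs(1.0 - p_e) < 1e-12 else float((p_o - p_e) / (1.0 - p_e))

    classes = cm.class_order
    return MetricsReport(
        accuracy=accuracy,
        weighted_f1=weighted_f1,
        cohens_kappa=kappa,
        per_class_precision={c: float(p) for c, p in zip(classes, precision)},
        per_class_recall={c: float(r) for c, r in zip(classes, recall)},
        n_test=int(total),
    )


def evaluate(true_labels, predicted_labels, class_order,
             f1_average: str = "weighted") -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(true_labels, predicted_labels, class_order),
                   f1_average=f1_average)
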