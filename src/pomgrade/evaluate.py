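"""Evaluation: confusion matrices, overall accuracy, multi-view aggregation.

Overall accuracy is A = N_T / N_V x 100%, where N_T is the number of
correctly classified samples (the confusion-matrix trace) and N_V the total
evaluated. In the online grading setting each fruit is photographed from
several angles; the per-view class scores are summed and the grade with the
highest total score wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .grades import GRADE_NAMES, N_CLASSES, GradeLabel


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = actual grade, columns = predicted grade."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        self.counts = c

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def per_class_recall(self) -> Dict[str, float]:
        out = {}
        for i, name in enumerate(GRADE_NAMES):
            row = self.counts[i].sum()
            out[name] = float(self.counts[i, i] / row) if row else float("nan")
        return out

    def to_dict(self) -> Dict:
        return dict(counts=self.counts.tolist(),
                    accuracy_percent=accuracy(self),
                    per_class_recall=self.per_class_recall())


def confusion_matrix(actual: Sequence[int], predicted: Sequence[int]
                     ) -> ConfusionMatrix:
    """counts[i][j] = number of samples with actual grade i predicted as j."""
    a = np.asarray([int(v) for v in actual])
    p = np.asarray([int(v) for v in predicted])
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    valid = set(range(N_CLASSES))
    if not (set(a.tolist()) <= valid and set(p.tolist()) <= valid):
        raise ValueError("labels must be grade codes in {0, 1, 2}")
    counts = _sk_confusion(a, p, labels=list(range(N_CLASSES)))
    return ConfusionMatrix(counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent, rounded half-up to 2 decimals."""
    if cm.n_total == 0:
        raise ValueError("empty confusion matrix")
    pct = Decimal(100 * cm.n_correct) / Decimal(cm.n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def aggregate_views(view_scores: Sequence[Sequence[float]]) -> GradeLabel:
    """Sum per-view class score vectors; highest total wins.

    Ties break toward the lowest class index (premium first). With a single
    view this reduces to the per-image argmax.
    """
    scores = np.asarray(view_scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("need at least one view")
    if scores.ndim != 2 or scores.shape[1] != N_CLASSES:
        raise ValueError(f"each view needs {N_CLASSES} class scores")
    totals = scores.sum(axis=0)
    return GradeLabel(int(np.argmax(totals)))
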