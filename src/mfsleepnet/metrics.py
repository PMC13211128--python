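"""Confusion-matrix evaluation: overall accuracy, Cohen's kappa, macro-F1.

Overall accuracy is the proportion of correctly predicted samples
(trace / N, reported in percent). Chance agreement for kappa uses the
standard multiclass marginal product. A class absent from both truth and
prediction contributes F1 = 0 to the macro average, with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles import N_STAGES, STAGES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "overall_accuracy",
    "cohens_kappa",
    "macro_f1",
    "per_class_scores",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 counts; rows are true stages, columns predicted, order W..REM."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_STAGES, N_STAGES) or (counts < 0).any():
            raise ValueError("confusion matrix must be 5x5 non-negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, n_classes: int = N_STAGES) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of samples on the diagonal."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / cm.n


def cohens_kappa(cm: ConfusionMatrix) -> float:
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    n = cm.n
    p0 = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    pe = float(row @ col)
    if pe == 1.0:
        if p0 == 1.0:
            return 1.0
        raise ValueError("kappa undefined: degenerate identical marginals with p0 < 1")
    return (p0 - pe) / (1.0 - pe)


def per_class_scores(cm: ConfusionMatrix) -> dict:
    counts = cm.counts
    out = {}
    for c, stage in enumerate(STAGES[:counts.shape[0]]):
        tp = counts[c, c]
        fp = counts[:, c].sum() - tp
        fn = counts[c, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        if tp == 0 and fp == 0 and fn == 0:
            warnings.warn(f"class {stage} absent from truth and prediction; "
                          "F1 set to 0", RuntimeWarning)
            f1 = 0.0
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        out[stage] = {"precision": precision, "recall": recall, "f1": f1}
    return out


def macro_f1(cm: ConfusionMatrix) -> float:
    scores = per_class_scores(cm)
    return float(np.mean([s["f1"] for s in scores.values()]))


@dataclass
class MetricsReport:
    oa: float       # percent
    kappa: float
    mf1: float      # fraction in [0, 1]
    per_class: dict = field(default_factory=dict)
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {"oa": self.oa, "kappa": self.kappa, "mf1": self.mf1,
             "per_class": self.per_class}
        if self.confusion is not None:
            d["confusion"] = self.confusion.counts.tolist()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def evaluate(y_true, y_pred) -> MetricsReport:
    cm = confusion(y_true, y_pred)
    return MetricsReport(
        oa=overall_accuracy(cm),
        kappa=cohens_kappa(cm),
        mf1=macro_f1(cm),
        per_class=per_class_scores(cm),
        confusion=cm,
    )
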