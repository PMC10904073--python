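"""Binary-classification metrics with explicit undefined-value semantics.

The Matthews correlation coefficient (MCC) is undefined whenever a marginal
of the confusion matrix is zero — for example when a classifier predicts the
same class for every sample. Small-cohort drug-response models do this often
(always predicting the majority class), and collapsing that outcome to 0
would hide it, so ``mcc`` returns a distinguished :data:`UNDEFINED` sentinel
instead. Downstream summaries exclude undefined repetitions and report how
many there were; a model whose every repetition is undefined is reported as
a blank, not a zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


class Undefined:
    """Singleton sentinel for an undefined metric value.

    Distinct from ``nan`` so that an undefined MCC can never be silently
    averaged or compared; distinct from 0 because a random classifier and a
    degenerate one are different outcomes.
    """

    _instance = None

    def __new__(cls) -> "Undefined":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "undefined"

    def __reduce__(self):
        return (Undefined, ())


UNDEFINED = Undefined()


def is_defined(value) -> bool:
    """True if *value* is an actual number rather than the undefined sentinel."""
    return not isinstance(value, Undefined)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary classification; positives are responders."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label and prediction vectors differ in length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(cm: ConfusionMatrix):
    """Matthews correlation coefficient, or :data:`UNDEFINED`.

    Returns ``(tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``. When
    the denominator is zero — any row or column of the confusion matrix
    empty — the value is undefined and the sentinel is returned; this
    function never raises.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return UNDEFINED
    return (tp * tn - fp * fn) / math.sqrt(denom)


def roc_auc(scores, labels):
    """Area under the ROC curve; responders (label 1) are positives.

    Equals the probability that a random positive outranks a random
    negative, with ties counted one half (the Mann–Whitney identity). Any
    monotone transform of the scores leaves it unchanged. Returns
    :data:`UNDEFINED` when only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        return UNDEFINED
    return float(roc_auc_score(labels, scores))


def median_defined(values: Iterable):
    """Median of the defined entries of *values* plus the undefined count.

    Returns ``(median, n_undefined)``; the median itself is
    :data:`UNDEFINED` when every entry is (a blank summary cell).
    """
    values = list(values)
    defined = [v for v in values if is_defined(v)]
    n_undefined = len(values) - len(defined)
    if not defined:
        return UNDEFINED, n_undefined
    return float(np.median(defined)), n_undefined


def format_metric(value, fmt: str = "{:.4f}") -> str:
    """Render a metric for tables: a number, or the string ``undefined``."""
    return fmt.format(value) if is_defined(value) else "undefined"
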