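"""Weighted multi-class evaluation metrics for the 6-class oil problem.

Precision, recall and F1 are support-weighted sums of per-class values
(weight ``w_i`` = proportion of true samples in class i), so weighted recall
telescopes to plain accuracy.  Cohen's kappa uses observed agreement ``P0``
against the chance agreement ``Pe`` implied by the row/column marginals.
Two loss conventions are reported side by side and never substituted for
each other:

* ``hamming_loss_eq8`` -- the literal one-hot bitwise definition,
  ``(1/(N*M)) * sum XOR(one-hot bits)``; for single-label data this equals
  ``2*(1-accuracy)/M``.
* ``zero_one_loss`` -- the misclassified fraction, ``1 - accuracy``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "N_CLASSES",
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "weighted_precision",
    "weighted_recall",
    "f1",
    "kappa",
    "hamming_loss_eq8",
    "zero_one_loss",
    "evaluate",
    "summary_table",
]

N_CLASSES = 6


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray  # (6, 6) int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
        if (c < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def weights(self) -> np.ndarray:
        """Per-class true-sample proportions ``w_i``."""
        return self.counts.sum(axis=1) / self.n


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if len(y_true) < 1:
        raise ValueError("need at least one prediction")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if ((arr < 0) | (arr >= N_CLASSES)).any():
            raise ValueError(f"{name} contains labels outside 0..{N_CLASSES - 1}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    return float(cm.tp.sum() / cm.n)


def weighted_precision(cm: ConfusionMatrix) -> float:
    """Support-weighted precision; a class with no predictions contributes 0."""
    tp, fp = cm.tp, cm.fp
    denom = tp + fp
    undefined = (denom == 0) & (cm.weights > 0)
    if undefined.any():
        warnings.warn(
            f"classes {np.flatnonzero(undefined).tolist()} received no predictions; "
            "their precision contributes 0",
            stacklevel=2,
        )
    per_class = np.divide(tp, denom, out=np.zeros(N_CLASSES, dtype=float), where=denom > 0)
    return float((cm.weights * per_class).sum())


def weighted_recall(cm: ConfusionMatrix) -> float:
    """Support-weighted recall; algebraically identical to accuracy."""
    tp, fn = cm.tp, cm.fn
    denom = tp + fn
    per_class = np.divide(tp, denom, out=np.zeros(N_CLASSES, dtype=float), where=denom > 0)
    return float((cm.weights * per_class).sum())


def f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def kappa(cm: ConfusionMatrix) -> Tuple[float, float]:
    """Cohen's kappa: returns (raw in [-1,1], rescaled (raw+1)/2 in [0,1]).

    ``P0`` is observed agreement, ``Pe`` the chance agreement from the
    marginal products.  A degenerate ``Pe = 1`` yields raw kappa 0.
    """
    n = cm.n
    p0 = float(cm.tp.sum() / n)
    pe = float((((cm.tp + cm.fp) * (cm.tp + cm.fn)).sum()) / (n * n))
    if pe >= 1.0:
        raw = 0.0
    else:
        raw = (p0 - pe) / (1.0 - pe)
    return raw, (raw + 1.0) / 2.0


def hamming_loss_eq8(y_true: Sequence[int], y_pred: Sequence[int], m: int = N_CLASSES) -> float:
    """Bitwise one-hot Hamming loss: each misclassified sample flips 2 of m bits."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and prediction")
    n = len(y_true)
    onehot_t = np.zeros((n, m), dtype=int)
    onehot_p = np.zeros((n, m), dtype=int)
    onehot_t[np.arange(n), y_true] = 1
    onehot_p[np.arange(n), y_pred] = 1
    return float(np.logical_xor(onehot_t, onehot_p).sum() / (n * m))


def zero_one_loss(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and prediction")
    return float(np.mean(y_true != y_pred))


@dataclass(frozen=True)
class EvalReport:
    """Complete metric bundle for one set of predictions."""

    accuracy: float
    precision: float
    recall: float
    f1_score: float
    kappa_raw: float
    kappa_rescaled: float
    hamming_loss_eq8: float
    zero_one_loss: float
    p0: float
    pe: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1_score": self.f1_score,
            "kappa_raw": self.kappa_raw,
            "kappa_rescaled": self.kappa_rescaled,
            "hamming_loss_eq8": self.hamming_loss_eq8,
            "zero_one_loss": self.zero_one_loss,
            "p0": self.p0,
            "pe": self.pe,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls.from_dict(json.loads(text))


def evaluate(y_true: Sequence[int], y_pred: Sequence[int]) -> EvalReport:
    cm = confusion(y_true, y_pred)
    p = weighted_precision(cm)
    r = weighted_recall(cm)
    raw, rescaled = kappa(cm)
    n = cm.n
    pe = float((((cm.tp + cm.fp) * (cm.tp + cm.fn)).sum()) / (n * n))
    return EvalReport(
        accuracy=accuracy(cm),
        precision=p,
        recall=r,
        f1_score=f1(p, r),
        kappa_raw=raw,
        kappa_rescaled=rescaled,
        hamming_loss_eq8=hamming_loss_eq8(y_true, y_pred),
        zero_one_loss=zero_one_loss(y_true, y_pred),
        p0=float(cm.tp.sum() / n),
        pe=pe,
    )


def summary_table(report: EvalReport) -> str:
    """Plain-text summary in the conventional row order."""
    rows = [
        ("Accuracy", report.accuracy),
        ("Precision", report.precision),
        ("Recall", report.recall),
        ("F1-score", report.f1_score),
        ("Kappa", report.kappa_raw),
        ("Hamming Loss (one-hot bitwise)", report.hamming_loss_eq8),
        ("Misclassification rate", report.zero_one_loss),
    ]
    width = max(len(name) for name, _ in rows)
    return "\n".join(f"{name:<{width}}  {value:.4f}" for name, value in rows)
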