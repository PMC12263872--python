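"""Confusion-matrix accounting and per-class / macro precision, recall, F1.

Binary labels only.  Macro values are the unweighted mean over the two
one-vs-rest tables; any 0/0 ratio is defined as 0 and reported with a
warning, so macro averaging is always total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion_counts",
    "prf",
    "macro_metrics",
    "format_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Per-class and macro-averaged precision / recall / F1."""

    per_class: dict  # label -> (precision, recall, f1)
    macro_precision: float
    macro_recall: float
    macro_f1: float
    counts: dict  # label -> ConfusionCounts


def _as_binary(y, name: str) -> np.ndarray:
    arr = np.asarray(y)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise InvalidInputError(f"{name} must contain only labels 0 and 1")
    return arr.astype(int)


def confusion_counts(y_true, y_pred, positive_class: int) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``positive_class`` as positive."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise InvalidInputError(
            f"length mismatch: y_true has {yt.size} entries, y_pred has {yp.size}"
        )
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (0/0); reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from one-vs-rest counts (0/0 convention -> 0)."""
    precision = _safe_ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _safe_ratio(counts.tp, counts.tp + counts.fn, "recall")
    if precision + recall == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def macro_metrics(y_true, y_pred) -> Metrics:
    """Per-class and macro P/R/F1 over both binary classes.

    Raises
    ------
    InvalidInputError
        If only one class appears in ``y_true``.
    """
    yt = _as_binary(y_true, "y_true")
    if len(np.unique(yt)) < 2:
        raise InvalidInputError("y_true must contain both classes for macro metrics")
    per_class = {}
    counts = {}
    for label in (0, 1):
        c = confusion_counts(y_true, y_pred, positive_class=label)
        counts[label] = c
        per_class[label] = prf(c)
    macro = np.mean([per_class[label] for label in (0, 1)], axis=0)
    return Metrics(
        per_class=per_class,
        macro_precision=float(macro[0]),
        macro_recall=float(macro[1]),
        macro_f1=float(macro[2]),
        counts=counts,
    )


def format_report(metrics: Metrics) -> str:
    """Plain-text evaluation report: confusion table, per-class and macro P/R/F1."""
    lines = ["class  precision  recall      f1      TP   FP   FN   TN"]
    for label in (0, 1):
        p, r, f = metrics.per_class[label]
        c = metrics.counts[label]
        lines.append(
            f"{label:>5}  {p:9.4f}  {r:6.4f}  {f:6.4f}  {c.tp:4d} {c.fp:4d} {c.fn:4d} {c.tn:4d}"
        )
    lines.append(
        f"macro  {metrics.macro_precision:9.4f}  {metrics.macro_recall:6.4f}  "
        f"{metrics.macro_f1:6.4f}"
    )
    return "\n".join(lines)
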