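"""Confusion matrices and macro-averaged classification metrics.

Conventions follow the four-class cell-type evaluation: rows of the
confusion matrix are true classes, columns predicted classes, in the fixed
order ESC, iPSC, ECC, somatic. The macro F-score is the harmonic mean of the
*macro* precision and *macro* recall (not the mean of per-class F-scores):

    P_macro = mean_c precision_c        R_macro = mean_c recall_c
    F_macro = 2 * P_macro * R_macro / (P_macro + R_macro)
    accuracy = trace / total

Per-class precision/recall with a zero denominator are undefined; they are
reported as NaN and enter macro averages as 0 with a warning, so metrics
stay defined for degenerate early-training checkpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

from .io import CLASSES


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-by-predicted counts over a fixed class order."""

    classes: tuple[str, ...]
    counts: np.ndarray  # (C, C) int, rows = true, cols = predicted

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.classes),) * 2 or (counts < 0).any():
            raise ValueError("counts must be a square non-negative matrix over classes")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside classes {list(classes)}: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(classes), counts)


def class_precision(cm: ConfusionMatrix, class_index: int) -> float:
    """Column-correct fraction; NaN if the class was never predicted."""
    col = cm.counts[:, class_index]
    denom = col.sum()
    return float(cm.counts[class_index, class_index] / denom) if denom else float("nan")


def class_recall(cm: ConfusionMatrix, class_index: int) -> float:
    """Row-correct fraction; NaN if the class has no true samples."""
    row = cm.counts[class_index, :]
    denom = row.sum()
    return float(cm.counts[class_index, class_index] / denom) if denom else float("nan")


def _macro(values: np.ndarray, what: str) -> float:
    if np.isnan(values).any():
        warnings.warn(
            f"undefined per-class {what} treated as 0 in macro average",
            RuntimeWarning,
            stacklevel=3,
        )
    return float(np.nan_to_num(values).mean())


@dataclass(frozen=True)
class MacroMetrics:
    """Per-class and macro-averaged precision/recall, F-macro and accuracy."""

    classes: tuple[str, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    precision_macro: float
    recall_macro: float
    f_macro: float
    accuracy: float

    def as_percent(self, ndigits: int = 2) -> dict[str, float]:
        """Display values as percentages rounded half-up to `ndigits`."""
        def pct(v: float) -> float:
            v = float(v)
            if np.isnan(v):
                return float("nan")
            q = Decimal(1).scaleb(-ndigits)
            return float(Decimal(repr(v * 100)).quantize(q, rounding=ROUND_HALF_UP))

        out = {f"precision_{c}": pct(p) for c, p in zip(self.classes, self.precision)}
        out.update({f"recall_{c}": pct(r) for c, r in zip(self.classes, self.recall)})
        out.update(
            precision_macro=pct(self.precision_macro),
            recall_macro=pct(self.recall_macro),
            f_macro=pct(self.f_macro),
            accuracy=pct(self.accuracy),
        )
        return out


def table_cells(cm: ConfusionMatrix) -> dict[str, float]:
    """Machine-readable report keyed by benchmark-table cell names.

    ``a``-``d`` letter the predicted-class column, digit 1-4 the true-class
    row (a1..d4 counts); ``e1..e4`` per-class precision and ``f1..f4``
    per-class recall as percentages, plus the macro summaries.
    """
    if len(cm.classes) != 4:
        raise ValueError("cell naming is defined for the four-class table")
    letters = "abcd"
    out: dict[str, float] = {}
    for i in range(4):  # true-class row
        for j in range(4):  # predicted-class column
            out[f"{letters[j]}{i + 1}"] = int(cm.counts[i, j])
    mm = macro_metrics(cm)
    pct = mm.as_percent()
    for i, c in enumerate(cm.classes):
        out[f"e{i + 1}"] = pct[f"precision_{c}"]
        out[f"f{i + 1}"] = pct[f"recall_{c}"]
    out["precision_macro"] = pct["precision_macro"]
    out["recall_macro"] = pct["recall_macro"]
    out["f_macro"] = pct["f_macro"]
    out["accuracy"] = pct["accuracy"]
    return out


def macro_metrics(cm: ConfusionMatrix) -> MacroMetrics:
    k = len(cm.classes)
    prec = np.array([class_precision(cm, i) for i in range(k)])
    rec = np.array([class_recall(cm, i) for i in range(k)])
    p_macro = _macro(prec, "precision")
    r_macro = _macro(rec, "recall")
    f_macro = (
        2 * p_macro * r_macro / (p_macro + r_macro) if (p_macro + r_macro) > 0 else 0.0
    )
    total = cm.total
    accuracy = float(np.trace(cm.counts) / total) if total else float("nan")
    return MacroMetrics(
        classes=cm.classes,
        precision=tuple(prec),
        recall=tuple(rec),
        precision_macro=p_macro,
        recall_macro=r_macro,
        f_macro=f_macro,
        accuracy=accuracy,
    )
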