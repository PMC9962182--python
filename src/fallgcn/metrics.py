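"""Confusion matrices and the accuracy / precision / recall / F1 suite.

All metrics are reported in percent. Per-class precision, recall and F1 use
the one-vs-rest counts of the confusion matrix; the headline values are
macro averages, i.e. unweighted means over classes, which is the honest
summary for fall data where ADL windows vastly outnumber fall windows (a
frequency-weighted average would hide poor fall recall behind abundant
easy ADLs).

A diagnostic ``precision_formula="literal-eq2"`` mode computes TN/(TN+FP)
instead of TP/(TP+FP) for precision. That formula is specificity, not
precision, and it breaks the harmonic-mean structure of F1 — it exists only
so its output can be compared side-by-side with the standard definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassCounts",
    "MetricsReport",
    "confusion_matrix",
    "one_vs_rest_counts",
    "metrics_report",
]


@dataclass
class ConfusionMatrix:
    """Counts[t, p] = number of samples with true class t predicted as p."""

    counts: np.ndarray
    class_ids: tuple = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if not self.class_ids:
            self.class_ids = tuple(range(self.counts.shape[0]))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.class_ids, name="true"),
            columns=pd.Index(self.class_ids, name="predicted"),
        )


def confusion_matrix(y_true, y_pred, class_ids=None) -> ConfusionMatrix:
    """Tally a confusion matrix over the given class id set.

    ``class_ids`` defaults to 0..max; labels outside the set raise.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if class_ids is None:
        hi = int(max(y_true.max(initial=-1), y_pred.max(initial=-1))) + 1
        class_ids = tuple(range(max(hi, 1)))
    class_ids = tuple(class_ids)
    index = {c: i for i, c in enumerate(class_ids)}
    c = len(class_ids)
    counts = np.zeros((c, c), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label pair ({t},{p}) outside class set {class_ids}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, class_ids)


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest tallies for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def one_vs_rest_counts(cm: ConfusionMatrix, class_index: int) -> ClassCounts:
    """TP/FP/FN/TN for one class, treating every other class as negative."""
    c = cm.counts
    tp = int(c[class_index, class_index])
    fn = int(c[class_index].sum()) - tp
    fp = int(c[:, class_index].sum()) - tp
    tn = cm.total - tp - fn - fp
    return ClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class MetricsReport:
    """Overall and per-class metrics, all in percent."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: pd.DataFrame
    averaging: str = "macro"
    precision_formula: str = "standard"

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
        }


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, False
    return num / den, True


def metrics_report(
    cm: ConfusionMatrix, precision_formula: str = "standard"
) -> MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F1 from a matrix.

    Classes absent from both truth and predictions get precision/recall 0
    and are flagged ``defined=False`` in the per-class table (they still
    enter the macro averages, keeping the average comparable across runs).
    """
    if precision_formula not in ("standard", "literal-eq2"):
        raise ValueError("precision_formula must be 'standard' or 'literal-eq2'")
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    accuracy = 100.0 * np.trace(cm.counts) / total
    rows = []
    for i, cid in enumerate(cm.class_ids):
        cc = one_vs_rest_counts(cm, i)
        if precision_formula == "standard":
            prec, p_ok = _safe_div(cc.tp, cc.tp + cc.fp)
        else:
            prec, p_ok = _safe_div(cc.tn, cc.tn + cc.fp)
        rec, r_ok = _safe_div(cc.tp, cc.tp + cc.fn)
        f1, _ = _safe_div(2.0 * prec * rec, prec + rec)
        rows.append(
            {
                "class": cid,
                "support": cc.tp + cc.fn,
                "precision": 100.0 * prec,
                "recall": 100.0 * rec,
                "f1": 100.0 * f1,
                "defined": bool(p_ok or r_ok),
            }
        )
    per_class = pd.DataFrame(rows).set_index("class")
    return MetricsReport(
        accuracy=float(accuracy),
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        per_class=per_class,
        precision_formula=precision_formula,
    )
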