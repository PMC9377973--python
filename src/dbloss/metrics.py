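"""Confusion-matrix metrics: missed/wrong detection rates and per-class report.

The missed detection rate (false negative rate) and wrong detection rate
(false positive rate) are the clinical screening metrics

    FNR = FN / (TP + FN)        FPR = FP / (FP + TN)

computed one-vs-rest per class from a k x k confusion matrix (rows = true
class, columns = predicted class) and macro-averaged when a scalar is
requested.  Empty denominators raise or surface as missing values — never as
silent zeros, which would bias comparisons between classifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "UndefinedRateError",
    "confusion",
    "fnr",
    "fpr",
    "macro_fnr",
    "macro_fpr",
    "per_class_report",
]


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested whose denominator is zero."""


@dataclass(frozen=True)
class ConfusionMatrix:
    table: np.ndarray  # k x k ints, rows true, cols predicted
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=int)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("confusion table must be square")
        if np.any(t < 0):
            raise ValueError("confusion table entries must be non-negative")
        if len(self.labels) != t.shape[0]:
            raise ValueError("labels must match table dimension")
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    @property
    def k(self) -> int:
        return self.table.shape[0]

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def confusion(
    y_true, y_pred, k: int, labels: tuple[str, ...] | None = None
) -> ConfusionMatrix:
    """Build a k x k confusion matrix; entry (i, j) counts true i predicted j."""
    yt = np.asarray(y_true, dtype=int).ravel()
    yp = np.asarray(y_pred, dtype=int).ravel()
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.size and (min(yt.min(), yp.min()) < 0 or max(yt.max(), yp.max()) >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    if yt.size == 0:
        table = np.zeros((k, k), dtype=int)
    else:
        table = _sk_confusion(yt, yp, labels=np.arange(k))
    if labels is None:
        labels = tuple(str(i) for i in range(k))
    return ConfusionMatrix(table, labels)


def _ovr(cm: ConfusionMatrix, i: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FN, FP, TN) for class i."""
    t = cm.table
    tp = int(t[i, i])
    fn = int(t[i, :].sum()) - tp
    fp = int(t[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return tp, fn, fp, tn


def fnr(cm: ConfusionMatrix, class_index: int) -> float:
    """Missed detection rate FN / (TP + FN) for one class."""
    tp, fn, _, _ = _ovr(cm, class_index)
    if tp + fn == 0:
        raise UndefinedRateError(
            f"FNR undefined for class {class_index}: no true samples"
        )
    return fn / (tp + fn)


def fpr(cm: ConfusionMatrix, class_index: int) -> float:
    """Wrong detection rate FP / (FP + TN) for one class."""
    _, _, fp, tn = _ovr(cm, class_index)
    if fp + tn == 0:
        raise UndefinedRateError(
            f"FPR undefined for class {class_index}: no negatives"
        )
    return fp / (fp + tn)


def _macro(cm: ConfusionMatrix, rate) -> float:
    vals = []
    for i in range(cm.k):
        try:
            vals.append(rate(cm, i))
        except UndefinedRateError:
            continue
    if not vals:
        raise UndefinedRateError("rate undefined for every class")
    return float(np.mean(vals))


def macro_fnr(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class FNR over classes where it is defined."""
    return _macro(cm, fnr)


def macro_fpr(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class FPR over classes where it is defined."""
    return _macro(cm, fpr)


def per_class_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision/recall/FNR/FPR plus an unweighted macro row.

    Undefined entries (empty rows or columns) are NaN, and the macro row
    averages only over defined values.
    """
    rows = []
    for i in range(cm.k):
        tp, fn, fp, tn = _ovr(cm, i)
        rows.append(
            {
                "label": cm.labels[i],
                "support": tp + fn,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "recall": tp / (tp + fn) if tp + fn else np.nan,
                "fnr": fn / (tp + fn) if tp + fn else np.nan,
                "fpr": fp / (fp + tn) if fp + tn else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("label")
    macro = df[["precision", "recall", "fnr", "fpr"]].mean(skipna=True)
    macro["support"] = df["support"].sum()
    df.loc["macro"] = macro
    return df


def report_to_json(cm: ConfusionMatrix, path) -> None:
    payload = {
        "labels": list(cm.labels),
        "confusion": cm.table.tolist(),
        "report": json.loads(per_class_report(cm).to_json(orient="index")),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
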