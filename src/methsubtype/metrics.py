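"""Evaluation statistics for multiclass subtype predictions.

All six statistics are computed from the C x C confusion matrix:
accuracy, macro-averaged precision and recall, support-weighted F1, the
multiclass (Gorodkin) Matthews correlation coefficient, and Cohen's kappa.
Zero-denominator conventions are fixed for determinism on degenerate
predictors: a per-class precision/recall with empty denominator
contributes 0 to the macro mean, and MCC with a zero denominator is 0.
Macro means run over all C vocabulary classes, including classes absent
from ``y_true``, so reports stay comparable across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MetricsReport:
    """The six headline statistics plus the per-class breakdown."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_weighted: float
    mcc: float
    kappa: float
    per_class: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_weighted": self.f1_weighted,
            "mcc": self.mcc,
            "kappa": self.kappa,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                fh.write(f"{key}\t{value:.6f}\n")


def _validate(y_true, y_pred, n_classes: int):
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D arrays of equal length")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains an index outside [0, {n_classes})")
    return y_true, y_pred


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Entry (i, j) counts samples with true class i predicted as j."""
    y_true, y_pred = _validate(y_true, y_pred, n_classes)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


def evaluate(y_true, y_pred, n_classes: int) -> MetricsReport:
    """Compute the full metric suite from paired class-index arrays."""
    cm = confusion_matrix(y_true, y_pred, n_classes)
    n = cm.sum()
    diag = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)  # true-class counts
    predicted = cm.sum(axis=0).astype(float)

    accuracy = float(diag.sum() / n)
    precision = _safe_div(diag, predicted)
    recall = _safe_div(diag, support)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    precision_macro = float(precision.mean())
    recall_macro = float(recall.mean())
    f1_weighted = float((f1 * support).sum() / n)

    # Gorodkin's multiclass MCC; reduces to the binary form at C = 2
    cov_tp = n * diag.sum() - support @ predicted
    den = np.sqrt(float(n * n - predicted @ predicted)) * np.sqrt(
        float(n * n - support @ support)
    )
    mcc = float(cov_tp / den) if den != 0 else 0.0

    p_e = float(support @ predicted) / (n * n)
    kappa = float((accuracy - p_e) / (1 - p_e)) if p_e != 1 else 0.0

    per_class = pd.DataFrame(
        {
            "support": support.astype(int),
            "precision": precision,
            "recall": recall,
            "f1": f1,
        },
        index=pd.RangeIndex(n_classes, name="class"),
    )
    return MetricsReport(
        accuracy=accuracy,
        precision_macro=precision_macro,
        recall_macro=recall_macro,
        f1_weighted=f1_weighted,
        mcc=mcc,
        kappa=kappa,
        per_class=per_class,
    )
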