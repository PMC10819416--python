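"""Classification metrics: confusion matrix, accuracy/sensitivity/specificity/
precision, Cohen's kappa, and one-vs-rest ROC curves.

Binary metrics follow the standard TP/TN/FP/FN definitions with the
second class (index 1) as the positive class; multiclass scalars are
macro averages of per-class one-vs-rest values.  Classes with a zero
denominator are flagged as undefined (NaN) and excluded from the macro
average with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["MetricsReport", "confusion_matrix", "metrics_from_confusion", "roc_points",
           "evaluate_predictions"]


@dataclass
class MetricsReport:
    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    kappa: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    roc: dict[str, Any] | None = None

    def as_dict(self) -> dict[str, Any]:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "kappa": self.kappa,
            "confusion": self.confusion.tolist(),
            "per_class": {str(k): v for k, v in self.per_class.items()},
        }
        if self.roc is not None:
            out["auc_macro"] = self.roc["auc_macro"]
            out["auc_per_class"] = {str(k): v["auc"] for k, v in self.roc["per_class"].items()}
        return out


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix, entry (i, j) = # windows with true class i predicted j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.bincount(y_true * n_classes + y_pred, minlength=n_classes * n_classes)
    return cm.reshape(n_classes, n_classes)


def _cohen_kappa(cm: np.ndarray) -> float:
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    """Scalar metrics from a confusion matrix (rows = true, cols = predicted)."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    n = int(cm.sum())
    if n == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    accuracy = float(np.trace(cm) / n)

    per_class: dict[int, dict[str, float]] = {}
    for c in range(k):
        tp = float(cm[c, c])
        fn = float(cm[c].sum() - tp)
        fp = float(cm[:, c].sum() - tp)
        tn = float(n - tp - fn - fp)
        per_class[c] = {
            "sensitivity": tp / (tp + fn) if tp + fn > 0 else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp > 0 else float("nan"),
            "precision": tp / (tp + fp) if tp + fp > 0 else float("nan"),
        }

    def macro(key: str) -> float:
        vals = np.array([per_class[c][key] for c in range(k)])
        defined = ~np.isnan(vals)
        if not defined.all():
            warnings.warn(
                f"{key} undefined for class(es) "
                f"{[c for c in range(k) if np.isnan(vals[c])]}; excluded from macro average",
                RuntimeWarning,
            )
        if not defined.any():
            return float("nan")
        return float(vals[defined].mean())

    if k == 2:
        # positive class = index 1: direct TP/TN/FP/FN substitution
        sens = per_class[1]["sensitivity"]
        spec = per_class[1]["specificity"]
        prec = per_class[1]["precision"]
        if np.isnan(sens) or np.isnan(prec) or np.isnan(spec):
            warnings.warn("binary metric undefined (zero denominator)", RuntimeWarning)
    else:
        sens, spec, prec = macro("sensitivity"), macro("specificity"), macro("precision")

    return MetricsReport(
        confusion=cm.astype(int),
        accuracy=accuracy,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        kappa=_cohen_kappa(cm),
        per_class=per_class,
    )


def roc_points(y_true, scores) -> dict[str, Any]:
    """One-vs-rest ROC curve + trapezoidal AUC per class, plus macro AUC.

    ``scores`` is (n, K) per-class probabilities (or (n,) for binary,
    interpreted as the positive-class score).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = np.column_stack([1.0 - scores, scores])
    if scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("ROC undefined for single-class labels")
    out: dict[str, Any] = {"per_class": {}}
    aucs = []
    for c in range(scores.shape[1]):
        if c not in classes:
            continue
        fpr, tpr, _ = _sk_roc_curve((y_true == c).astype(int), scores[:, c])
        a = float(_sk_auc(fpr, tpr))
        out["per_class"][int(c)] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": a}
        aucs.append(a)
    out["auc_macro"] = float(np.mean(aucs))
    return out


def evaluate_predictions(y_true, y_pred, scores=None, n_classes: int | None = None) -> MetricsReport:
    """Confusion matrix + scalars (+ ROC when probabilities are supplied)."""
    y_true = np.asarray(y_true, dtype=int)
    k = n_classes if n_classes is not None else int(max(y_true.max(), np.max(y_pred)) + 1)
    report = metrics_from_confusion(confusion_matrix(y_true, y_pred, k))
    if scores is not None:
        report.roc = roc_points(y_true, scores)
    return report
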