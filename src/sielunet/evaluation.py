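"""Confusion-matrix metrics, PR/ROC curves and validation-curve reporting.

Metric conventions: accuracy, precision, recall (= sensitivity), F1 and
specificity are percentages; MCC is the dimensionless Matthews correlation
in [-1, 1].  Degenerate denominators are defined rather than raised: a zero
MCC denominator gives MCC = 0, and precision with no predicted positives is
0 (with a warning).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import average_precision_score as _sk_ap
from sklearn.metrics import precision_recall_curve as _sk_pr
from sklearn.metrics import roc_curve as _sk_roc

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "pr_curve",
    "roc_curve",
    "validation_curve_report",
    "table2_frame",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Six derived metrics; percents in [0, 100], MCC in [-1, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    mcc: float

    @property
    def sensitivity(self) -> float:  # alias by construction
        return self.recall

    def to_dict(self) -> dict:
        return asdict(self)

    def formatted(self) -> dict:
        """Percentages to 2 decimals (table formatting convention)."""
        d = {k: round(v, 2) for k, v in asdict(self).items()}
        d["mcc"] = round(self.mcc, 4)
        return d


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN for binary 0/1 vectors of equal length."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive the six metrics from a confusion matrix."""
    tp, tn, fp, fn = float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn)
    accuracy = (tp + tn) / cm.n * 100.0
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp) * 100.0
    recall = tp / (tp + fn) * 100.0 if tp + fn > 0 else 0.0
    specificity = tn / (tn + fp) * 100.0 if tn + fp > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall,
        f1=f1, specificity=specificity, mcc=mcc,
    )


def _check_scores(y_true, scores) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("both classes must be present in y_true")
    return y_true, scores


def roc_curve(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """(FPR, TPR) points over the swept thresholds plus trapezoid area."""
    y_true, scores = _check_scores(y_true, scores)
    fpr, tpr, _ = _sk_roc(y_true, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def pr_curve(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """(recall, precision) points plus the average-precision area summary."""
    y_true, scores = _check_scores(y_true, scores)
    precision, recall, _ = _sk_pr(y_true, scores)
    area = float(_sk_ap(y_true, scores))
    return list(zip(recall.tolist(), precision.tolist())), area


def validation_curve_report(history: dict) -> pd.DataFrame:
    """Per-epoch train/validation accuracy table from a training history."""
    if not history or not history.get("loss"):
        raise ValueError("empty training history")
    n = len(history["loss"])
    return pd.DataFrame(
        {
            "epoch": np.arange(1, n + 1),
            "train_acc": history["train_acc"],
            "val_acc": history["val_acc"],
            "loss": history["loss"],
        }
    )


def plot_validation_curve(history: dict, path) -> None:
    """Write a train-vs-validation accuracy per-epoch plot (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = validation_curve_report(history)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["epoch"], df["train_acc"], label="training accuracy")
    ax.plot(df["epoch"], df["val_acc"], label="validation accuracy")
    ax.set_xlabel("epoch")
    ax.set_ylabel("accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def table2_frame(reports: dict[str, dict[str, MetricsReport]]) -> pd.DataFrame:
    """Model-comparison table: rows = models, train/test column pairs."""
    rows = {}
    for model, split_reports in reports.items():
        row = {}
        for split in ("training", "testing"):
            rep = split_reports.get(split)
            if rep is None:
                continue
            f = rep.formatted()
            for metric in ("accuracy", "precision", "recall", "f1", "specificity", "mcc"):
                row[f"{metric}_{split}"] = f[metric]
        rows[model] = row
    return pd.DataFrame.from_dict(rows, orient="index")
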