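"""Classification and regression metrics used to assess both pipelines.

Classification: confusion matrix, per-class precision/recall/F1/support with
macro and support-weighted averages and accuracy. Regression (3-dimensional
valence/arousal/dominance): MAE, pooled RMSE, per-dimension-averaged R²,
smooth-L1, and rounded accuracy — the share of samples whose predictions match
the targets after mapping back to the 1–5 rating scale and rounding to
integers (per dimension, and jointly across all three).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassificationReport",
    "RegressionReport",
    "confusion_matrix",
    "classification_report",
    "regression_metrics",
    "smooth_l1",
    "round_half_away",
]


def round_half_away(x: np.ndarray, decimals: int = 0) -> np.ndarray:
    """Round half away from zero (so 0.5 → 1, 2.345 → 2.35 at 2 decimals),
    unlike numpy's round-half-even."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass
class ClassificationReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def to_text(self) -> str:
        lines = [f"{'Class':>6} {'Precision':>10} {'Recall':>8} {'F1-score':>9} {'Support':>8}"]
        for c in range(len(self.support)):
            lines.append(
                f"{c:>6} {self.precision[c]:>10.2f} {self.recall[c]:>8.2f} "
                f"{self.f1[c]:>9.2f} {self.support[c]:>8d}"
            )
        n = int(self.support.sum())
        lines.append(f"{'Accuracy':>6} {self.accuracy:>10.2f} {'':>8} {'':>9} {n:>8d}")
        lines.append(
            f"{'Macro':>6} {self.macro_precision:>10.2f} {self.macro_recall:>8.2f} "
            f"{self.macro_f1:>9.2f} {n:>8d}"
        )
        lines.append(
            f"{'Wgt':>6} {self.weighted_precision:>10.2f} {self.weighted_recall:>8.2f} "
            f"{self.weighted_f1:>9.2f} {n:>8d}"
        )
        return "\n".join(lines)


@dataclass
class RegressionReport:
    mae: float
    rmse: float
    r2: float
    r2_per_dim: np.ndarray
    rounded_accuracy_all: float
    rounded_accuracy_per_dim: np.ndarray
    smooth_l1: float


def confusion_matrix(y_true, y_pred, k: int) -> np.ndarray:
    """k×k count matrix; entry (i, j) counts true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= k):
            raise ValueError(f"{name} contains labels outside 0..{k - 1}")
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def classification_report(confusion: np.ndarray) -> ClassificationReport:
    """Per-class and averaged metrics from a confusion matrix of counts.

    Classes never predicted (empty column) get precision 0 with a warning.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion must be a non-empty square matrix")
    n = cm.sum()
    if n == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm)
    support = cm.sum(axis=1)
    colsum = cm.sum(axis=0)
    if np.any(colsum == 0):
        warnings.warn("some classes were never predicted; precision set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(colsum > 0, diag / np.where(colsum > 0, colsum, 1), 0.0)
        recall = np.where(support > 0, diag / np.where(support > 0, support, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    w = support / n
    return ClassificationReport(
        precision=precision,
        recall=recall,
        f1=f1,
        support=support.astype(int),
        accuracy=float(diag.sum() / n),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float((w * precision).sum()),
        weighted_recall=float((w * recall).sum()),
        weighted_f1=float((w * f1).sum()),
    )


def smooth_l1(pred, true, beta: float = 1.0) -> float:
    """Smooth-L1 (Huber) loss, mean over all entries: e²/(2β) for |e| < β,
    else |e| − β/2."""
    e = np.abs(np.asarray(pred, dtype=float) - np.asarray(true, dtype=float))
    return float(np.where(e < beta, e ** 2 / (2 * beta), e - beta / 2).mean())


def regression_metrics(pred, true, *, rating_scale: bool = True) -> RegressionReport:
    """Full regression report for n×3 normalised VAD predictions.

    MAE and RMSE pool over all n×3 entries; R² is computed per dimension then
    averaged.  Rounded accuracy maps both arrays back to the 1–5 rating scale
    (x·4 + 1) before integer rounding unless ``rating_scale`` is off, in which
    case rounding happens on the values as given.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    true = np.atleast_2d(np.asarray(true, dtype=float))
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal shapes")
    err = pred - true
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    ss_tot = ((true - true.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(ss_tot == 0):
        dim = int(np.flatnonzero(ss_tot == 0)[0])
        raise ValueError(f"R² undefined: target dimension {dim} is constant")
    ss_res = (err ** 2).sum(axis=0)
    r2_per_dim = 1.0 - ss_res / ss_tot
    if rating_scale:
        p_round = round_half_away(pred * 4.0 + 1.0)
        t_round = round_half_away(true * 4.0 + 1.0)
    else:
        p_round = round_half_away(pred)
        t_round = round_half_away(true)
    match = p_round == t_round
    return RegressionReport(
        mae=mae,
        rmse=rmse,
        r2=float(r2_per_dim.mean()),
        r2_per_dim=r2_per_dim,
        rounded_accuracy_all=float(match.all(axis=1).mean()),
        rounded_accuracy_per_dim=match.mean(axis=0),
        smooth_l1=smooth_l1(pred, true),
    )
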