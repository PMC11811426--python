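"""Evaluation metrics: precision/recall/F1, RMSE/MAE, ROC and AUC.

F1 is the harmonic mean of precision and recall computed from the
thresholded classification scores; RMSE and MAE are computed on the
continuous PHQ-8 severity estimates.  The ROC curve is built by sweeping
the score threshold and AUC by the trapezoid rule.  With a single-class
truth vector AUC (and F1 when no positives exist) is reported as missing
rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalReport", "compute_metrics", "roc_curve_points", "auc_trapezoid"]


@dataclass
class EvalReport:
    f1: float | None
    precision: float | None
    recall: float | None
    rmse: float | None
    mae: float | None
    auc: float | None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    group: str | None = None
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "group": self.group, "n": self.n, "f1": self.f1,
            "precision": self.precision, "recall": self.recall,
            "rmse": self.rmse, "mae": self.mae, "auc": self.auc,
        }


def roc_curve_points(y_true: np.ndarray, scores: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) points from (0,0) to (1,1), one per distinct threshold."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return []
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    # collapse ties: keep the last index of each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(ss)), ss.size - 1]
    pts = [(0.0, 0.0)]
    for i in distinct:
        pts.append((fps[i] / n_neg, tps[i] / n_pos))
    return pts


def auc_trapezoid(roc_points: list[tuple[float, float]]) -> float | None:
    if not roc_points:
        return None
    fpr = np.array([p[0] for p in roc_points])
    tpr = np.array([p[1] for p in roc_points])
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(scores: np.ndarray, y_true: np.ndarray,
                    phq8_pred: np.ndarray | None = None,
                    phq8_true: np.ndarray | None = None,
                    threshold: float = 0.5, group: str | None = None) -> EvalReport:
    """Full evaluation report for one set of predictions.

    ``scores`` are classification scores (probabilities if ``threshold`` is
    the default 0.5, or any monotone score with a matching threshold);
    severity errors are computed only when both PHQ-8 vectors are given.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true).astype(int)
    if scores.shape != y.shape:
        raise ValueError("scores and y_true must have identical shapes")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    elif precision is None and recall is None:
        f1 = None
    else:
        f1 = 0.0 if (tp + fn) > 0 or (tp + fp) > 0 else None

    rmse = mae = None
    if phq8_pred is not None and phq8_true is not None:
        err = np.asarray(phq8_pred, dtype=float) - np.asarray(phq8_true, dtype=float)
        rmse = float(np.sqrt(np.mean(err**2)))
        mae = float(np.mean(np.abs(err)))

    roc = roc_curve_points(y, scores)
    return EvalReport(f1=f1, precision=precision, recall=recall, rmse=rmse,
                      mae=mae, auc=auc_trapezoid(roc), roc_points=roc,
                      group=group, n=int(y.size))
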