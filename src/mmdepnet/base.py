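"""Shared estimator plumbing for the dual-head (label + PHQ-8) networks."""

from __future__ import annotations

import numpy as np

from .autodiff import no_grad

__all__ = ["DualHeadPredictorMixin", "check_fitted", "split_targets"]


def check_fitted(est, attr: str = "model_"):
    if not hasattr(est, attr):
        raise RuntimeError(
            f"{type(est).__name__} is not fitted yet; call fit() first")


def split_targets(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept y as (n,) binary labels or (n, 2) [label, phq8] pairs.

    Without an explicit severity column the PHQ-8 regression target falls
    back to the label scaled into score units (0 or 24), which keeps the
    joint objective well defined.
    """
    y = np.asarray(y)
    if y.ndim == 1:
        labels = y.astype(int)
        phq8 = labels.astype(float) * 24.0
    elif y.ndim == 2 and y.shape[1] == 2:
        labels = y[:, 0].astype(int)
        phq8 = y[:, 1].astype(float)
    else:
        raise ValueError("y must be (n,) labels or (n, 2) [label, phq8]")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels, phq8


class DualHeadPredictorMixin:
    """predict / predict_proba / transform on top of a fitted ``model_``.

    Subclasses implement ``_forward(inputs)`` returning numpy
    ``(features, logits, phq8)`` for already-validated inputs, and
    ``_prepare(X)`` mapping user input to those inputs.
    """

    _eval_chunk = 32

    def _forward_all(self, X):
        check_fitted(self)
        inputs = self._prepare(X)
        n = len(inputs)
        feats, logits, phq8 = [], [], []
        self.model_.eval()
        with no_grad():
            for lo in range(0, n, self._eval_chunk):
                f, z, p = self._forward(inputs[lo:lo + self._eval_chunk])
                feats.append(f)
                logits.append(z)
                phq8.append(p)
        return (np.concatenate(feats), np.concatenate(logits), np.concatenate(phq8))

    def decision_function(self, X) -> np.ndarray:
        return self._forward_all(X)[1]

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        # threshold at logit 0 (probability 0.5)
        return (self.decision_function(X) >= 0.0).astype(int)

    def predict_severity(self, X) -> np.ndarray:
        """PHQ-8 severity estimates from the regression head."""
        return self._forward_all(X)[2]

    def transform(self, X) -> np.ndarray:
        """Pooled feature vectors (the representation consumed by fusion)."""
        return self._forward_all(X)[0]
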