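"""Video-Audio Fusion Network (VAFN).

The two branch feature vectors F_V and F_A are zero-padded at the tail to
a common length d, stacked horizontally into ``H_VA`` (2×d) and
concatenated vertically into ``V_VA`` (length 2d).  A fully connected
layer reduces ``V_VA`` to the attention weights ``V_VAF`` (softmax over
the two modalities), and ``F_VA = V_VAFᵀ · H_VA`` — a convex per-modality
combination, so every fused entry lies between the two padded inputs.
The fused vector is max-pooled (window k, stride k) and classified by the
dual head.

An alternative elementwise reading — a length-d sigmoid gate
``F_VA = g ⊙ F_VP + (1-g) ⊙ F_AP`` — is available via
``attention_mode="elementwise"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .autodiff import Tensor, concatenate, no_grad, stack
from .base import DualHeadPredictorMixin, split_targets
from .nn import Dropout, Linear, Module
from .training import TrainConfig, fit_model, LR_FUSION

__all__ = ["VafnConfig", "pad_align", "VafnModel", "VAFNClassifier", "max_pool1d"]


@dataclass(frozen=True)
class VafnConfig:
    d_video: int = 32
    d_audio: int = 24
    attention_mode: str = "modality"   # or "elementwise"
    pool_window: int = 4
    dropout: float = 0.5

    def validate(self) -> None:
        if self.attention_mode not in ("modality", "elementwise"):
            raise ValueError(f"attention_mode must be modality or elementwise, "
                             f"got {self.attention_mode!r}")
        if not 0.4 <= self.dropout <= 0.6:
            raise ValueError(f"dropout must lie in [0.4, 0.6], got {self.dropout}")
        d = max(self.d_video, self.d_audio)
        if not 1 <= self.pool_window <= d:
            raise ValueError(f"pool_window must be in [1, {d}], got {self.pool_window}")

    @property
    def d(self) -> int:
        return max(self.d_video, self.d_audio)


def pad_align(f_v: np.ndarray, f_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad the shorter vector (or batch of vectors) at the tail."""
    f_v = np.atleast_1d(np.asarray(f_v, dtype=np.float64))
    f_a = np.atleast_1d(np.asarray(f_a, dtype=np.float64))
    if f_v.shape[-1] == 0 or f_a.shape[-1] == 0:
        raise ValueError("feature vectors must be non-empty")
    d = max(f_v.shape[-1], f_a.shape[-1])

    def _pad(x):
        if x.shape[-1] == d:
            return x.copy()
        width = [(0, 0)] * (x.ndim - 1) + [(0, d - x.shape[-1])]
        return np.pad(x, width)

    return _pad(f_v), _pad(f_a)


def max_pool1d(x: np.ndarray, window: int) -> np.ndarray:
    """Non-overlapping 1-D max pool (window = stride); remainder dropped."""
    x = np.asarray(x)
    d = x.shape[-1]
    if not 1 <= window <= d:
        raise ValueError(f"pool window must be in [1, {d}], got {window}")
    keep = (d // window) * window
    return x[..., :keep].reshape(x.shape[:-1] + (d // window, window)).max(axis=-1)


class VafnModel(Module):
    def __init__(self, cfg: VafnConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        d = cfg.d
        out = 2 if cfg.attention_mode == "modality" else d
        self.fc = Linear(2 * d, out, rng)
        self.dropout = Dropout(cfg.dropout)
        pooled = d // cfg.pool_window
        self.head_cls = Linear(pooled, 1, rng, zero_init=True)
        self.head_reg = Linear(pooled, 1, rng, zero_init=True)

    def fuse(self, f_vp: Tensor, f_ap: Tensor) -> tuple[Tensor, Tensor]:
        """(V_VAF attention weights, fused F_VA) for batched padded inputs (B, d)."""
        h_va = stack([f_vp, f_ap], axis=1)          # (B, 2, d)
        v_va = concatenate([f_vp, f_ap], axis=1)    # (B, 2d)
        z = self.fc(v_va)
        if self.cfg.attention_mode == "modality":
            v_vaf = z.softmax(axis=1)               # (B, 2), sums to 1
            b = f_vp.shape[0]
            f_va = (h_va * v_vaf.reshape(b, 2, 1)).sum(axis=1)
        else:
            gate = z.sigmoid()                      # (B, d) elementwise convex gate
            f_va = gate * f_vp + (1.0 - gate) * f_ap
            v_vaf = gate
        return v_vaf, f_va

    def forward(self, inputs: tuple[np.ndarray, np.ndarray]):
        f_v, f_a = inputs
        f_vp, f_ap = pad_align(f_v, f_a)
        v_vaf, f_va = self.fuse(Tensor(f_vp.astype(np.float32)),
                                Tensor(f_ap.astype(np.float32)))
        pooled = self._pool(f_va)
        dropped = self.dropout(pooled)
        logits = self.head_cls(dropped).reshape(-1)
        phq8 = self.head_reg(dropped).reshape(-1)
        return f_va, logits, phq8

    def _pool(self, f_va: Tensor) -> Tensor:
        k = self.cfg.pool_window
        b, d = f_va.shape
        keep = (d // k) * k
        return f_va[:, :keep].reshape(b, d // k, k).max(axis=2)

    # functional single-vector views (convenience for tests and notebooks) ---
    def fuse_vectors(self, f_vp: np.ndarray, f_ap: np.ndarray) -> np.ndarray:
        """F_VA for a single pair of padded vectors (numpy in/out)."""
        if f_vp.shape != f_ap.shape:
            raise ValueError("padded vectors must have equal length")
        with no_grad():
            _, f_va = self.fuse(Tensor(f_vp[None].astype(np.float32)),
                                Tensor(f_ap[None].astype(np.float32)))
        return f_va.data[0]

    def predict_vector(self, f_va: np.ndarray) -> tuple[float, float]:
        """(logit, phq8 estimate) from one fused vector."""
        pooled = max_pool1d(f_va, self.cfg.pool_window)[None].astype(np.float32)
        with no_grad():
            was_training = self.training
            self.eval()
            logit = self.head_cls(Tensor(pooled)).data[0, 0]
            phq8 = self.head_reg(Tensor(pooled)).data[0, 0]
            self.train(was_training)
        return float(logit), float(phq8)


class VAFNClassifier(DualHeadPredictorMixin, ClassifierMixin, BaseEstimator):
    """Fusion-stage classifier over precomputed branch features.

    ``X`` is a pair ``(F_V, F_A)`` of arrays with shapes (n, d_v) and
    (n, d_a).  The branch backbones stay frozen (staged training, with the
    smaller fusion learning rate); joint fine-tuning is out of scope of
    this estimator and is done by composing the branch estimators.
    """

    def __init__(self, attention_mode="modality", pool_window=4, dropout=0.5,
                 lr=LR_FUSION, iterations=300, batch_size=16, weight_decay=1e-2,
                 loss_weights=(1.0, 1.0), seed=0):
        self.attention_mode = attention_mode
        self.pool_window = pool_window
        self.dropout = dropout
        self.lr = lr
        self.iterations = iterations
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.loss_weights = loss_weights
        self.seed = seed

    def _prepare(self, X):
        f_v, f_a = X
        f_v = np.asarray(f_v, dtype=np.float32)
        f_a = np.asarray(f_a, dtype=np.float32)
        if f_v.shape[0] != f_a.shape[0]:
            raise ValueError("modality feature arrays must align on samples")
        f_v = (f_v - self.video_mean_) / self.video_scale_
        f_a = (f_a - self.audio_mean_) / self.audio_scale_
        return _PairBatch(f_v, f_a)

    def _forward(self, inputs):
        f_va, logits, phq8 = self.model_((inputs.f_v, inputs.f_a))
        return f_va.data, logits.data, phq8.data * self.phq8_scale_ + self.phq8_mean_

    def fit(self, X, y):
        f_v, f_a = X
        f_v = np.asarray(f_v, dtype=np.float32)
        f_a = np.asarray(f_a, dtype=np.float32)
        labels, phq8 = split_targets(y)
        self.classes_ = np.array([0, 1])
        self.video_mean_ = f_v.mean(axis=0)
        self.video_scale_ = f_v.std(axis=0) + 1e-6
        self.audio_mean_ = f_a.mean(axis=0)
        self.audio_scale_ = f_a.std(axis=0) + 1e-6
        self.phq8_mean_ = float(phq8.mean())
        self.phq8_scale_ = float(phq8.std() + 1e-6)
        phq8 = (phq8 - self.phq8_mean_) / self.phq8_scale_
        batch_all = self._prepare((f_v, f_a))

        rng = np.random.default_rng(self.seed & 0x7FFFFFFF)
        self.config_ = VafnConfig(d_video=f_v.shape[1], d_audio=f_a.shape[1],
                                  attention_mode=self.attention_mode,
                                  pool_window=self.pool_window, dropout=self.dropout)
        self.model_ = VafnModel(self.config_, rng)
        cfg = TrainConfig(lr=self.lr, iterations=self.iterations,
                          batch_size=self.batch_size, weight_decay=self.weight_decay,
                          loss_weights=tuple(self.loss_weights), seed=self.seed)
        n = len(batch_all)

        def sampler(batch_rng):
            idx = batch_rng.integers(0, n, size=min(cfg.batch_size, n))
            sub = batch_all[idx]
            return {"inputs": (sub.f_v, sub.f_a), "label": labels[idx], "phq8": phq8[idx]}

        def forward(model, inputs):
            return model(inputs)

        self.history_ = fit_model(self.model_, sampler, forward, cfg)
        self.loss_curve_ = [h["loss"] for h in self.history_]
        self.n_iter_ = self.iterations
        return self


class _PairBatch:
    """Sliceable pair of aligned feature arrays (supports len / slicing)."""

    def __init__(self, f_v: np.ndarray, f_a: np.ndarray):
        self.f_v = f_v
        self.f_a = f_a

    def __len__(self):
        return self.f_v.shape[0]

    def __getitem__(self, idx):
        return _PairBatch(self.f_v[idx], self.f_a[idx])
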