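"""TSNet-DD: a 3-D residual video network with temporal-spatial attention.

The backbone follows the ResNet-18/34 stage layout in 3-D (stem 7×7×7
convolution with stride 1×2×2, then a 3×3×3 max pool with stride 1×2×2,
then four residual stages).  Inside every residual block each of the two
convolution sub-modules is followed by a Temporal-Spatial Attention Module
(TSAM) before the skip addition.  A TSAM is the elementwise sum of two
gated copies of its input:

* the **temporal attention module (TAM)** pools the feature map over
  (T, H, W) by average and max, pushes both 1×1×C descriptors through one
  shared two-layer bottleneck MLP, sums, applies a sigmoid, and rescales
  every channel — ``F_t = F_v ⊙ σ(MLP(avg) + MLP(max))``;
* the **spatial attention module (SAM)** pools over channels by mean and
  max, stacks the two H×W maps, convolves with a 1×k×k kernel (same
  padding) and a sigmoid, and rescales every (t, h, w) position —
  ``F_s = F_v ⊙ σ(conv([mean, max]))``.

With every attention parameter at zero both gates are exactly 0.5, so
``F_ts = 0.5·F_v + 0.5·F_v = F_v`` and the whole network collapses to the
attention-free residual backbone.

The "32"/"64" naming counts TAM and SAM as separate attention modules:
8 blocks × 2 sub-modules × 2 modules = 32 for the ResNet-18 layout, and
16 × 2 × 2 = 64 for ResNet-34.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .autodiff import Tensor, concatenate
from .base import DualHeadPredictorMixin, split_targets
from .nn import Conv3d, Dropout, GroupNorm, Linear, MaxPool3d, Module
from .training import TrainConfig, fit_model, LR_BRANCH

__all__ = ["TsnetConfig", "TemporalAttention", "SpatialAttention", "TSAM",
           "ResidualBlock", "TsnetModel", "TSNetClassifier", "BLOCKS_PER_STAGE"]

BLOCKS_PER_STAGE = {"tsnet32": (2, 2, 2, 2), "tsnet64": (3, 4, 6, 3)}


@dataclass(frozen=True)
class TsnetConfig:
    depth: str = "tsnet32"
    in_channels: int = 3
    base_channels: int = 64
    attention_reduction: int = 16
    sam_kernel: int = 7
    feature_dim: int = 32
    dropout: float = 0.5
    use_tsam: bool = True

    def validate(self) -> None:
        if self.depth not in BLOCKS_PER_STAGE:
            raise ValueError(f"depth must be one of {sorted(BLOCKS_PER_STAGE)}, got {self.depth!r}")
        if not 0.4 <= self.dropout <= 0.6:
            raise ValueError(f"dropout must lie in [0.4, 0.6], got {self.dropout}")
        if self.sam_kernel % 2 == 0:
            raise ValueError(f"sam_kernel must be odd, got {self.sam_kernel}")
        if self.attention_reduction < 1:
            raise ValueError("attention_reduction must be positive")

    @property
    def blocks_per_stage(self) -> tuple[int, ...]:
        return BLOCKS_PER_STAGE[self.depth]

    @property
    def n_blocks(self) -> int:
        return sum(self.blocks_per_stage)

    @property
    def n_attention_modules(self) -> int:
        """TAM and SAM counted separately: blocks × 2 sub-modules × 2."""
        return self.n_blocks * 4

    @property
    def n_tsam(self) -> int:
        """TSAM insertion points: one per conv sub-module."""
        return self.n_blocks * 2


class TemporalAttention(Module):
    """Channel-wise gate from global average + max pooling (CBAM-style)."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"channels ({channels}) must be divisible by attention_reduction ({reduction})")
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def weights(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3, 4))          # (B, C)
        mx = x.max(axis=(2, 3, 4))
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid()                    # (B, C) in (0, 1)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        w = self.weights(x)
        b, c = w.shape
        return w, x * w.reshape(b, c, 1, 1, 1)


class SpatialAttention(Module):
    """Position-wise gate from channel mean + max maps."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"sam_kernel must be odd, got {kernel}")
        pad = kernel // 2
        self.conv = Conv3d(2, 1, (1, kernel, kernel), rng,
                           stride=(1, 1, 1), padding=(0, pad, pad))

    def weights(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)   # (B, 1, T, H, W)
        mx = x.max(axis=1, keepdims=True)
        desc = concatenate([avg, mx], axis=1)
        return self.conv(desc).sigmoid()      # (B, 1, T, H, W)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        w = self.weights(x)
        return w, x * w


class TSAM(Module):
    """Temporal-spatial attention: F_ts = F_t + F_s (shape preserving)."""

    def __init__(self, channels: int, reduction: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.tam = TemporalAttention(channels, reduction, rng)
        self.sam = SpatialAttention(kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        _, f_t = self.tam(x)
        _, f_s = self.sam(x)
        return f_t + f_s

    def zero_parameters(self) -> None:
        for p in self.parameters():
            p.data[...] = 0.0


class ResidualBlock(Module):
    """Two 3×3×3 conv sub-modules, each followed by a TSAM, then the skip."""

    def __init__(self, in_channels: int, out_channels: int, stride, cfg: TsnetConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(in_channels, out_channels, 3, rng, stride=stride,
                            padding=(1, 1, 1), bias=False)
        self.norm1 = GroupNorm(min(8, out_channels), out_channels)
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng, stride=(1, 1, 1),
                            padding=(1, 1, 1), bias=False)
        self.norm2 = GroupNorm(min(8, out_channels), out_channels)
        self.use_tsam = cfg.use_tsam
        if cfg.use_tsam:
            self.tsam1 = TSAM(out_channels, cfg.attention_reduction, cfg.sam_kernel, rng)
            self.tsam2 = TSAM(out_channels, cfg.attention_reduction, cfg.sam_kernel, rng)
        stride = tuple(stride) if isinstance(stride, (tuple, list)) else (stride,) * 3
        if in_channels != out_channels or stride != (1, 1, 1):
            self.proj = Conv3d(in_channels, out_channels, 1, rng, stride=stride,
                               padding=(0, 0, 0), bias=False)
            self.proj_norm = GroupNorm(min(8, out_channels), out_channels)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x))
        if self.use_tsam:
            h = self.tsam1(h)
        h = h.relu()
        h = self.norm2(self.conv2(h))
        if self.use_tsam:
            h = self.tsam2(h)
        skip = x if self.proj is None else self.proj_norm(self.proj(x))
        return (h + skip).relu()


class TsnetModel(Module):
    """Full TSNet-DD: stem → 4 stages → global pool → dropout → dual head."""

    def __init__(self, cfg: TsnetConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c0 = cfg.base_channels
        self.stem_conv = Conv3d(cfg.in_channels, c0, 7, rng, stride=(1, 2, 2),
                                padding=(3, 3, 3))
        self.stem_norm = GroupNorm(min(8, c0), c0)
        self.stem_pool = MaxPool3d(3, stride=(1, 2, 2), padding=(1, 1, 1))
        self.stages: list[ResidualBlock] = []
        channels = c0
        for s, n_blocks in enumerate(cfg.blocks_per_stage):
            out_c = c0 * (2**s)
            for b in range(n_blocks):
                stride = (2, 2, 2) if (s > 0 and b == 0) else (1, 1, 1)
                self.stages.append(ResidualBlock(channels, out_c, stride, cfg, rng))
                channels = out_c
        self.project = Linear(channels, cfg.feature_dim, rng)
        self.dropout = Dropout(cfg.dropout)
        self.head_cls = Linear(cfg.feature_dim, 1, rng, zero_init=True)
        self.head_reg = Linear(cfg.feature_dim, 1, rng, zero_init=True)

    def stem(self, x: Tensor) -> Tensor:
        """7×7×7 stride-(1,2,2) conv then 3×3×3 stride-(1,2,2) max pool → F_v."""
        if x.ndim != 5:
            raise ValueError("clip batch must be (batch, channels, T, H, W)")
        if min(x.shape[3], x.shape[4]) < 32:
            raise ValueError(
                f"spatial dims must be at least 32 to survive the stem, got {x.shape[3:]}")
        return self.stem_pool(self.stem_norm(self.stem_conv(x)).relu())

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Return (F_V (B, feature_dim), logits (B,), phq8 estimate (B,))."""
        h = self.stem(x)
        self._check_finite(h, "stem")
        for i, block in enumerate(self.stages):
            h = block(h)
            self._check_finite(h, f"stage block {i}")
        pooled = h.mean(axis=(2, 3, 4))
        feat = self.project(pooled)
        dropped = self.dropout(feat)
        logits = self.head_cls(dropped).reshape(-1)
        phq8 = self.head_reg(dropped).reshape(-1)
        return feat, logits, phq8

    @staticmethod
    def _check_finite(t: Tensor, stage: str) -> None:
        if not np.all(np.isfinite(t.data)):
            raise RuntimeError(f"non-finite activations in {stage}")

    def zero_attention_parameters(self) -> None:
        """Zero every TAM/SAM parameter: the network becomes the plain backbone."""
        for m in self.modules():
            if isinstance(m, TSAM):
                m.zero_parameters()


class TSNetClassifier(DualHeadPredictorMixin, ClassifierMixin, BaseEstimator):
    """Depression screening from facial-video clips (scikit-learn API).

    ``X`` is (n_clips, frames, height, width, channels) with pixel values
    in [0, 1]; ``y`` is either binary labels (n,) or (n, 2) columns
    [label, phq8].  The fitted model exposes ``transform`` for the pooled
    visual feature vector F_V consumed by the fusion network.
    """

    def __init__(self, depth="tsnet32", base_channels=8, attention_reduction=4,
                 sam_kernel=7, feature_dim=32, dropout=0.5, use_tsam=True,
                 lr=LR_BRANCH, iterations=300, batch_size=8, weight_decay=1e-2,
                 loss_weights=(1.0, 1.0), seed=0):
        self.depth = depth
        self.base_channels = base_channels
        self.attention_reduction = attention_reduction
        self.sam_kernel = sam_kernel
        self.feature_dim = feature_dim
        self.dropout = dropout
        self.use_tsam = use_tsam
        self.lr = lr
        self.iterations = iterations
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.loss_weights = loss_weights
        self.seed = seed

    def _net_config(self, in_channels: int) -> TsnetConfig:
        return TsnetConfig(
            depth=self.depth, in_channels=in_channels,
            base_channels=self.base_channels,
            attention_reduction=self.attention_reduction,
            sam_kernel=self.sam_kernel, feature_dim=self.feature_dim,
            dropout=self.dropout, use_tsam=self.use_tsam,
        )

    @staticmethod
    def _to_internal(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 5:
            raise ValueError("X must be (n, frames, height, width, channels)")
        return np.ascontiguousarray(X.transpose(0, 4, 1, 2, 3))

    def _prepare(self, X) -> np.ndarray:
        clips = self._to_internal(X)
        return (clips - self.pixel_mean_) / self.pixel_scale_

    def _forward(self, inputs: np.ndarray):
        feat, logits, phq8 = self.model_(Tensor(inputs))
        return feat.data, logits.data, phq8.data * self.phq8_scale_ + self.phq8_mean_

    def fit(self, X, y):
        clips = self._to_internal(X)
        labels, phq8 = split_targets(y)
        if clips.shape[0] != labels.size:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array([0, 1])
        # per-channel standardisation with training statistics
        self.pixel_mean_ = clips.mean(axis=(0, 2, 3, 4), keepdims=True)
        self.pixel_scale_ = clips.std(axis=(0, 2, 3, 4), keepdims=True) + 1e-6
        data = (clips - self.pixel_mean_) / self.pixel_scale_
        # regression trains on the z-scored severity so the MSE term is
        # commensurate with the BCE term; predictions are un-scaled
        self.phq8_mean_ = float(phq8.mean())
        self.phq8_scale_ = float(phq8.std() + 1e-6)
        phq8 = (phq8 - self.phq8_mean_) / self.phq8_scale_

        rng = np.random.default_rng(self.seed & 0x7FFFFFFF)
        self.config_ = self._net_config(in_channels=clips.shape[1])
        self.model_ = TsnetModel(self.config_, rng)
        cfg = TrainConfig(lr=self.lr, iterations=self.iterations,
                          batch_size=self.batch_size, weight_decay=self.weight_decay,
                          loss_weights=tuple(self.loss_weights), seed=self.seed)

        n = data.shape[0]

        def sampler(batch_rng):
            idx = batch_rng.integers(0, n, size=min(cfg.batch_size, n))
            return {"inputs": data[idx], "label": labels[idx], "phq8": phq8[idx]}

        def forward(model, inputs):
            return model(Tensor(inputs))

        self.history_ = fit_model(self.model_, sampler, forward, cfg)
        self.loss_curve_ = [h["loss"] for h in self.history_]
        self.n_iter_ = self.iterations
        return self
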