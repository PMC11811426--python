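"""GCN-LSTM over the MFCC frame-similarity graph.

Graph convolutions use the symmetric-normalised propagation rule with
self-loops, ``Â = D̃^{-1/2} (A_w + I) D̃^{-1/2}`` with ``A_w`` the weighted
adjacency and ``D̃`` the degree of ``A_w + I``; each layer computes
``ReLU(Â X W)``.  The resulting node embeddings, kept in temporal frame
order (optionally subsampled with a fixed stride), feed a single-layer
LSTM whose final hidden state — after dropout — drives the usual dual
head (binary logit + PHQ-8 estimate).  An edgeless graph reduces every
layer to ``ReLU(X W)`` since ``Â = I``.

Ablation variants: ``gcn_only`` replaces the LSTM with a temporal mean
pool over node embeddings; ``lstm_only`` feeds raw node features straight
to the LSTM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .audio_features import AudioGraph
from .autodiff import Tensor
from .base import DualHeadPredictorMixin, split_targets
from .nn import Dropout, LSTM, Linear, Module, _param
from .training import TrainConfig, fit_model, LR_BRANCH

__all__ = ["GcnLstmConfig", "normalized_adjacency", "GcnLayer", "GcnLstmModel",
           "GCNLSTMClassifier"]

_VARIANTS = ("gcn_lstm", "gcn_only", "lstm_only")


@dataclass(frozen=True)
class GcnLstmConfig:
    n_mfcc: int = 13
    gcn_layers: int = 2
    gcn_hidden: int = 16
    lstm_hidden: int = 32
    feature_dim: int = 24
    dropout: float = 0.5
    subsample: int = 1           # temporal stride over node embeddings
    variant: str = "gcn_lstm"

    def validate(self) -> None:
        if self.gcn_layers < 1:
            raise ValueError("gcn_layers must be >= 1")
        if not 0.4 <= self.dropout <= 0.6:
            raise ValueError(f"dropout must lie in [0.4, 0.6], got {self.dropout}")
        if self.subsample < 1:
            raise ValueError("subsample stride must be >= 1")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")


def normalized_adjacency(graph: AudioGraph) -> np.ndarray:
    """Dense Â = D̃^{-1/2}(A_w + I)D̃^{-1/2}; rows of a unit-weight regular
    graph sum to 1."""
    a = graph.adjacency() + np.eye(graph.n_nodes)
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return (a * inv_sqrt[:, None]) * inv_sqrt[None, :]


class GcnLayer(Module):
    """One graph convolution: ReLU(Â X W) (no bias, per the spectral rule)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = _param(rng.normal(0.0, std, size=(in_features, out_features)).astype(np.float32))

    def forward(self, a_hat: np.ndarray, x: Tensor) -> Tensor:
        return (Tensor(a_hat.astype(np.float32)) @ (x @ self.weight)).relu()


class GcnLstmModel(Module):
    def __init__(self, cfg: GcnLstmConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.gcn_layers: list[GcnLayer] = []
        if cfg.variant != "lstm_only":
            dim = cfg.n_mfcc
            for _ in range(cfg.gcn_layers):
                self.gcn_layers.append(GcnLayer(dim, cfg.gcn_hidden, rng))
                dim = cfg.gcn_hidden
            seq_dim = cfg.gcn_hidden
        else:
            seq_dim = cfg.n_mfcc
        if cfg.variant != "gcn_only":
            self.lstm = LSTM(seq_dim, cfg.lstm_hidden, rng)
            readout_dim = cfg.lstm_hidden
        else:
            self.lstm = None
            readout_dim = seq_dim
        self.project = Linear(readout_dim, cfg.feature_dim, rng)
        self.dropout = Dropout(cfg.dropout)
        self.head_cls = Linear(cfg.feature_dim, 1, rng, zero_init=True)
        self.head_reg = Linear(cfg.feature_dim, 1, rng, zero_init=True)

    def node_embeddings(self, graph_input: tuple[np.ndarray, np.ndarray]) -> Tensor:
        """Stacked graph convolutions for one graph -> (n_nodes, hidden)."""
        a_hat, feats = graph_input
        h = Tensor(feats.astype(np.float32))
        for layer in self.gcn_layers:
            h = layer(a_hat, h)
        return h

    def forward(self, graph_inputs: list) -> tuple[Tensor, Tensor, Tensor]:
        """graph_inputs: list of (Â, node features, node_order) per sample.

        Returns (F_A (B, feature_dim), logits (B,), phq8 (B,)).
        """
        cfg = self.cfg
        seqs = []
        lengths = []
        for a_hat, feats, order in graph_inputs:
            if feats.shape[0] == 0:
                raise ValueError("empty graph")
            h = self.node_embeddings((a_hat, feats)) if cfg.variant != "lstm_only" \
                else Tensor(feats.astype(np.float32))
            # restore temporal order, then subsample with a fixed stride
            idx = np.argsort(np.asarray(order))[:: cfg.subsample]
            h = h[idx]
            seqs.append(h)
            lengths.append(h.shape[0])

        max_len = max(lengths)
        from .autodiff import pad as ad_pad, stack as ad_stack
        padded = [ad_pad(s, ((0, max_len - s.shape[0]), (0, 0))) if s.shape[0] < max_len else s
                  for s in seqs]
        batch = ad_stack(padded, axis=0)        # (B, S, F)
        if cfg.variant == "gcn_only":
            mask = np.zeros((len(seqs), max_len, 1), dtype=np.float32)
            for i, ln in enumerate(lengths):
                mask[i, :ln, 0] = 1.0
            summed = (batch * Tensor(mask)).sum(axis=1)
            readout = summed * Tensor(1.0 / np.asarray(lengths, dtype=np.float32)[:, None])
        else:
            mask = np.zeros((len(seqs), max_len), dtype=np.float32)
            for i, ln in enumerate(lengths):
                mask[i, :ln] = 1.0
            _, readout = self.lstm(batch, mask)
        feat = self.project(readout)
        dropped = self.dropout(feat)
        logits = self.head_cls(dropped).reshape(-1)
        phq8 = self.head_reg(dropped).reshape(-1)
        return feat, logits, phq8


def gcn_layer_forward(x: np.ndarray, graph: AudioGraph, weight: np.ndarray) -> np.ndarray:
    """Functional single graph-convolution: ReLU(Â X W) as plain numpy."""
    if x.shape[0] != graph.n_nodes:
        raise ValueError("node feature row count must equal graph node count")
    a_hat = normalized_adjacency(graph)
    return np.maximum(a_hat @ x @ weight, 0.0)


class GCNLSTMClassifier(DualHeadPredictorMixin, ClassifierMixin, BaseEstimator):
    """Depression screening from audio-frame graphs (scikit-learn API).

    ``X`` is a sequence of :class:`~mmdepnet.audio_features.AudioGraph`;
    node features are z-scored with statistics pooled over the training
    graphs before entering the GCN (graph topology is fixed upstream).
    """

    def __init__(self, gcn_layers=2, gcn_hidden=16, lstm_hidden=32, feature_dim=24,
                 dropout=0.5, subsample=1, variant="gcn_lstm",
                 lr=LR_BRANCH, iterations=300, batch_size=8, weight_decay=1e-2,
                 loss_weights=(1.0, 1.0), seed=0):
        self.gcn_layers = gcn_layers
        self.gcn_hidden = gcn_hidden
        self.lstm_hidden = lstm_hidden
        self.feature_dim = feature_dim
        self.dropout = dropout
        self.subsample = subsample
        self.variant = variant
        self.lr = lr
        self.iterations = iterations
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.loss_weights = loss_weights
        self.seed = seed

    def _prepare(self, X) -> list:
        inputs = []
        for g in X:
            feats = (g.node_features - self.feature_mean_) / self.feature_scale_
            inputs.append((normalized_adjacency(g), feats, g.node_order))
        return inputs

    def _forward(self, inputs: list):
        feat, logits, phq8 = self.model_(inputs)
        return feat.data, logits.data, phq8.data * self.phq8_scale_ + self.phq8_mean_

    def fit(self, X, y):
        graphs = list(X)
        labels, phq8 = split_targets(y)
        if len(graphs) != labels.size:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array([0, 1])
        all_feats = np.vstack([g.node_features for g in graphs])
        self.feature_mean_ = all_feats.mean(axis=0)
        self.feature_scale_ = all_feats.std(axis=0) + 1e-6
        self.phq8_mean_ = float(phq8.mean())
        self.phq8_scale_ = float(phq8.std() + 1e-6)
        phq8 = (phq8 - self.phq8_mean_) / self.phq8_scale_
        inputs = self._prepare(graphs)

        rng = np.random.default_rng(self.seed & 0x7FFFFFFF)
        self.config_ = GcnLstmConfig(
            n_mfcc=graphs[0].node_features.shape[1], gcn_layers=self.gcn_layers,
            gcn_hidden=self.gcn_hidden, lstm_hidden=self.lstm_hidden,
            feature_dim=self.feature_dim, dropout=self.dropout,
            subsample=self.subsample, variant=self.variant,
        )
        self.model_ = GcnLstmModel(self.config_, rng)
        cfg = TrainConfig(lr=self.lr, iterations=self.iterations,
                          batch_size=self.batch_size, weight_decay=self.weight_decay,
                          loss_weights=tuple(self.loss_weights), seed=self.seed)
        n = len(inputs)

        def sampler(batch_rng):
            idx = batch_rng.integers(0, n, size=min(cfg.batch_size, n))
            return {"inputs": [inputs[i] for i in idx],
                    "label": labels[idx], "phq8": phq8[idx]}

        def forward(model, batch_inputs):
            return model(batch_inputs)

        self.history_ = fit_model(self.model_, sampler, forward, cfg)
        self.loss_curve_ = [h["loss"] for h in self.history_]
        self.n_iter_ = self.iterations
        return self
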