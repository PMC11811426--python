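"""Optimisation loop shared by all three networks.

AdamW with a linear learning-rate decay, a joint objective (binary
cross-entropy on the depression label plus mean-squared error on the
PHQ-8 severity score), divergence detection, and a structured metric log.
Defaults mirror the reference training recipe: lr 1e-4 for the modality
branches, 5e-5 for fusion, 5000 iterations, dropout in [0.4, 0.6].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import AdamW, Module

__all__ = ["TrainConfig", "joint_loss", "fit_model", "bce_with_logits"]

LR_BRANCH = 1e-4
LR_FUSION = 5e-5


@dataclass
class TrainConfig:
    lr: float = LR_BRANCH
    iterations: int = 5000
    batch_size: int = 8
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-2
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (classification, regression)
    schedule: str = "linear"
    seed: int = 0
    log_every: int = 50
    divergence_threshold: float = 1e6

    def validate(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.schedule not in ("linear", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")

    def lr_at(self, iteration: int) -> float:
        if self.schedule == "constant":
            return self.lr
        return self.lr * (1.0 - iteration / max(self.iterations, 1))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from raw logits."""
    y = Tensor(np.asarray(targets, dtype=np.float32))
    absz = logits.relu() + (-logits).relu()
    # log(1 + e^-|z|) + max(z, 0) - z*y
    return (logits.relu() - logits * y + ((-absz).exp() + 1.0).log()).mean()


def joint_loss(logits: Tensor, phq8_estimate: Tensor, label: np.ndarray,
               phq8: np.ndarray, loss_weights: tuple[float, float] = (1.0, 1.0)) -> Tensor:
    """λ_cls · BCE(label) + λ_reg · MSE(PHQ-8)."""
    lam_cls, lam_reg = loss_weights
    loss = None
    if lam_cls:
        loss = lam_cls * bce_with_logits(logits, label)
    if lam_reg:
        resid = phq8_estimate - Tensor(np.asarray(phq8, dtype=np.float32))
        mse = (resid * resid).mean()
        loss = lam_reg * mse if loss is None else loss + lam_reg * mse
    if loss is None:
        raise ValueError("both loss weights are zero")
    if not np.isfinite(loss.data):
        raise FloatingPointError("joint loss is NaN/inf")
    return loss


def fit_model(model: Module, sampler, forward, cfg: TrainConfig) -> list[dict]:
    """Generic training loop.

    ``sampler(rng)`` returns a batch dict with keys ``inputs`` (anything the
    forward understands), ``label`` and ``phq8`` (numpy vectors);
    ``forward(model, inputs)`` returns ``(features, logits, phq8_estimate)``.
    Returns the per-interval metric log.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    for m in model.modules():
        if hasattr(m, "rng") and hasattr(m, "p"):  # reseed dropout masks
            m.rng = np.random.default_rng((cfg.seed & 0x7FFFFFFF) + 1)
    opt = AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    history: list[dict] = []
    model.train()
    for it in range(cfg.iterations):
        batch = sampler(rng)
        _, logits, phq8_est = forward(model, batch["inputs"])
        loss = joint_loss(logits, phq8_est, batch["label"], batch["phq8"],
                          cfg.loss_weights)
        if float(loss.data) > cfg.divergence_threshold:
            raise RuntimeError(f"training diverged at iteration {it}: loss={float(loss.data):.3g}")
        opt.zero_grad()
        loss.backward()
        opt.step(lr=cfg.lr_at(it))
        if it % cfg.log_every == 0 or it == cfg.iterations - 1:
            history.append({"iteration": it, "loss": float(loss.data),
                            "lr": cfg.lr_at(it)})
    model.eval()
    return history
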