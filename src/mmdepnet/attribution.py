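"""Integrated-gradients attribution.

Attributions are the straight-path integral of model gradients from a
baseline to the input, approximated by a midpoint Riemann sum:

    IG_i(x) = (x_i - b_i) * (1/m) * Σ_k ∂f/∂x_i evaluated at b + (k-½)/m (x-b)

The method satisfies completeness (Σ IG = f(x) - f(baseline)) in the limit,
is exact for linear models at any number of steps, and vanishes when the
input equals the baseline.  For long per-frame recordings, attributions can
be aggregated over fixed-size frame windows (default 100 frames).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .autodiff import Tensor

__all__ = ["integrated_gradients", "aggregate_frames", "read_feature_table",
           "FEATURE_GROUPS"]

# E-DAIC-style per-frame table column prefixes (OpenFace-like naming)
FEATURE_GROUPS = {
    "au": ("AU",),
    "gaze": ("gaze",),
    "pose": ("pose",),
}


def integrated_gradients(f, x: np.ndarray, baseline: np.ndarray | None = None,
                         steps: int = 64) -> np.ndarray:
    """Attribution map of the scalar-valued differentiable ``f`` at ``x``.

    ``f`` maps a :class:`Tensor` of ``x``'s shape (or a batch of them) to a
    scalar Tensor (sum over the batch is fine — gradients separate).
    ``baseline`` defaults to zeros.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    x = np.asarray(x, dtype=np.float32)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=np.float32)
    if b.shape != x.shape:
        raise ValueError(f"baseline shape {b.shape} != input shape {x.shape}")

    total = np.zeros_like(x, dtype=np.float64)
    delta = x - b
    for k in range(1, steps + 1):
        alpha = (k - 0.5) / steps
        point = Tensor(b + alpha * delta)
        point.requires_grad = True
        out = f(point)
        if out.size != 1:
            out = out.sum()
        out.backward()
        total += point.grad
    return delta.astype(np.float64) * (total / steps)


def aggregate_frames(attributions: np.ndarray, window: int = 100) -> np.ndarray:
    """Sum attributions over consecutive frame windows along axis 0.

    A trailing partial window is kept (summed as-is), so totals are
    preserved: ``aggregate_frames(a).sum() == a.sum()``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a = np.asarray(attributions)
    n = a.shape[0]
    bounds = list(range(0, n, window)) + [n]
    return np.stack([a[lo:hi].sum(axis=0) for lo, hi in zip(bounds[:-1], bounds[1:])])


def read_feature_table(path, groups: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Read an E-DAIC-style per-frame feature table (delimited text).

    Columns are assigned to named groups by prefix match (case-insensitive,
    whitespace-stripped); ungrouped numeric columns are ignored.  Returns
    (numeric frame × feature DataFrame, {group: [column, ...]}).
    """
    table = pd.read_csv(path)
    table.columns = [c.strip() for c in table.columns]
    groups = groups or FEATURE_GROUPS
    assignment: dict[str, list[str]] = {g: [] for g in groups}
    for col in table.columns:
        low = col.lower()
        for g, prefixes in groups.items():
            if any(low.startswith(p.lower()) for p in prefixes):
                assignment[g].append(col)
                break
    used = [c for cols in assignment.values() for c in cols]
    numeric = table[used].apply(pd.to_numeric, errors="coerce")
    return numeric, {g: cols for g, cols in assignment.items() if cols}
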