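"""Neural-network building blocks (numpy + the in-package autodiff tape).

Layers follow the usual conventions: activations are ``(batch, channels,
time, height, width)`` for video feature maps, ``(batch, features)`` for
vectors and ``(batch, steps, features)`` for sequences.  Every layer takes a
``numpy.random.Generator`` for weight initialisation so whole networks are
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor, _accum, as_tensor, concatenate

__all__ = [
    "Module", "Linear", "Conv3d", "MaxPool3d", "GroupNorm", "Dropout",
    "LSTM", "AdamW", "conv3d", "max_pool3d",
]


def _triple(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


class Module:
    """Minimal container with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(arr: np.ndarray) -> Tensor:
    t = Tensor(arr)
    t.requires_grad = True
    return t


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            std = np.sqrt(2.0 / in_features)
            w = rng.normal(0.0, std, size=(in_features, out_features))
        self.weight = _param(w.astype(np.float32))
        self.bias = _param(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# ---------------------------------------------------------------------------
# 3-D convolution / pooling as first-class autodiff ops
# ---------------------------------------------------------------------------

def _windows(x: np.ndarray, kernel: tuple, stride: tuple) -> np.ndarray:
    """Strided sliding-window view (B,C,D',H',W',kt,kh,kw) — no copy."""
    win = sliding_window_view(x, kernel, axis=(2, 3, 4))
    return win[:, :, ::stride[0], ::stride[1], ::stride[2]]


def _corr3d(x: np.ndarray, w: np.ndarray, stride: tuple) -> np.ndarray:
    """Valid cross-correlation of ``x`` (B,C,D,H,W) with ``w`` (Co,Ci,kt,kh,kw)."""
    win = _windows(x, w.shape[2:], stride)
    return np.einsum("bcdhwxyz,ocxyz->bodhw", win, w, optimize=True)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride=(1, 1, 1),
           padding=(0, 0, 0)) -> Tensor:
    """Strided, zero-padded 3-D cross-correlation (the deep-learning "conv").

    Implemented as im2col + BLAS matmul; the gathered column matrix is kept
    on the tape and reused for the weight gradient, so the expensive window
    copy happens once per call.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    st = _triple(stride)
    pt, ph, pw = _triple(padding)
    kt, kh, kw = weight.data.shape[2:]
    co, ci = weight.data.shape[:2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    win = _windows(xp, (kt, kh, kw), st)
    b, _, dp, hp, wp = win.shape[:5]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        b * dp * hp * wp, ci * kt * kh * kw)
    out_data = (cols @ weight.data.reshape(co, -1).T).reshape(
        b, dp, hp, wp, co).transpose(0, 4, 1, 2, 3)
    out_data = np.ascontiguousarray(out_data)
    if bias is not None:
        out_data += bias.data[None, :, None, None, None]

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        g = np.asarray(g)
        pairs = []
        if weight.requires_grad:
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, co)
            gw = (g2.T @ cols).reshape(weight.data.shape)
            pairs.append((weight, gw))
        if bias is not None and bias.requires_grad:
            pairs.append((bias, g.sum(axis=(0, 2, 3, 4))))
        if x.requires_grad:
            # gradient w.r.t. input = stride-dilated grad correlated with the
            # channel-swapped, spatially flipped kernel (transposed convolution)
            full = tuple(d - k + 1 for d, k in zip(xp.shape[2:], (kt, kh, kw)))
            gdil = np.zeros((b, co) + full, dtype=np.float32)
            gdil[:, :, ::st[0], ::st[1], ::st[2]] = g
            gpad = np.pad(gdil, ((0, 0), (0, 0), (kt - 1, kt - 1),
                                 (kh - 1, kh - 1), (kw - 1, kw - 1)))
            wflip = weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            gx_pad = _corr3d(gpad, np.ascontiguousarray(wflip), (1, 1, 1))
            gx = gx_pad[:, :, pt:gx_pad.shape[2] - pt or None,
                        ph:gx_pad.shape[3] - ph or None,
                        pw:gx_pad.shape[4] - pw or None]
            pairs.append((x, gx))
        _accum(pairs)

    return Tensor._result(out_data, parents, backward)


def max_pool3d(x: Tensor, kernel=(3, 3, 3), stride=(1, 1, 1), padding=(0, 0, 0)) -> Tensor:
    x = as_tensor(x)
    kt, kh, kw = _triple(kernel)
    st, sh, sw = _triple(stride)
    pt, ph, pw = _triple(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))[:, :, ::st, ::sh, ::sw]
    b, c, dp, hp, wp = win.shape[:5]
    flat = win.reshape(b, c, dp, hp, wp, kt * kh * kw)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        ot, oh, ow = np.unravel_index(idx, (kt, kh, kw))
        bi, ci, ti, hi, wi = np.meshgrid(
            np.arange(b), np.arange(c), np.arange(dp), np.arange(hp), np.arange(wp),
            indexing="ij",
        )
        gpad = np.zeros_like(xp)
        np.add.at(gpad, (bi, ci, ti * st + ot, hi * sh + oh, wi * sw + ow), np.asarray(g))
        gx = gpad[:, :, pt:gpad.shape[2] - pt or None,
                  ph:gpad.shape[3] - ph or None,
                  pw:gpad.shape[4] - pw or None]
        _accum(((x, gx),))

    return Tensor._result(out_data, (x,), backward)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 rng: np.random.Generator, stride=(1, 1, 1), padding=(0, 0, 0),
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        k = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = in_channels * int(np.prod(k))
        if zero_init:
            w = np.zeros((out_channels, in_channels) + k)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels) + k)
        self.weight = _param(w.astype(np.float32))
        self.bias = _param(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class MaxPool3d(Module):
    def __init__(self, kernel_size, stride, padding=(0, 0, 0)):
        super().__init__()
        self.kernel = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)

    def forward(self, x: Tensor) -> Tensor:
        return max_pool3d(x, self.kernel, self.stride, self.padding)


class GroupNorm(Module):
    """Group normalisation over (channel-group, T, H, W); batch-size free."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("num_channels must be divisible by num_groups")
        self.groups = num_groups
        self.eps = eps
        self.gamma = _param(np.ones(num_channels, dtype=np.float32))
        self.beta = _param(np.zeros(num_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[:2]
        rest = x.shape[2:]
        xg = x.reshape(b, self.groups, -1)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        xn = xn.reshape((b, c) + rest)
        shape = (1, c) + (1,) * len(rest)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng = np.random.default_rng(0)  # reseeded by the training loop

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class LSTM(Module):
    """Single-layer LSTM; consumes (batch, steps, features), supports masking.

    Gate layout in the stacked weight matrices is (input, forget, cell,
    output).  The forget-gate bias starts at 1, the usual remedy for early
    gradient vanishing on long sequences.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        s = 1.0 / np.sqrt(hidden_size)
        self.w_ih = _param(rng.uniform(-s, s, size=(input_size, 4 * hidden_size)).astype(np.float32))
        self.w_hh = _param(rng.uniform(-s, s, size=(hidden_size, 4 * hidden_size)).astype(np.float32))
        b = np.zeros(4 * hidden_size, dtype=np.float32)
        b[hidden_size:2 * hidden_size] = 1.0
        self.bias = _param(b)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
        """Return (all hidden states (B,S,H), final hidden state (B,H)).

        ``mask`` is (B, S) with 1 for real steps; masked steps leave the
        state untouched, so the final state is the state at each sequence's
        true length.
        """
        b, steps, _ = x.shape
        hsize = self.hidden_size
        h = Tensor(np.zeros((b, hsize), dtype=np.float32))
        c = Tensor(np.zeros((b, hsize), dtype=np.float32))
        outs = []
        for t in range(steps):
            xt = x[:, t, :]
            gates = xt @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, :hsize].sigmoid()
            f = gates[:, hsize:2 * hsize].sigmoid()
            g = gates[:, 2 * hsize:3 * hsize].tanh()
            o = gates[:, 3 * hsize:].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            if mask is not None:
                mt = Tensor(mask[:, t:t + 1].astype(np.float32))
                c = mt * c_new + (1.0 - mt) * c
                h = mt * h_new + (1.0 - mt) * h
            else:
                c, h = c_new, h_new
            outs.append(h.reshape(b, 1, hsize))
        return concatenate(outs, axis=1), h


class AdamW(Module):
    """Decoupled-weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        super().__init__()
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data

    def zero_grad(self):
        for p in self.params:
            p.grad = None
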