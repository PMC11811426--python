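"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps a float32
ndarray, records the operations applied to it, and :meth:`Tensor.backward`
replays the tape in reverse topological order.  Only the operations the
networks in this package need are implemented; each op states its
vector-Jacobian product in closed form, so gradients are exact up to
floating point.

Broadcasting follows numpy semantics; gradients of broadcast operands are
reduced back to the operand's shape by summing over the broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "pad", "as_tensor", "no_grad"]

_DTYPE = np.float32


class _NoGrad:
    """Context manager that disables tape recording (evaluation mode)."""

    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` to ``shape`` by summing over axes numpy broadcast."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus (optionally) a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=_DTYPE)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if p.requires_grad)
        if parents and not _NoGrad._active:
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            _accum(((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape))))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, (self,), lambda g: _accum(((self, -g),)))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            pairs = []
            if self.requires_grad:
                pairs.append((self, _unbroadcast(g * other.data, self.data.shape)))
            if other.requires_grad:
                pairs.append((other, _unbroadcast(g * self.data, other.data.shape)))
            _accum(pairs)

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            pairs = []
            if self.requires_grad:
                pairs.append((self, _unbroadcast(g / other.data, self.data.shape)))
            if other.requires_grad:
                pairs.append((other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)))
            _accum(pairs)

        return Tensor._result(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            _accum(((self, g * p * self.data ** (p - 1)),))

        return Tensor._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out_data = a @ b
        # promote 1-D operands so the vector-Jacobian products below are uniform
        a2 = a[None, :] if a.ndim == 1 else a
        b2 = b[:, None] if b.ndim == 1 else b

        def backward(g):
            g2 = np.asarray(g)
            if a.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            if b.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            pairs = []
            if self.requires_grad:
                ga = g2 @ np.swapaxes(b2, -1, -2)
                if a.ndim == 1:
                    ga = ga.reshape(a.shape) if ga.ndim == 2 else ga.sum(axis=tuple(range(ga.ndim - 2))).reshape(a.shape)
                else:
                    ga = _unbroadcast(ga, a.shape)
                pairs.append((self, ga))
            if other.requires_grad:
                gb = np.swapaxes(a2, -1, -2) @ g2
                if b.ndim == 1:
                    gb = gb.reshape(b.shape) if gb.ndim == 2 else gb.sum(axis=tuple(range(gb.ndim - 2))).reshape(b.shape)
                else:
                    gb = _unbroadcast(gb, b.shape)
                pairs.append((other, gb))
            _accum(pairs)

        return Tensor._result(out_data, (self, other), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            _accum(((self, np.broadcast_to(gg, self.data.shape).copy()),))

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            full = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
            mask = (self.data == full).astype(_DTYPE)
            mask /= mask.sum(axis=axis, keepdims=True)  # ties share the gradient
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            _accum(((self, mask * gg),))

        return Tensor._result(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            _accum(((self, np.asarray(g).reshape(self.data.shape)),))

        return Tensor._result(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            _accum(((self, np.asarray(g).transpose(inv)),))

        return Tensor._result(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, idx, g)
            _accum(((self, gi),))

        return Tensor._result(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            _accum(((self, g * out_data),))

        return Tensor._result(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            _accum(((self, g / self.data),))

        return Tensor._result(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            _accum(((self, g * 0.5 / out_data),))

        return Tensor._result(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            _accum(((self, g * (1.0 - out_data**2)),))

        return Tensor._result(out_data, (self,), backward)

    def sigmoid(self):
        # numerically stable logistic
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        out_data[~pos] = e / (1.0 + e)

        def backward(g):
            _accum(((self, g * out_data * (1.0 - out_data)),))

        return Tensor._result(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            _accum(((self, g * (self.data > 0)),))

        return Tensor._result(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            _accum(((self, out_data * (g - dot)),))

        return Tensor._result(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward() on a tensor that does not require grad")
        topo = _toposort(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=_DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    state: dict[int, int] = {}
    stack_ = [(root, iter(root._parents))]
    state[id(root)] = 1
    while stack_:
        node, it = stack_[-1]
        advanced = False
        for p in it:
            sid = state.get(id(p), 0)
            if sid == 0:
                state[id(p)] = 1
                stack_.append((p, iter(p._parents)))
                advanced = True
                break
        if not advanced:
            stack_.pop()
            state[id(node)] = 2
            order.append(node)
    return order


def _accum(pairs) -> None:
    for tensor, grad in pairs:
        if not tensor.requires_grad:
            continue
        g = np.asarray(grad, dtype=_DTYPE)
        if tensor.grad is None:
            tensor.grad = g.copy()
        else:
            tensor.grad += g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(np.asarray(g), splits, axis=axis)
        _accum(tuple(zip(tensors, parts)))

    return Tensor._result(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.split(np.asarray(g), len(tensors), axis=axis)
        _accum(tuple((t, np.squeeze(p, axis=axis)) for t, p in zip(tensors, parts)))

    return Tensor._result(out_data, tuple(tensors), backward)


def pad(t: Tensor, pad_width) -> Tensor:
    """Zero-pad; ``pad_width`` follows :func:`numpy.pad` convention."""
    t = as_tensor(t)
    out_data = np.pad(t.data, pad_width)
    slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, t.data.shape))

    def backward(g):
        _accum(((t, np.asarray(g)[slices]),))

    return Tensor._result(out_data, (t,), backward)
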