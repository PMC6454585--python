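"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a recurrent tagger: broadcast-aware arithmetic,
matmul, pointwise nonlinearities, reductions with a stabilized log-sum-exp,
fancy indexing (scatter-add on the way back) and concatenation.  Everything
is float64; graphs are built eagerly and freed when the output goes out of
scope.  Gradients are exact (no approximations), which the test suite
verifies against central finite differences.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "div",
    "matmul",
    "tanh",
    "sigmoid",
    "exp",
    "log",
    "tsum",
    "logsumexp",
    "softmax",
    "inner_last",
    "concatenate",
    "stack",
    "reshape",
    "expand_dims",
    "squeeze",
    "swapaxes",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core -------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and (p.requires_grad or p._parents):
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _wants(p: Tensor) -> bool:
    return p.requires_grad or bool(p._parents)


# -- arithmetic --------------------------------------------------------
def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if _wants(a):
            a._accum(_unbroadcast(g, a.data.shape))
        if _wants(b):
            b._accum(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if _wants(a):
            a._accum(_unbroadcast(g, a.data.shape))
        if _wants(b):
            b._accum(_unbroadcast(-g, b.data.shape))

    return _node(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if _wants(a):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if _wants(b):
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if _wants(a):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if _wants(b):
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _node(a.data / b.data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if _wants(a):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if _wants(b):
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))

    return _node(np.matmul(a.data, b.data), (a, b), backward)


# -- pointwise ---------------------------------------------------------
def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        if _wants(a):
            a._accum(g * (1.0 - out_data ** 2))

    return _node(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if _wants(a):
            a._accum(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if _wants(a):
            a._accum(g * out_data)

    return _node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if _wants(a):
            a._accum(g / a.data)

    return _node(np.log(a.data), (a,), backward)


# -- reductions --------------------------------------------------------
def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if not _wants(a):
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def logsumexp(a, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis``.

    The shift constant is detached, so the gradient is exactly the softmax
    of the inputs along ``axis``.
    """
    a = _as_tensor(a)
    m = np.max(a.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = sub(a, Tensor(m))
    out = add(log(tsum(exp(shifted), axis=axis, keepdims=True)), Tensor(m))
    if not keepdims:
        out = squeeze(out, axis)
    return out


def softmax(a, axis: int) -> Tensor:
    return exp(sub(a, logsumexp(a, axis=axis, keepdims=True)))


def inner_last(a, w) -> Tensor:
    """Contract the last axis of ``a`` (..., k) with a vector ``w`` (k,)."""
    a, w = _as_tensor(a), _as_tensor(w)

    def backward(g):
        if _wants(a):
            a._accum(g[..., None] * w.data)
        if _wants(w):
            k = a.data.shape[-1]
            w._accum(a.data.reshape(-1, k).T @ g.reshape(-1))

    return _node(a.data @ w.data, (a, w), backward)


# -- shape manipulation ------------------------------------------------
def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if _wants(a):
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accum(buf)

    return _node(a.data[idx], (a,), backward)


def concatenate(tensors: Iterable, axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if _wants(t):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in ts], axis=axis), ts, backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.data.shape

    def backward(g):
        if _wants(a):
            a._accum(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def expand_dims(a, axis: int) -> Tensor:
    a = _as_tensor(a)
    new_shape = list(a.data.shape)
    new_shape.insert(axis if axis >= 0 else a.data.ndim + 1 + axis, 1)
    return reshape(a, tuple(new_shape))


def squeeze(a, axis: int) -> Tensor:
    a = _as_tensor(a)
    new_shape = list(a.data.shape)
    if new_shape[axis] != 1:
        raise ValueError(f"cannot squeeze axis {axis} of shape {a.data.shape}")
    del new_shape[axis]
    return reshape(a, tuple(new_shape))


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if _wants(a):
            a._accum(np.swapaxes(g, ax1, ax2))

    return _node(np.swapaxes(a.data, ax1, ax2), (a,), backward)


def stack(tensors: Iterable, axis: int = 0) -> Tensor:
    return concatenate([expand_dims(t, axis) for t in tensors], axis=axis)


# -- optimizer ---------------------------------------------------------
class Adam:
    """Adaptive-moment gradient descent (Kingma & Ba defaults)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
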