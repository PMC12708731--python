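"""Minimal reverse-mode automatic differentiation over numpy float64 arrays.

Supports exactly the operations the loss functions and reference encoders
need: broadcasted arithmetic, batched matmul, exp/log/pow, reductions,
reshape/transpose/indexing, relu, and a numerically stabilised softmax.
Gradients are accumulated by topological-order backpropagation.  Everything
is float64; there is no device abstraction and no graph caching — tensors
are cheap, graphs are built per forward pass and discarded after backward.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "softmax", "exp", "log", "tsum", "tmean", "sqrt"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._prev: tuple = ()
        self._vjps: tuple = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data, parents, vjps):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._vjps = tuple(vjps)
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            (lambda g: _unbroadcast(g, self.shape), lambda g: _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g * other.data, self.shape),
                lambda g: _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        assert np.isscalar(p)
        return Tensor._make(
            self.data ** p,
            (self,),
            (lambda g: g * p * self.data ** (p - 1.0),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def vjp_a(g):
            return _unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)), a.shape)

        def vjp_b(g):
            return _unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g), b.shape)

        return Tensor._make(np.matmul(a, b), (self, other), (vjp_a, vjp_b))

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- elementwise ---------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), (lambda g: g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), (lambda g: g / self.data,))

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), (lambda g: g * mask,))

    # -- reductions / shape --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, self.shape).copy()

        return Tensor._make(out_data, (self,), (vjp,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            self.data.reshape(shape), (self,), (lambda g: g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), (lambda g: g.transpose(inv),)
        )

    @property
    def T(self):
        return self.transpose(tuple(range(self.ndim))[::-1])

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return Tensor._make(self.data[idx], (self,), (vjp,))

    # -- backward ------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.shape).copy()
        for t in reversed(topo):
            if not t._prev:
                continue
            for parent, vjp in zip(t._prev, t._vjps):
                if parent.requires_grad:
                    parent.grad = parent.grad + vjp(t.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- generic helpers working on Tensor or ndarray ----------------------------


def _is_t(x):
    return isinstance(x, Tensor)


def exp(x):
    return x.exp() if _is_t(x) else np.exp(x)


def log(x):
    return x.log() if _is_t(x) else np.log(x)


def sqrt(x):
    return x.sqrt() if _is_t(x) else np.sqrt(x)


def tsum(x, axis=None, keepdims=False):
    return x.sum(axis=axis, keepdims=keepdims) if _is_t(x) else np.sum(
        x, axis=axis, keepdims=keepdims
    )


def tmean(x, axis=None, keepdims=False):
    return x.mean(axis=axis, keepdims=keepdims) if _is_t(x) else np.mean(
        x, axis=axis, keepdims=keepdims
    )


def softmax(x, axis: int = -1):
    """Numerically stable softmax along `axis` for Tensor or ndarray."""
    if _is_t(x):
        m = x.data.max(axis=axis, keepdims=True)  # constant shift, no grad needed
        e = (x - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)
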