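"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the sleep-staging network needs:
element-wise arithmetic with broadcasting, ReLU/sigmoid, 1-D convolution,
max/average pooling, batch normalization, linear layers, concatenation and
reductions. Float64 throughout for deterministic CPU behaviour.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "relu",
    "sigmoid",
    "mean_time",
]


class Tensor:
    """An array node in the computation graph.

    ``grad`` is populated for *every* node reached during ``backward`` —
    intermediate activations included — which is what gradient-based
    class-activation mapping relies on.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            self.accumulate(_unbroadcast(g, self.data.shape))
            other.accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, True, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self.accumulate(-g)

        return Tensor(-self.data, True, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            other.accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, True, (self, other), bw)

    __rmul__ = __mul__

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self.accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), True, (self,), bw)

    def transpose_ct(self):
        """Swap the channel and time axes of a (B, C, T) tensor."""

        def bw(g):
            self.accumulate(np.swapaxes(g, 1, 2))

        return Tensor(np.swapaxes(self.data, 1, 2), True, (self,), bw)

    def sum(self):
        def bw(g):
            self.accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(self.data.sum(), True, (self,), bw)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tuple(tensors), bw)


def relu(x):
    x = as_tensor(x)
    mask = x.data > 0

    def bw(g):
        x.accumulate(g * mask)

    return Tensor(x.data * mask, True, (x,), bw)


def sigmoid(x):
    x = as_tensor(x)
    with np.errstate(over="ignore"):  # saturates cleanly to 0/1
        out = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x.accumulate(g * out * (1.0 - out))

    return Tensor(out, True, (x,), bw)


def mean_time(x, keepdims=True):
    """Average over the trailing (time) axis of a (B, C, T) tensor."""
    x = as_tensor(x)
    T = x.data.shape[-1]

    def bw(g):
        if not keepdims:
            g = g[..., None]
        x.accumulate(np.broadcast_to(g / T, x.data.shape).copy())

    return Tensor(x.data.mean(axis=-1, keepdims=keepdims), True, (x,), bw)
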