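"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for full-batch Cox-loss training of the fusion networks:
dense layers, batch normalization, ReLU, softmax, the fusion aggregations
(mean/max/concat/convex combination/multinomial selection) and a Cox partial
likelihood loss node with an analytic gradient.
"""

from __future__ import annotations

import numpy as np

from ..data import SurvivalOutcome
from ..survival import cox_nll_breslow, cox_nll_breslow_grad

__all__ = [
    "Tensor", "add", "matmul", "mul", "relu", "concat", "mean_stack",
    "max_stack", "select_stack", "softmax_rows", "weighted_sum", "cox_loss",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        a.grad += _unbroadcast(g, a.data.shape)
        b.grad += _unbroadcast(g, b.data.shape)

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        a.grad += g @ b.data.T
        b.grad += a.data.T @ g

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        a.grad += _unbroadcast(g * b.data, a.data.shape)
        b.grad += _unbroadcast(g * a.data, b.data.shape)

    out._backward = bw
    return out


def scale(a: Tensor, c) -> Tensor:
    """Multiply by a constant array or scalar (no gradient through c)."""
    c = np.asarray(c, dtype=float)
    out = Tensor(a.data * c, (a,))

    def bw(g):
        a.grad += _unbroadcast(g * c, a.data.shape)

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))

    def bw(g):
        a.grad += g * mask

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.grad += g[tuple(sl)]

    out._backward = bw
    return out


def mean_stack(tensors: list[Tensor]) -> Tensor:
    M = len(tensors)
    out = Tensor(sum(t.data for t in tensors) / M, tuple(tensors))

    def bw(g):
        for t in tensors:
            t.grad += g / M

    out._backward = bw
    return out


def max_stack(tensors: list[Tensor]) -> Tensor:
    stacked = np.stack([t.data for t in tensors])
    arg = stacked.argmax(axis=0)
    out = Tensor(stacked.max(axis=0), tuple(tensors))

    def bw(g):
        for m, t in enumerate(tensors):
            t.grad += g * (arg == m)

    out._backward = bw
    return out


def select_stack(tensors: list[Tensor], index: np.ndarray) -> Tensor:
    """Cell-wise selection: out[c] = tensors[index[c]][c] (Embrace sampling)."""
    stacked = np.stack([t.data for t in tensors])
    out = Tensor(np.take_along_axis(stacked, index[None], axis=0)[0], tuple(tensors))

    def bw(g):
        for m, t in enumerate(tensors):
            t.grad += g * (index == m)

    out._backward = bw
    return out


def softmax_rows(a: Tensor) -> Tensor:
    z = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)
    out = Tensor(y, (a,))

    def bw(g):
        a.grad += y * (g - (g * y).sum(axis=1, keepdims=True))

    out._backward = bw
    return out


def weighted_sum(tensors: list[Tensor], weights: Tensor) -> Tensor:
    """sum_i weights[:, i:i+1] * tensors[i]; gradient flows into both."""
    n, M = weights.data.shape
    if M != len(tensors):
        raise ValueError("one weight column per tensor required")
    out_data = sum(weights.data[:, i : i + 1] * tensors[i].data for i in range(M))
    out = Tensor(out_data, tuple(tensors) + (weights,))

    def bw(g):
        for i, t in enumerate(tensors):
            t.grad += g * weights.data[:, i : i + 1]
            weights.grad[:, i] += (g * t.data).sum(axis=1)

    out._backward = bw
    return out


def cox_loss(theta: Tensor, outcome: SurvivalOutcome) -> Tensor:
    """Breslow-ties negative Cox partial log-likelihood of an (n, 1) log hazard."""
    flat = theta.data.ravel()
    out = Tensor(cox_nll_breslow(flat, outcome), (theta,))

    def bw(g):
        theta.grad += (g * cox_nll_breslow_grad(flat, outcome)).reshape(theta.data.shape)

    out._backward = bw
    return out
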