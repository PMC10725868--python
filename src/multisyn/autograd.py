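"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical core behind the neural building blocks: a
:class:`Tensor` wrapping an ``ndarray``, a small set of differentiable
operations (matmul, broadcast add/mul, relu, tanh, softmax, concat, reshape,
reductions, cross-entropy) and the AdamW optimizer. Everything is CPU numpy
and fully deterministic given a seeded ``numpy.random.Generator``.

Conventions: sample batches live in the leading axis; parameters are 2-D
weight matrices ``(in, out)`` and 1-D biases. ``matmul`` supports stacked
(batched) operands on either side; gradients for broadcast operands are
reduced back to the original shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Linear",
    "AdamW",
    "concat",
    "relu",
    "tanh",
    "softmax",
    "cross_entropy",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, _as_tensor(other)

        def bwd(g):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._node(a.data + b.data, (a, b), bwd)

    def __sub__(self, other: "Tensor") -> "Tensor":
        a, b = self, _as_tensor(other)

        def bwd(g):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(-g, b.shape))

        return Tensor._node(a.data - b.data, (a, b), bwd)

    def __mul__(self, other) -> "Tensor":
        a, b = self, _as_tensor(other)

        def bwd(g):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._node(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self, _as_tensor(other)

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accumulate(_unbroadcast(ga, a.shape))
            b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._node(np.matmul(a.data, b.data), (a, b), bwd)

    def square(self) -> "Tensor":
        a = self

        def bwd(g):
            a._accumulate(g * 2.0 * a.data)

        return Tensor._node(a.data**2, (a,), bwd)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        a = self
        orig = a.shape

        def bwd(g):
            a._accumulate(g.reshape(orig))

        return Tensor._node(a.data.reshape(*shape), (a,), bwd)

    def swap_last2(self) -> "Tensor":
        a = self

        def bwd(g):
            a._accumulate(np.swapaxes(g, -1, -2))

        return Tensor._node(np.swapaxes(a.data, -1, -2), (a,), bwd)

    def sum(self) -> "Tensor":
        a = self

        def bwd(g):
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._node(a.data.sum(), (a,), bwd)

    def mean(self) -> "Tensor":
        a = self
        n = a.data.size

        def bwd(g):
            a._accumulate(np.broadcast_to(g / n, a.shape).copy())

        return Tensor._node(a.data.mean(), (a,), bwd)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor._node(np.where(mask, x.data, 0.0), (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def bwd(g):
        x._accumulate(g * (1.0 - y**2))

    return Tensor._node(y, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    return Tensor._node(y, (x,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; callers skip this entirely at evaluation time."""
    if rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` is an int array of shape (B,)."""
    labels = np.asarray(labels)
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - logz
    n = labels.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)

    return Tensor._node(loss, (logits,), bwd)


class Linear:
    """Dense layer ``x @ W + b`` with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.W) + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class AdamW:
    """Adam with decoupled weight decay (decay applied to the raw weights)."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
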