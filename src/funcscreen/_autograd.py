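"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the encoder and classification head need:
matmul, broadcast add/mul, concat, row gather, segment sum (scatter-add),
relu, sigmoid, softplus and reductions. Float64 throughout; gradients are
accumulated on leaf tensors created with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "tensor", "constant", "add", "mul", "matmul", "concat",
    "take_rows", "segment_sum", "relu", "sigmoid", "softplus", "total",
    "mean", "scale",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def tensor(data, requires_grad: bool = True) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=requires_grad)


def constant(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=False)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, requires_grad=_needs(a, b), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, requires_grad=_needs(a, b), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, requires_grad=_needs(a, b), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=_needs(*tensors), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


def take_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(a.data[idx], requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accumulate(acc)

    out._backward = backward
    return out


def segment_sum(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise scatter-add: ``out[s] = sum of a[i] with segment_ids[i] == s``."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, a.data)
    out = Tensor(data, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[segment_ids])

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), requires_grad=a.requires_grad,
                 parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    out._backward = backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-branch logistic
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                 np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = Tensor(s, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def softplus(a: Tensor) -> Tensor:
    x = a.data
    sp = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(sp, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            sig = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                           np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
            a._accumulate(g * sig)

    out._backward = backward
    return out


def total(a: Tensor) -> Tensor:
    out = Tensor(np.array(a.data.sum()), requires_grad=a.requires_grad,
                 parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g, a.data.shape))

    out._backward = backward
    return out


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    out = Tensor(np.array(a.data.mean()), requires_grad=a.requires_grad,
                 parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g / n, a.data.shape))

    out._backward = backward
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)

    out._backward = backward
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimiser over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
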