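"""Minimal reverse-mode automatic differentiation on numpy arrays.

Exactly the operations the three classifiers need: broadcast add, matmul,
elementwise nonlinearities (ReLU, ELU, LeakyReLU), multiplication by a
constant mask (dropout), row softmax, column concatenation, and a fused
cross-entropy-from-logits loss restricted to a row subset (the transductive
training mask).  Gradients follow the standard vector-Jacobian products; the
test suite verifies them against central finite differences.

This is not a general tensor library: shapes are 1-D/2-D, dtype is float64,
and there is no graph reuse after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "add", "matmul", "relu", "elu", "leaky_relu",
           "mul_const", "add_const", "softmax_rows", "concat",
           "cross_entropy_with_logits", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar or any-shape seed) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents,
                  backward=backward if req else None)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.data.shape)

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            if b.data.ndim == 1:
                a.grad += np.outer(g, b.data) if a.data.ndim == 2 else g * b.data
            else:
                a.grad += g @ b.data.T
        if b.requires_grad:
            if a.data.ndim == 1:
                b.grad += np.outer(a.data, g) if b.data.ndim == 2 else g * a.data
            else:
                b.grad += a.data.T @ g

    return _make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x.grad += g * mask

    return _make(out_data, (x,), backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg = x.data <= 0
    out_data = np.where(neg, alpha * np.expm1(x.data), x.data)

    def backward(g):
        x.grad += g * np.where(neg, out_data + alpha, 1.0)

    return _make(out_data, (x,), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def backward(g):
        x.grad += g * np.where(mask, 1.0, slope)

    return _make(out_data, (x,), backward)


def mul_const(x: Tensor, c) -> Tensor:
    c = np.asarray(c, dtype=float)
    out_data = x.data * c

    def backward(g):
        x.grad += _unbroadcast(g * c, x.data.shape)

    return _make(out_data, (x,), backward)


def add_const(x: Tensor, c) -> Tensor:
    out_data = x.data + np.asarray(c, dtype=float)

    def backward(g):
        x.grad += _unbroadcast(g, x.data.shape)

    return _make(out_data, (x,), backward)


def softmax_rows(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        # dL/dx = y * (g - sum(g*y))
        inner = (g * out_data).sum(axis=-1, keepdims=True)
        x.grad += out_data * (g - inner)

    return _make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return _make(out_data, tuple(tensors), backward)


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray,
                              rows: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy over ``rows`` (all rows if None) of an (n, C) logit matrix."""
    labels = np.asarray(labels)
    if rows is None:
        rows = np.arange(logits.data.shape[0])
    rows = np.asarray(rows)
    if rows.dtype == bool:
        rows = np.flatnonzero(rows)
    if rows.size == 0:
        raise ValueError("cross-entropy over an empty row set")
    sub = logits.data[rows]
    y = labels[rows]
    z = sub - sub.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -log_probs[np.arange(len(y)), y].mean()
    probs = np.exp(log_probs)

    def backward(g):
        grad = np.zeros_like(logits.data)
        delta = probs.copy()
        delta[np.arange(len(y)), y] -= 1.0
        grad[rows] = g * delta / len(y)
        logits.grad += grad

    return _make(np.asarray(loss), (logits,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate == 0.0:
        return x
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return mul_const(x, mask)
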