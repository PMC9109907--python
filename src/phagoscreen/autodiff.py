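"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough tape-based autodiff to train the embedding families and MLP
heads in this package: dense algebra, elementwise nonlinearities, row
gather/scatter for message passing on batched graphs, a per-edge matrix-
vector product for bond-conditioned convolutions, and a fused softmax
cross-entropy loss.  Gradients are accumulated by topological traversal of
the recorded operation graph; every operation's backward rule is exercised
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = [
    "Tensor", "tensor", "add", "sub", "mul", "div", "matmul", "relu",
    "leaky_relu", "exp", "concat", "gather", "segment_sum", "segment_mean",
    "reshape", "edge_matvec", "cross_entropy", "mean_", "backward",
]


class Tensor:
    """A node in the computation graph: a value, its gradient, parents."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._backward: Callable | None = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def tensor(data, requires_grad=True) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    out._backward = bw
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, (a, b))
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))
    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    out._backward = bw
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, (a, b))
    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))
    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)
    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, alpha * a.data), (a,))
    out._backward = lambda g: _accum(a, np.where(mask, g, alpha * g))
    return out


def exp(a: Tensor) -> Tensor:
    val = np.exp(a.data)
    out = Tensor(val, (a,))
    out._backward = lambda g: _accum(a, g * val)
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)
    out._backward = bw
    return out


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``a[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(a.data[idx], (a,))
    def bw(g):
        acc = np.zeros_like(a.data)
        np.add.at(acc, idx, g)
        _accum(a, acc)
    out._backward = bw
    return out


def segment_sum(a: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets given by ``seg``."""
    seg = np.asarray(seg, dtype=np.int64)
    val = np.zeros((num_segments,) + a.data.shape[1:])
    np.add.at(val, seg, a.data)
    out = Tensor(val, (a,))
    out._backward = lambda g: _accum(a, g[seg])
    return out


def segment_mean(a: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Mean of rows per bucket; empty buckets yield zero rows."""
    seg = np.asarray(seg, dtype=np.int64)
    counts = np.bincount(seg, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)[:, None]
    s = segment_sum(a, seg, num_segments)
    return div(s, Tensor(counts, requires_grad=False))


def reshape(a: Tensor, shape: tuple) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))
    out._backward = lambda g: _accum(a, g.reshape(a.data.shape))
    return out


def edge_matvec(h: Tensor, W: Tensor) -> Tensor:
    """Per-edge matrix-vector product: (E, din) x (E, din, dout) -> (E, dout)."""
    out = Tensor(np.einsum("ei,eio->eo", h.data, W.data), (h, W))
    def bw(g):
        _accum(h, np.einsum("eo,eio->ei", g, W.data))
        _accum(W, np.einsum("ei,eo->eio", h.data, g))
    out._backward = bw
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of integer ``labels`` (fused, stable)."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-300))
    out = Tensor(nll.mean(), (logits,))
    def bw(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        _accum(logits, g * grad / n)
    out._backward = bw
    return out


def mean_(a: Tensor) -> Tensor:
    out = Tensor(a.data.mean(), (a,))
    out._backward = lambda g: _accum(a, np.full_like(a.data, g / a.data.size))
    return out


def backward(loss: Tensor) -> None:
    """Reverse-accumulate gradients from a scalar loss."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain (non-graph) softmax used at prediction time."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
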