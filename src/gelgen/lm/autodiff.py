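"""Minimal reverse-mode automatic differentiation over numpy arrays.

Covers exactly the operations the transformer decoder needs: broadcast
add/mul, (batched) matmul, transpose, reshape, embedding gather, softmax,
layer normalization, tanh-approximated GELU and masked cross-entropy.
Gradients accumulate into ``.grad``; ``backward()`` runs a topological
sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if g.dtype != np.float32:
        g = g.astype(np.float32)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    out._backward = bw
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, (a,))
    out._backward = lambda g: _accum(a, g * s)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.matmul(a.data, b.data), (a, b))

    def bw(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        # reduce any broadcast batch dimensions
        while ga.ndim > len(a.shape):
            ga = ga.sum(axis=0)
        while gb.ndim > len(b.shape):
            gb = gb.sum(axis=0)
        _accum(a, ga)
        _accum(b, gb)

    out._backward = bw
    return out


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))
    out = Tensor(a.data.transpose(axes), (a,))
    out._backward = lambda g: _accum(a, g.transpose(inv))
    return out


def reshape(a: Tensor, shape: tuple) -> Tensor:
    orig = a.shape
    out = Tensor(a.data.reshape(shape), (a,))
    out._backward = lambda g: _accum(a, g.reshape(orig))
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out = Tensor(table.data[ids], (table,))

    def bw(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, ids, g)
            _accum(table, gt)

    out._backward = bw
    return out


def softmax(a: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``mask`` is an additive constant (e.g. -inf)."""
    x = a.data if mask is None else a.data + mask
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, (a,))

    def bw(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        _accum(a, y * (g - dot))

    out._backward = bw
    return out


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out = Tensor(gain.data * xhat + bias.data, (a, gain, bias))

    def bw(g):
        _accum(gain, _unbroadcast(g * xhat, gain.shape))
        _accum(bias, _unbroadcast(g, bias.shape))
        dxhat = g * gain.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        _accum(a, inv * (dxhat - m1 - xhat * m2))

    out._backward = bw
    return out


_GELU_C = float(np.sqrt(2.0 / np.pi))
_GELU_A = 0.044715


def gelu(a: Tensor) -> Tensor:
    x = a.data
    x2 = x * x
    t = np.tanh(np.float32(_GELU_C) * (x + np.float32(_GELU_A) * x2 * x))
    out = Tensor(0.5 * x * (1.0 + t), (a,))

    def bw(g):
        du = np.float32(_GELU_C) * (1.0 + np.float32(3.0 * _GELU_A) * x2)
        _accum(a, g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du))

    out._backward = bw
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray, ignore_id: int = -1) -> Tensor:
    """Mean negative log-likelihood over targets != ignore_id.

    ``logits`` has shape (..., V); ``targets`` the matching leading shape.
    """
    flat = logits.data.reshape(-1, logits.data.shape[-1])
    tgt = np.asarray(targets).reshape(-1)
    valid = tgt != ignore_id
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid targets")
    x = flat - flat.max(axis=1, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=1))
    idx = np.where(valid, tgt, 0)
    logp = x[np.arange(len(tgt)), idx] - lse
    loss = -(logp * valid).sum() / n
    out = Tensor(loss, (logits,))

    def bw(g):
        p = np.exp(x - lse[:, None]).astype(np.float32)
        p[np.arange(len(tgt)), idx] -= 1.0
        p *= (valid.astype(np.float32) * np.float32(float(g) / n))[:, None]
        _accum(logits, p.reshape(logits.shape))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(self, params: dict, lr: float = 3e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
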