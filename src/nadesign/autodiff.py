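"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core that backs the message-passing network: a tape of
`Tensor` nodes, each holding an ndarray, its gradient, and a closure that
propagates gradients to its parents.  Only the operations the network needs
are implemented (affine maps, layer norm, GELU, log-softmax, gathers with
scatter-add backward, reductions, concatenation).  Gradients flow in float32
or float64 matching the forward dtype.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    for _ in range(ndim_extra):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # ---- graph traversal -------------------------------------------------

    def backward(self):
        """Reverse-accumulate gradients from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # ---- operators -------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, scalar):
        return mul(self, 1.0 / float(scalar))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, a.requires_grad or b.requires_grad, (a, b))

    def bw():
        _accum(a, out.grad)
        _accum(b, out.grad)

    out._backward = bw if out.requires_grad else None
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, a.requires_grad or b.requires_grad, (a, b))

    def bw():
        _accum(a, out.grad * b.data)
        _accum(b, out.grad * a.data)

    out._backward = bw if out.requires_grad else None
    return out


def matmul(a, b) -> Tensor:
    """Batched matrix product; `b` is 2-D (a weight matrix)."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, a.requires_grad or b.requires_grad, (a, b))

    def bw():
        if a.requires_grad:
            _accum(a, out.grad @ b.data.T)
        if b.requires_grad:
            ga = a.data.reshape(-1, a.data.shape[-1])
            go = out.grad.reshape(-1, out.grad.shape[-1])
            _accum(b, ga.T @ go)

    out._backward = bw if out.requires_grad else None
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))

    def bw():
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            _accum(t, g)

    out._backward = bw if req else None
    return out


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), a.requires_grad, (a,))

    def bw():
        _accum(a, out.grad.reshape(a.data.shape))

    out._backward = bw if out.requires_grad else None
    return out


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), a.requires_grad, (a,))

    def bw():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape))

    out._backward = bw if out.requires_grad else None
    return out


def mean_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def gather(a, index) -> Tensor:
    """Row lookup a[index] with scatter-add backward (embedding / kNN gather)."""
    a = as_tensor(a)
    index = np.asarray(index)
    out = Tensor(a.data[index], a.requires_grad, (a,))

    def bw():
        g = np.zeros_like(a.data)
        np.add.at(g, index.reshape(-1), out.grad.reshape(-1, *a.data.shape[1:]))
        _accum(a, g)

    out._backward = bw if out.requires_grad else None
    return out


_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a) -> Tensor:
    from scipy.special import erf

    a = as_tensor(a)
    phi = 0.5 * (1.0 + erf(a.data / _SQRT2))
    out = Tensor(a.data * phi, a.requires_grad, (a,))

    def bw():
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data**2)
        _accum(a, out.grad * (phi + a.data * pdf))

    out._backward = bw if out.requires_grad else None
    return out


def layer_norm(a, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    a = as_tensor(a)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(
        xhat * gain.data + bias.data,
        a.requires_grad or gain.requires_grad or bias.requires_grad,
        (a, gain, bias),
    )

    def bw():
        g = out.grad
        if gain.requires_grad:
            _accum(gain, (g * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0))
        if bias.requires_grad:
            _accum(bias, g.reshape(-1, xhat.shape[-1]).sum(axis=0))
        if a.requires_grad:
            gx = g * gain.data
            d = a.data.shape[-1]
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            _accum(a, term * inv)
            del d

    out._backward = bw if out.requires_grad else None
    return out


def log_softmax(a, axis=-1) -> Tensor:
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    z = a.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(z - lse, a.requires_grad, (a,))

    def bw():
        p = np.exp(out.data)
        _accum(a, out.grad - p * out.grad.sum(axis=axis, keepdims=True))

    out._backward = bw if out.requires_grad else None
    return out


def dropout(a, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when p == 0."""
    if p <= 0.0:
        return as_tensor(a)
    a = as_tensor(a)
    keep = (rng.random(a.data.shape) >= p).astype(a.data.dtype) / (1.0 - p)
    return mul(a, keep)


# ---- parameters and optimizer --------------------------------------------


def parameter(data) -> Tensor:
    t = Tensor(np.asarray(data, dtype=np.float32))
    t.requires_grad = True
    return t


def zero_grads(params: dict):
    for p in params.values():
        p.grad = None


def global_grad_norm(params: dict) -> float:
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    return math.sqrt(total)


def clip_grad_norm(params: dict, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most `max_norm`.

    Returns the pre-clipping norm.
    """
    norm = global_grad_norm(params)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam with the (beta1=0.9, beta2=0.98, eps=1e-9) configuration."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.98, eps=1e-9):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
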