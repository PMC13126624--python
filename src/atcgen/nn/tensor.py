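"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records, while gradients are
enabled, the closure needed to push its gradient back to its parents.
The op set is exactly what the sequence models here need: broadcasted
arithmetic, (batched) matmul, pointwise nonlinearities, reductions,
indexing/embedding lookup, concatenation, softmax/log-softmax, layer
normalization, dropout and a fused masked cross-entropy.

Gradients accumulate into ``.grad`` during :meth:`Tensor.backward`; graphs
are one-shot (rebuilt every forward pass).  ``no_grad()`` suspends graph
recording for inference.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(
        p.requires_grad or p._parents for p in parents
    ):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- arithmetic ---------------------------------------------------------
def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(grad):
        a._accumulate(_unbroadcast(grad, a.shape))
        b._accumulate(_unbroadcast(grad, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    return add(a, mul(b, -1.0))


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(grad):
        a._accumulate(_unbroadcast(grad * b.data, a.shape))
        b._accumulate(_unbroadcast(grad * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports batched left operand with 2-D weights and
    same-batch 3-D × 3-D products."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(grad):
        ga = grad @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ grad
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# ---- pointwise ----------------------------------------------------------
def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)

    def backward(grad):
        a._accumulate(grad * (1.0 - t * t))

    return _make(t, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def backward(grad):
        a._accumulate(grad * s * (1.0 - s))

    return _make(s, (a,), backward)


def relu(a: Tensor) -> Tensor:
    m = a.data > 0

    def backward(grad):
        a._accumulate(grad * m)

    return _make(a.data * m, (a,), backward)


# ---- reductions / shaping ----------------------------------------------
def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(grad):
        a._accumulate(grad.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    def backward(grad):
        a._accumulate(np.swapaxes(grad, ax1, ax2))

    return _make(np.swapaxes(a.data, ax1, ax2), (a,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0, *sizes])

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * grad.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(idx)])

    return _make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def take_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``a[idx]`` along axis 0 (embedding lookup / state select)."""
    idx = np.asarray(idx)

    def backward(grad):
        g = np.zeros_like(a.data)
        np.add.at(g, idx, grad)
        a._accumulate(g)

    return _make(a.data[idx], (a,), backward)


def gather_time(a: Tensor, t_idx: np.ndarray) -> Tensor:
    """Select ``a[t_idx[b], b]`` from a (T, B, H) tensor → (B, H)."""
    b_idx = np.arange(a.shape[1])

    def backward(grad):
        g = np.zeros_like(a.data)
        np.add.at(g, (t_idx, b_idx), grad)
        a._accumulate(g)

    return _make(a.data[t_idx, b_idx], (a,), backward)


# ---- softmax family -----------------------------------------------------
def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
    out_data = x - lse

    def backward(grad):
        sm = np.exp(out_data)
        a._accumulate(grad - sm * grad.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(grad):
        dot = (grad * s).sum(axis=axis, keepdims=True)
        a._accumulate(s * (grad - dot))

    return _make(s, (a,), backward)


def masked_cross_entropy(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray
) -> Tensor:
    """Mean token-level cross-entropy over positions where ``mask`` is true.

    ``logits``: (N, V); ``targets``: (N,) int; ``mask``: (N,) bool.
    """
    lp = log_softmax(logits, axis=-1)
    n = np.arange(targets.shape[0])
    picked = take_rows(reshape(lp, (-1,)), n * logits.shape[-1] + targets)
    w = mask.astype(float)
    denom = max(w.sum(), 1.0)
    return mul(tsum(mul(picked, -w)), 1.0 / denom)


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out_data = xhat * gain.data + bias.data
    H = a.shape[-1]

    def backward(grad):
        gain._accumulate(_unbroadcast(grad * xhat, gain.shape))
        bias._accumulate(_unbroadcast(grad, bias.shape))
        gx = grad * gain.data
        ga = inv * (
            gx
            - gx.mean(axis=-1, keepdims=True)
            - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        )
        a._accumulate(ga)

    return _make(out_data, (a, gain, bias), backward)


def dropout(a: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return a
    keep = (rng.random(a.shape) >= p) / (1.0 - p)

    def backward(grad):
        a._accumulate(grad * keep)

    return _make(a.data * keep, (a,), backward)


def add_const(a: Tensor, const: np.ndarray) -> Tensor:
    """Add a non-differentiable array (attention masks, position codes)."""

    def backward(grad):
        a._accumulate(_unbroadcast(grad, a.shape))

    return _make(a.data + const, (a,), backward)
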