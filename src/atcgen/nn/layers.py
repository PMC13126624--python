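"""Neural building blocks: parameters, linear/embedding layers, an LSTM
cell and multi-head attention, on top of the autodiff :mod:`.tensor` core."""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    add,
    add_const,
    concat,
    matmul,
    sigmoid,
    softmax,
    take_rows,
    tanh,
)


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("parameter count mismatch in checkpoint")
        for p, a in zip(params, arrays):
            if p.data.shape != np.asarray(a).shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = np.asarray(a, dtype=np.float64)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        self.W = glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.W)
        return add(y, self.b) if self.b is not None else y


class Embedding(Module):
    def __init__(self, rng, n_tokens: int, dim: int):
        self.W = Tensor(rng.normal(0.0, 0.1, size=(n_tokens, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return take_rows(self.W, np.asarray(idx))


class LSTMCell(Module):
    """Fused-gate LSTM cell (input/forget/cell/output gate order)."""

    def __init__(self, rng, n_in: int, n_hidden: int):
        self.Wx = glorot(rng, n_in, 4 * n_hidden)
        self.Wh = glorot(rng, n_hidden, 4 * n_hidden)
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias init
        self.b = Tensor(b, requires_grad=True)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.n_hidden
        z = add(add(matmul(x, self.Wx), matmul(h, self.Wh)), self.b)
        zi = _slice_last(z, 0, H)
        zf = _slice_last(z, H, 2 * H)
        zg = _slice_last(z, 2 * H, 3 * H)
        zo = _slice_last(z, 3 * H, 4 * H)
        i, f, g, o = sigmoid(zi), sigmoid(zf), tanh(zg), sigmoid(zo)
        from .tensor import mul as tmul

        c_new = add(tmul(f, c), tmul(i, g))
        h_new = tmul(o, tanh(c_new))
        return h_new, c_new


def _slice_last(t: Tensor, lo: int, hi: int) -> Tensor:
    from .tensor import _make

    def backward(grad):
        g = np.zeros_like(t.data)
        g[..., lo:hi] = grad
        t._accumulate(g)

    return _make(t.data[..., lo:hi], (t,), backward)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` heads over (B, T, D)."""

    def __init__(self, rng, d_model: int, n_heads: int):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.Wq = Linear(rng, d_model, d_model)
        self.Wk = Linear(rng, d_model, d_model)
        self.Wv = Linear(rng, d_model, d_model)
        self.Wo = Linear(rng, d_model, d_model)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        from .tensor import reshape, swapaxes

        x = reshape(x, (B, T, self.n_heads, self.d_head))
        x = swapaxes(x, 1, 2)  # (B, h, T, d)
        return reshape(x, (B * self.n_heads, T, self.d_head))

    def __call__(
        self, q_in: Tensor, kv_in: Tensor, mask: np.ndarray | None = None
    ) -> Tensor:
        """``mask`` is an additive (Tq, Tk) or (B*h, Tq, Tk) array of 0/−inf."""
        from .tensor import reshape, swapaxes

        B, Tq, D = q_in.shape
        Tk = kv_in.shape[1]
        q = self._split(self.Wq(q_in), B, Tq)
        k = self._split(self.Wk(kv_in), B, Tk)
        v = self._split(self.Wv(kv_in), B, Tk)
        scores = matmul(q, swapaxes(k, 1, 2))
        from .tensor import mul as tmul

        scores = tmul(scores, 1.0 / np.sqrt(self.d_head))
        if mask is not None:
            scores = add_const(scores, mask)
        attn = softmax(scores, axis=-1)
        ctx = matmul(attn, v)  # (B*h, Tq, d)
        ctx = reshape(ctx, (B, self.n_heads, Tq, self.d_head))
        ctx = swapaxes(ctx, 1, 2)
        ctx = reshape(ctx, (B, Tq, D))
        return self.Wo(ctx)
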