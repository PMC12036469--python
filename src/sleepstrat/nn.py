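"""Minimal dense/attention layer library with hand-written backpropagation.

Implements exactly the pieces the epoch encoder needs — linear layers,
layer normalization, GELU, multi-head self-attention, pre-norm transformer
blocks and an Adam optimizer — on float64 NumPy arrays.  Every layer caches
its forward inputs and implements ``backward`` returning the input gradient
while accumulating parameter gradients.  Gradient correctness is enforced by
finite-difference tests rather than an autodiff framework.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def init_normal(rng: np.random.Generator, shape, scale: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, scale, size=shape)


class Dense:
    """Affine map over the last axis: ``y = x @ W + b``."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, name: str = ""):
        self.W = Parameter(init_normal(rng, (d_in, d_out)), f"{name}.W")
        self.b = Parameter(np.zeros(d_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class LayerNorm:
    """Normalization over the last axis with learned gain and bias."""

    def __init__(self, d: int, eps: float = 1e-5, name: str = ""):
        self.g = Parameter(np.ones(d), f"{name}.g")
        self.b = Parameter(np.zeros(d), f"{name}.b")
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.g, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.g.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.g.grad += (dy * xhat).reshape(-1, d).sum(axis=0)
        self.b.grad += dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.g.value
        # standard layernorm input gradient
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT2PI * np.exp(-0.5 * x * x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention:
    """Bidirectional (unmasked) multi-head self-attention."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int, name: str = ""):
        if d % n_heads:
            raise ValueError(f"embed dim {d} not divisible by {n_heads} heads")
        self.d, self.h = d, n_heads
        self.dh = d // n_heads
        self.qkv = Dense(rng, d, 3 * d, f"{name}.qkv")
        self.out = Dense(rng, d, d, f"{name}.out")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return self.qkv.parameters() + self.out.parameters()

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, l, _ = x.shape
        return x.reshape(b, l, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, l, d = x.shape
        qkv = self.qkv.forward(x)
        q, k, v = (self._split(a) for a in np.split(qkv, 3, axis=-1))
        scale = 1.0 / math.sqrt(self.dh)
        attn = softmax(np.matmul(q, k.transpose(0, 1, 3, 2)) * scale)
        o = np.matmul(attn, v)  # (b, h, l, dh)
        self._cache = (q, k, v, attn)
        o = o.transpose(0, 2, 1, 3).reshape(b, l, d)
        return self.out.forward(o)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        b, h, l, dh = q.shape
        do = self.out.backward(dy).reshape(b, l, h, dh).transpose(0, 2, 1, 3)
        dattn = np.matmul(do, v.transpose(0, 1, 3, 2))
        dv = np.matmul(attn.transpose(0, 1, 3, 2), do)
        ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        scale = 1.0 / math.sqrt(dh)
        dq = np.matmul(ds, k) * scale
        dk = np.matmul(ds.transpose(0, 1, 3, 2), q) * scale
        dqkv = np.concatenate(
            [a.transpose(0, 2, 1, 3).reshape(b, l, h * dh) for a in (dq, dk, dv)],
            axis=-1,
        )
        return self.qkv.backward(dqkv)


class TransformerBlock:
    """Pre-norm block: ``x + MHSA(LN(x))`` then ``y + FFN(LN(y))``."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int,
                 ffn_mult: int = 4, name: str = ""):
        self.ln1 = LayerNorm(d, name=f"{name}.ln1")
        self.attn = MultiHeadSelfAttention(rng, d, n_heads, f"{name}.attn")
        self.ln2 = LayerNorm(d, name=f"{name}.ln2")
        self.fc1 = Dense(rng, d, ffn_mult * d, f"{name}.fc1")
        self.fc2 = Dense(rng, ffn_mult * d, d, f"{name}.fc2")
        self._h: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return (
            self.ln1.parameters() + self.attn.parameters()
            + self.ln2.parameters() + self.fc1.parameters() + self.fc2.parameters()
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x + self.attn.forward(self.ln1.forward(x))
        h = self.fc1.forward(self.ln2.forward(y))
        self._h = h
        return y + self.fc2.forward(gelu(h))

    def backward(self, dz: np.ndarray) -> np.ndarray:
        dgelu = self.fc2.backward(dz)
        dh = dgelu * gelu_grad(self._h)
        dy = dz + self.ln2.backward(self.fc1.backward(dh))
        dx_branch = self.ln1.backward(self.attn.backward(dy))
        return dy + dx_branch


class TransformerEncoder:
    """Stack of pre-norm blocks with a final layer norm."""

    def __init__(self, rng: np.random.Generator, d: int, n_layers: int, n_heads: int):
        self.blocks = [
            TransformerBlock(rng, d, n_heads, name=f"block{i}")
            for i in range(n_layers)
        ]
        self.ln_f = LayerNorm(d, name="ln_f")

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for b in self.blocks:
            params += b.parameters()
        return params + self.ln_f.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        for b in self.blocks:
            x = b.forward(x)
        return self.ln_f.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.ln_f.backward(dy)
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        return dy


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
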