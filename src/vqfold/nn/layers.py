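"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .tensor import Tensor, concat, softmax, where_mask


class Module:
    """Base class; parameters are discovered recursively by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Tensor], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params: list[Tensor], seen: set[int]) -> None:
        if isinstance(value, Tensor):
            if value.requires_grad and id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float = 1.0):
        std = scale / math.sqrt(n_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gain + self.shift


class MLP(Module):
    def __init__(self, n_in: int, hidden: int, n_out: int,
                 rng: np.random.Generator, n_hidden_layers: int = 1):
        dims = [n_in] + [hidden] * n_hidden_layers + [n_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.table = Tensor(rng.normal(0.0, 0.02, size=(n_tokens, dim)),
                            requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table[np.asarray(idx, dtype=np.int64)]


class MultiHeadAttention(Module):
    """Scaled dot-product attention; self-attention when kv is the query input.

    With `rel_pos_clip` set, a learned per-head relative-position bias
    (clipped at +/- rel_pos_clip) is added to the attention logits, making
    self-attention translation-equivariant along the sequence.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 kv_dim: Optional[int] = None, out_scale: float = 1.0,
                 rel_pos_clip: Optional[int] = None):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        kv_dim = dim if kv_dim is None else kv_dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(kv_dim, dim, rng)
        self.v_proj = Linear(kv_dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng, scale=out_scale)
        self.rel_pos_clip = rel_pos_clip
        self.rel_pos_bias = None
        if rel_pos_clip is not None:
            self.rel_pos_bias = Tensor(
                np.zeros((n_heads, 2 * rel_pos_clip + 1)), requires_grad=True)

    def _split(self, x: Tensor, length: int) -> Tensor:
        # (..., L, dim) -> (..., heads, L, head_dim)
        new_shape = x.shape[:-2] + (length, self.n_heads, self.head_dim)
        return x.reshape(new_shape).swapaxes(-2, -3)

    def __call__(self, x: Tensor, kv: Optional[Tensor] = None,
                 kv_mask: Optional[np.ndarray] = None) -> Tensor:
        kv = x if kv is None else kv
        Lq, Lk = x.shape[-2], kv.shape[-2]
        q = self._split(self.q_proj(x), Lq)
        k = self._split(self.k_proj(kv), Lk)
        v = self._split(self.v_proj(kv), Lk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.head_dim))
        if self.rel_pos_bias is not None and Lq == Lk:
            rel = np.clip(np.arange(Lk)[None, :] - np.arange(Lq)[:, None],
                          -self.rel_pos_clip, self.rel_pos_clip) \
                + self.rel_pos_clip
            scores = scores + self.rel_pos_bias[:, rel]
        if kv_mask is not None:
            m = np.broadcast_to(np.asarray(kv_mask, bool), scores.shape[:-2] + (Lk,))
            scores = where_mask(m[..., None, :], scores, -1e9)
        attn = softmax(scores, axis=-1)
        out = attn @ v  # (..., heads, Lq, head_dim)
        out = out.swapaxes(-2, -3).reshape(x.shape[:-1] + (self.n_heads * self.head_dim,))
        return self.out_proj(out)


def sinusoidal_embedding(positions: np.ndarray, dim: int,
                         max_period: float = 10000.0) -> np.ndarray:
    """Standard transformer sin/cos embedding of integer or real positions."""
    positions = np.asarray(positions, dtype=np.float64)
    half = dim // 2
    freqs = np.exp(-math.log(max_period) * np.arange(half) / max(half - 1, 1))
    args = positions[..., None] * freqs
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=-1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros_like(emb[..., :1])], axis=-1)
    return emb
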