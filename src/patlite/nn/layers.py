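"""Neural-network building blocks on top of the autodiff engine.

Modules mirror the familiar container pattern: attributes that are
:class:`Parameter`, :class:`Module` or :class:`ModuleList` are discovered
recursively, giving dotted parameter names used by the HDF5 checkpoints.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor, softmax

__all__ = ["Module", "ModuleList", "Linear", "LayerNorm",
           "MultiHeadAttention", "FeedForward", "TransformerBlock"]


class Module:
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, (Module, ModuleList)):
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class ModuleList:
    def __init__(self, modules=()):
        self._modules = list(modules)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]

    def append(self, m):
        self._modules.append(m)

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._modules):
            yield from m.named_parameters(prefix=f"{prefix}{i}.")


class Linear(Module):
    """Affine map on the last axis, Glorot-normal initialised."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.normal(0.0, std, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Standard scaled dot-product multi-head self-attention."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"embedding dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, collect_attention: bool = False):
        B, N, D = x.shape
        H, hd = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B,N,D) -> (B,H,N,hd)
            return t.reshape(B, N, H, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        att = softmax(scores, axis=-1)          # (B,H,N,N)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        out = self.wo(out)
        return out, (att.data.copy() if collect_attention else None)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerBlock(Module):
    """Post-norm block: attention -> add&norm -> feed-forward -> add&norm."""

    def __init__(self, dim: int, heads: int, ff_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ff_dim, rng)
        self.norm2 = LayerNorm(dim)

    def __call__(self, x: Tensor, collect_attention: bool = False):
        a, att = self.attn(x, collect_attention=collect_attention)
        h = self.norm1(x + a)
        out = self.norm2(h + self.ffn(h))
        return out, att
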