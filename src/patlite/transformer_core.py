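"""Actigraphy Transformer building blocks.

A week of minute-level actigraphy (T = 10,080) is split into N = T/S
non-overlapping patches of S minutes; each patch becomes one transformer
token via a shared linear (or small convolutional) embedding, fixed
sine/cosine positional embeddings are added, and a stack of post-norm
transformer blocks produces the sequence representation.  Patching reduces
a week to a few hundred tokens (e.g. S = 18 gives N = 560), sidestepping
the quadratic cost of attention on 10,080 raw minutes.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np

from . import nn
from .errors import ValidationError

__all__ = ["PatchConfig", "ModelConfig", "num_patches", "patchify",
           "unpatchify", "positional_encoding", "LinearPatchEmbed",
           "ConvPatchEmbed", "ATEncoder", "PRESETS", "make_config",
           "encoder_param_count", "closed_form_encoder_params"]


# ----------------------------------------------------------------- configs
@dataclasses.dataclass(frozen=True)
class PatchConfig:
    T: int
    S: int

    def __post_init__(self):
        num_patches(self.T, self.S)  # validates divisibility

    @property
    def N(self) -> int:
        return self.T // self.S


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters for the encoder."""

    patch: PatchConfig
    D: int = 64
    layers: int = 2
    heads: int = 4
    ff_dim: int = 128
    embed_mode: str = "linear"          # or "conv"
    dropout: float = 0.0
    conv_channels: tuple[int, int] = (8, 8)
    conv_kernel: int = 3
    preset_name: Optional[str] = None

    def __post_init__(self):
        if self.D % self.heads != 0:
            raise ValidationError(f"D={self.D} must be divisible by heads={self.heads}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if self.embed_mode not in ("linear", "conv"):
            raise ValidationError(f"unknown embed_mode {self.embed_mode!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["patch"] = {"T": self.patch.T, "S": self.patch.S}
        d["conv_channels"] = list(self.conv_channels)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["patch"] = PatchConfig(**d["patch"])
        d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)


# Presets target the published parameter scales of the small/medium/large
# actigraphy foundation models (~285 K / ~1.00 M / ~1.99 M encoder+embedding
# parameters); the released models' exact layer/head/width values are not
# public, so no weight-level equivalence is claimed.  "tiny" is a desk-scale
# config for tests and demos.
PRESETS: dict[str, dict] = {
    "tiny":  dict(S=180, D=16,  layers=1,  heads=4, ff_dim=32),
    "PAT-S": dict(S=18,  D=64,  layers=4,  heads=4, ff_dim=416),
    "PAT-M": dict(S=18,  D=128, layers=5,  heads=8, ff_dim=512),
    "PAT-L": dict(S=18,  D=128, layers=10, heads=8, ff_dim=512),
}


def make_config(preset: str, T: int = 10_080, embed_mode: str = "linear",
                **overrides) -> ModelConfig:
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = dict(PRESETS[preset])
    p.update(overrides)
    S = p.pop("S")
    return ModelConfig(patch=PatchConfig(T=T, S=S), embed_mode=embed_mode,
                       preset_name=preset, **p)


# ------------------------------------------------------------------ patching
def num_patches(T: int, S: int) -> int:
    """N = T/S; raises unless S divides T exactly (no silent truncation)."""
    if T <= 0 or S <= 0:
        raise ValidationError("T and S must be positive")
    if T % S != 0:
        raise ValidationError(f"patch size {S} does not divide series length {T}")
    return T // S


def patchify(x: np.ndarray, S: int) -> np.ndarray:
    """Reshape (..., T) minutes into (..., N, S) patches, order preserved."""
    x = np.asarray(x)
    T = x.shape[-1]
    N = num_patches(T, S)
    return x.reshape(*x.shape[:-1], N, S)


def unpatchify(patches: np.ndarray) -> np.ndarray:
    patches = np.asarray(patches)
    return patches.reshape(*patches.shape[:-2], patches.shape[-2] * patches.shape[-1])


def positional_encoding(N: int, D: int) -> np.ndarray:
    """Fixed sinusoidal positional embeddings, shape (N, D).

    pe[pos, 2i] = sin(pos / 10000^(2i/D)), pe[pos, 2i+1] = cos(same).
    """
    if D % 2 != 0:
        raise ValidationError(f"positional encoding needs even D, got {D}")
    pos = np.arange(N)[:, None].astype(np.float64)
    i = np.arange(D // 2)[None, :].astype(np.float64)
    angle = pos / np.power(10_000.0, 2.0 * i / D)
    pe = np.empty((N, D))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


# ---------------------------------------------------------------- embeddings
class LinearPatchEmbed(nn.Module):
    """One shared affine map S -> D applied to every patch."""

    def __init__(self, S: int, D: int, rng: np.random.Generator):
        self.proj = nn.Linear(S, D, rng)

    def __call__(self, patches: nn.Tensor) -> nn.Tensor:
        return self.proj(patches)


class ConvPatchEmbed(nn.Module):
    """Small shared 1D conv stack within each patch, flattened to D.

    Two same-padded conv layers with ReLU, then a linear map from the
    flattened (S * channels) activations to D.  Shared across patches.
    """

    def __init__(self, S: int, D: int, rng: np.random.Generator,
                 channels: tuple[int, int] = (8, 8), kernel: int = 3):
        self.S, self.channels, self.kernel = S, channels, kernel
        c1, c2 = channels
        std1 = np.sqrt(2.0 / (kernel * 1 + c1))
        std2 = np.sqrt(2.0 / (kernel * c1 + c2))
        self.w1 = nn.Parameter(rng.normal(0.0, std1, size=(kernel * 1, c1)))
        self.b1 = nn.Parameter(np.zeros(c1))
        self.w2 = nn.Parameter(rng.normal(0.0, std2, size=(kernel * c1, c2)))
        self.b2 = nn.Parameter(np.zeros(c2))
        self.out = nn.Linear(S * c2, D, rng)
        pad = kernel // 2
        # window indices into the zero-padded length axis
        self._idx = (np.arange(S)[:, None] + np.arange(kernel)[None, :])
        self._pad = pad

    def _conv(self, x: nn.Tensor, w: nn.Parameter, b: nn.Parameter) -> nn.Tensor:
        # x: (B, S, Cin) -> same-padded conv -> (B, S, Cout)
        B, S, Cin = x.shape
        zeros = nn.Tensor(np.zeros((B, self._pad, Cin)))
        xp = nn.concat([zeros, x, zeros], axis=1)
        win = nn.take_windows(xp, self._idx)          # (B, S, K, Cin)
        win = win.reshape(B, S, self.kernel * Cin)
        return win @ w + b

    def __call__(self, patches: nn.Tensor) -> nn.Tensor:
        B, N, S = patches.shape
        x = patches.reshape(B * N, S, 1)
        x = self._conv(x, self.w1, self.b1).relu()
        x = self._conv(x, self.w2, self.b2).relu()
        x = x.reshape(B * N, S * self.channels[1])
        return self.out(x).reshape(B, N, -1)


def make_patch_embed(cfg: ModelConfig, rng: np.random.Generator) -> nn.Module:
    if cfg.embed_mode == "conv":
        return ConvPatchEmbed(cfg.patch.S, cfg.D, rng,
                              channels=cfg.conv_channels, kernel=cfg.conv_kernel)
    return LinearPatchEmbed(cfg.patch.S, cfg.D, rng)


# ------------------------------------------------------------------- encoder
class ATEncoder(nn.Module):
    """Patch embedding + positional embedding + transformer block stack."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.embed = make_patch_embed(cfg, rng)
        self.blocks = nn.ModuleList(
            nn.TransformerBlock(cfg.D, cfg.heads, cfg.ff_dim, rng)
            for _ in range(cfg.layers))
        self._pe = positional_encoding(cfg.patch.N, cfg.D)

    def embed_series(self, batch: np.ndarray) -> nn.Tensor:
        """(B, T) standardized minutes -> (B, N, D) tokens with positions."""
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 1:
            batch = batch[None, :]
        if batch.shape[-1] != self.cfg.patch.T:
            raise ValidationError(
                f"series length {batch.shape[-1]} != configured T {self.cfg.patch.T}")
        patches = nn.Tensor(patchify(batch, self.cfg.patch.S))
        tokens = self.embed(patches)
        return tokens + nn.Tensor(self._pe)

    def forward_tokens(self, tokens: nn.Tensor, collect_attention: bool = False):
        """Run the block stack; optionally return per-block attention maps.

        Attention maps are (B, heads, n_tok, n_tok) softmax matrices.
        """
        if not np.all(np.isfinite(tokens.data)):
            raise ValidationError("non-finite encoder input")
        atts = []
        x = tokens
        for block in self.blocks:
            x, att = block(x, collect_attention=collect_attention)
            if collect_attention:
                atts.append(att)
        return (x, atts) if collect_attention else (x, None)

    def __call__(self, batch: np.ndarray, collect_attention: bool = False):
        return self.forward_tokens(self.embed_series(batch),
                                   collect_attention=collect_attention)


# ------------------------------------------------------------- param counts
def encoder_param_count(enc: ATEncoder) -> int:
    """Trainable-parameter count by direct summation over arrays."""
    return enc.num_params()


def closed_form_encoder_params(cfg: ModelConfig) -> int:
    """Independent closed-form count for the same architecture.

    Per block: 4 attention projections (D^2 + D each), two LayerNorms
    (2D each), and the feed-forward pair D->ff->D with biases.  Embedding:
    S*D + D for linear mode; conv mode adds the two conv kernels and the
    flatten projection.
    """
    D, ff, S = cfg.D, cfg.ff_dim, cfg.patch.S
    attn = 4 * (D * D + D)
    ffn = D * ff + ff + ff * D + D
    norms = 2 * (2 * D)
    block = attn + ffn + norms
    if cfg.embed_mode == "linear":
        embed = S * D + D
    else:
        c1, c2 = cfg.conv_channels
        k = cfg.conv_kernel
        embed = (k * 1 * c1 + c1) + (k * c1 * c2 + c2) + (S * c2 * D + D)
    return cfg.layers * block + embed
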