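"""Masked-autoencoder pretraining for the actigraphy transformer.

A random fraction of patches (default 90%) is removed from each standardized
week; only the visible patches pass through the encoder.  The encoder
outputs are projected to the decoder width, a single shared learned mask
token is re-inserted at every masked position, positional embeddings are
added again, and a lightweight transformer decoder plus a per-patch linear
head reconstructs the full 10,080-minute signal.  The loss is minute-level
MSE, either over every minute ("all", the default) or over masked minutes
only ("masked_only").
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Optional, Sequence

import h5py
import numpy as np

from . import nn
from .actigraphy_io import ActigraphyDataset
from .errors import NumericalError, ValidationError
from .transformer_core import (ATEncoder, ModelConfig, patchify,
                               positional_encoding)

__all__ = ["MaskSpec", "MAEConfig", "MAEModel", "PretrainedModel",
           "sample_mask", "reconstruction_loss", "pretrain",
           "save_pretrained", "load_pretrained"]


# -------------------------------------------------------------------- masks
@dataclasses.dataclass
class MaskSpec:
    """A visible/masked partition of the N patch indices."""

    N: int
    ratio: float
    masked_idx: np.ndarray
    visible_idx: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self):
        self.masked_idx = np.sort(np.asarray(self.masked_idx, dtype=int))
        self.visible_idx = np.sort(np.asarray(self.visible_idx, dtype=int))
        union = np.union1d(self.masked_idx, self.visible_idx)
        if len(self.masked_idx) + len(self.visible_idx) != self.N or \
                not np.array_equal(union, np.arange(self.N)):
            raise ValidationError("masked and visible must partition 0..N-1")

    def minute_mask(self, S: int) -> np.ndarray:
        """Boolean length-N*S vector marking minutes in masked patches."""
        m = np.zeros(self.N, dtype=bool)
        m[self.masked_idx] = True
        return np.repeat(m, S)


def mask_count(N: int, ratio: float) -> int:
    """floor(ratio * N) — ratio 0 masks nothing, nothing masks everything."""
    return int(math.floor(ratio * N))


def sample_mask(N: int, ratio: float, seed: int | np.random.Generator) -> MaskSpec:
    """Uniform random patch subset of size floor(ratio*N), without replacement."""
    if not 0.0 <= ratio < 1.0:
        raise ValidationError(f"mask ratio must be in [0, 1), got {ratio}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = mask_count(N, ratio)
    perm = rng.permutation(N)
    return MaskSpec(N=N, ratio=ratio, masked_idx=perm[:M], visible_idx=perm[M:],
                    seed=None if isinstance(seed, np.random.Generator) else seed)


def _sample_visible_batch(B: int, N: int, ratio: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-example visible indices, shape (B, N-M), each row sorted."""
    M = mask_count(N, ratio)
    order = np.argsort(rng.random((B, N)), axis=1)
    return np.sort(order[:, M:], axis=1)


# ------------------------------------------------------------------- config
@dataclasses.dataclass
class MAEConfig:
    encoder: ModelConfig
    decoder_layers: int = 1
    decoder_heads: int = 4
    decoder_D: int = 64
    mask_ratio: float = 0.90
    loss_mode: str = "all"              # or "masked_only"
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    val_fraction: float = 0.0           # held-out corpus fraction for early stopping
    patience: Optional[int] = None      # epochs without val improvement; None = off
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mask_ratio < 1.0:
            raise ValidationError("mask_ratio must be in [0, 1)")
        if self.loss_mode not in ("all", "masked_only"):
            raise ValidationError(f"unknown loss_mode {self.loss_mode!r}")
        if self.decoder_D % self.decoder_heads != 0:
            raise ValidationError("decoder_D must be divisible by decoder_heads")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["encoder"] = json.loads(self.encoder.to_json())
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "MAEConfig":
        d = json.loads(s)
        d["encoder"] = ModelConfig.from_json(json.dumps(d["encoder"]))
        return cls(**d)


# -------------------------------------------------------------------- model
class MAEModel(nn.Module):
    """Asymmetric masked autoencoder around an :class:`ATEncoder`."""

    def __init__(self, cfg: MAEConfig, rng: np.random.Generator):
        ecfg = cfg.encoder
        self.cfg = cfg
        self.encoder = ATEncoder(ecfg, rng)
        self.enc_to_dec = nn.Linear(ecfg.D, cfg.decoder_D, rng)
        self.mask_token = nn.Parameter(
            rng.normal(0.0, 0.02, size=cfg.decoder_D))
        self.decoder_blocks = nn.ModuleList(
            nn.TransformerBlock(cfg.decoder_D, cfg.decoder_heads,
                                2 * cfg.decoder_D, rng)
            for _ in range(cfg.decoder_layers))
        self.head = nn.Linear(cfg.decoder_D, ecfg.patch.S, rng)
        self._pe_dec = positional_encoding(ecfg.patch.N, cfg.decoder_D)
        dec = self.decoder_param_count()
        enc = self.encoder_param_count()
        if dec >= enc:
            raise ValidationError(
                f"decoder ({dec} params) must be strictly smaller than "
                f"encoder ({enc} params)")

    def encoder_param_count(self) -> int:
        return self.encoder.num_params()

    def decoder_param_count(self) -> int:
        n = self.enc_to_dec.num_params() + int(self.mask_token.data.size)
        n += sum(b.num_params() for b in self.decoder_blocks)
        n += self.head.num_params()
        return n

    def _visible_indices(self, batch_size: int,
                         masks) -> np.ndarray:
        if isinstance(masks, MaskSpec):
            return np.tile(masks.visible_idx, (batch_size, 1))
        if isinstance(masks, np.ndarray):
            return masks
        return np.stack([m.visible_idx for m in masks])

    def forward(self, batch: np.ndarray, masks) -> tuple[nn.Tensor, dict]:
        """Reconstruct a (B, T) standardized batch under the given masks.

        ``masks`` may be one MaskSpec (shared), a sequence of MaskSpec, or a
        (B, V) array of visible indices.  Returns the (B, T) reconstruction
        and an ``info`` dict recording the encoder/decoder token counts.
        """
        batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
        B = batch.shape[0]
        N = self.cfg.encoder.patch.N
        vis = self._visible_indices(B, masks)
        if vis.shape[0] != B:
            raise ValidationError("one mask per example required")
        tokens = self.encoder.embed_series(batch)            # (B, N, D) + PE
        visible_tokens = nn.gather_tokens(tokens, vis)       # (B, V, D)
        encoded, _ = self.encoder.forward_tokens(visible_tokens)
        dec_in = nn.assemble_tokens(self.enc_to_dec(encoded),
                                    self.mask_token, vis, N)  # (B, N, Dd)
        dec_in = dec_in + nn.Tensor(self._pe_dec)
        x = dec_in
        for block in self.decoder_blocks:
            x, _ = block(x)
        patches = self.head(x)                               # (B, N, S)
        recon = patches.reshape(B, N * self.cfg.encoder.patch.S)
        info = {"n_visible": int(vis.shape[1]),
                "n_encoder_tokens": int(visible_tokens.shape[1]),
                "n_decoder_tokens": int(dec_in.shape[1]),
                "reconstruction_length": int(recon.shape[1])}
        return recon, info

    def reconstruct(self, batch: np.ndarray, masks) -> np.ndarray:
        recon, _ = self.forward(batch, masks)
        return recon.data


def mae_forward(model: MAEModel, series_batch: np.ndarray,
                masks) -> tuple[np.ndarray, dict]:
    """Functional wrapper over :meth:`MAEModel.forward` returning arrays."""
    recon, info = model.forward(series_batch, masks)
    return recon.data, info


# --------------------------------------------------------------------- loss
def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray, mask: MaskSpec,
                        mode: str = "all") -> float:
    """Minute-level MSE between input and reconstruction.

    mode="all" averages over every minute; mode="masked_only" averages over
    the minutes belonging to masked patches.
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValidationError("input and reconstruction shapes differ")
    sq = (x - x_hat) ** 2
    if mode == "all":
        return float(sq.mean())
    if mode == "masked_only":
        if len(mask.masked_idx) == 0:
            raise ValidationError("masked_only loss undefined with empty mask")
        S = x.shape[-1] // mask.N
        mm = mask.minute_mask(S)
        return float(sq[..., mm].mean())
    raise ValidationError(f"unknown loss mode {mode!r}")


def _batch_loss_tensor(x: np.ndarray, recon: nn.Tensor, vis: np.ndarray,
                       N: int, S: int, mode: str) -> nn.Tensor:
    diff = recon - nn.Tensor(x)
    sq = diff * diff
    if mode == "all":
        return sq.mean()
    patch_mask = np.ones((x.shape[0], N), dtype=bool)
    np.put_along_axis(patch_mask, vis, False, axis=1)
    minute_mask = np.repeat(patch_mask, S, axis=1).astype(np.float64)
    total = minute_mask.sum()
    if total == 0:
        raise ValidationError("masked_only loss undefined with empty mask")
    return (sq * nn.Tensor(minute_mask)).sum() * (1.0 / total)


# ----------------------------------------------------------------- training
@dataclasses.dataclass
class PretrainedModel:
    model: MAEModel
    config: MAEConfig
    loss_history: list[float]
    val_history: list[float] = dataclasses.field(default_factory=list)


def pretrain(corpus: ActigraphyDataset, cfg: MAEConfig) -> PretrainedModel:
    """Train the masked autoencoder on a standardized corpus.

    Fresh random masks are drawn per example per epoch; all randomness
    (init, shuffling, masks) flows from ``cfg.seed``.  If ``val_fraction``
    and ``patience`` are set, training early-stops on held-out
    reconstruction loss and the best weights are restored.
    """
    if corpus.n < cfg.batch_size:
        raise ValidationError("corpus smaller than one batch")
    root = np.random.default_rng(cfg.seed)
    init_rng = np.random.default_rng(root.integers(2 ** 31))
    loop_rng = np.random.default_rng(root.integers(2 ** 31))
    model = MAEModel(cfg, init_rng)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    N, S = cfg.encoder.patch.N, cfg.encoder.patch.S

    values = corpus.values
    n_val = int(round(cfg.val_fraction * corpus.n))
    order = loop_rng.permutation(corpus.n)
    val_x = values[order[:n_val]]
    train_x = values[order[n_val:]]

    history: list[float] = []
    val_history: list[float] = []
    best_val = np.inf
    best_state: dict | None = None
    bad_epochs = 0
    for epoch in range(cfg.epochs):
        idx = loop_rng.permutation(len(train_x))
        epoch_losses = []
        for start in range(0, len(idx) - cfg.batch_size + 1, cfg.batch_size):
            xb = train_x[idx[start:start + cfg.batch_size]]
            vis = _sample_visible_batch(len(xb), N, cfg.mask_ratio, loop_rng)
            recon, _ = model.forward(xb, vis)
            loss = _batch_loss_tensor(xb, recon, vis, N, S, cfg.loss_mode)
            if not np.isfinite(loss.data):
                raise NumericalError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
        if n_val > 0:
            vis = _sample_visible_batch(len(val_x), N, cfg.mask_ratio, loop_rng)
            recon, _ = model.forward(val_x, vis)
            vloss = float(_batch_loss_tensor(val_x, recon, vis, N, S,
                                             cfg.loss_mode).data)
            val_history.append(vloss)
            if vloss < best_val - 1e-12:
                best_val, best_state, bad_epochs = vloss, model.state_dict(), 0
            else:
                bad_epochs += 1
                if cfg.patience is not None and bad_epochs >= cfg.patience:
                    break
    if best_state is not None and cfg.patience is not None:
        model.load_state_dict(best_state)
    return PretrainedModel(model=model, config=cfg, loss_history=history,
                           val_history=val_history)


# -------------------------------------------------------------- checkpoints
def save_pretrained(pm: PretrainedModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = pm.config.to_json()
        f.create_dataset("loss_history", data=np.asarray(pm.loss_history))
        f.create_dataset("val_history", data=np.asarray(pm.val_history))
        grp = f.create_group("params")
        for name, arr in pm.model.state_dict().items():
            grp.create_dataset(name, data=arr)


def load_pretrained(path) -> PretrainedModel:
    with h5py.File(path, "r") as f:
        if "config_json" not in f.attrs or "params" not in f:
            raise ValidationError(f"corrupted checkpoint {path}")
        cfg = MAEConfig.from_json(f.attrs["config_json"])
        state = _flatten_h5_group(f["params"])
        loss_history = list(f["loss_history"][()])
        val_history = list(f["val_history"][()])
    model = MAEModel(cfg, np.random.default_rng(0))
    model.load_state_dict(state)
    return PretrainedModel(model=model, config=cfg, loss_history=loss_history,
                           val_history=val_history)


def _flatten_h5_group(grp) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}

    def visit(name, obj):
        if isinstance(obj, h5py.Dataset):
            out[name] = obj[()]

    grp.visititems(visit)
    return out
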