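"""Classifier heads on top of a pretrained (or freshly initialised) encoder.

After pretraining, the decoder and mask token are discarded; the patch
embedding plus encoder stack form the reusable foundation model.  A small
feed-forward head with a sigmoid turns the mean-pooled token representation
into a binary-outcome probability.  Two regimes are supported: end-to-end
fine-tuning (FT, nothing frozen — the primary mode) and linear probing
(LP, encoder and patch embedding frozen, only the head trains).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import h5py
import numpy as np

from . import nn
from .actigraphy_io import ActigraphyDataset
from .errors import NumericalError, ValidationError
from .evaluation import auc
from .pretraining import PretrainedModel, _flatten_h5_group
from .transformer_core import ATEncoder, ModelConfig

__all__ = ["ClassifierConfig", "PATEncoder", "Classifier", "extract_encoder",
           "build_classifier", "train_classifier", "predict_proba",
           "save_classifier", "load_classifier"]


@dataclasses.dataclass
class ClassifierConfig:
    mode: str = "FT"                    # or "LP"
    pooling: str = "mean"               # or "flatten"
    head_hidden: Optional[int] = None
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0
    init: str = "pretrained"            # or "random"

    def __post_init__(self):
        if self.mode not in ("FT", "LP"):
            raise ValidationError(f"mode must be FT or LP, got {self.mode!r}")
        if self.pooling not in ("mean", "flatten"):
            raise ValidationError(f"pooling must be mean or flatten")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ClassifierConfig":
        return cls(**json.loads(s))


class PATEncoder(nn.Module):
    """Patch embedding + encoder extracted from a pretrained autoencoder."""

    def __init__(self, encoder: ATEncoder):
        self.encoder = encoder

    @property
    def cfg(self) -> ModelConfig:
        return self.encoder.cfg

    def __call__(self, batch: np.ndarray, collect_attention: bool = False):
        return self.encoder(batch, collect_attention=collect_attention)


def extract_encoder(model: PretrainedModel) -> PATEncoder:
    """Keep the patch embedding and encoder; drop decoder and mask token.

    The extracted encoder reproduces the pretrained model's encoder
    activations exactly on the same input (an all-visible forward pass).
    """
    return PATEncoder(model.model.encoder)


class Classifier(nn.Module):
    def __init__(self, pat: PATEncoder, cfg: ClassifierConfig,
                 rng: np.random.Generator):
        self.pat = pat
        self.clf_cfg = cfg
        D = pat.cfg.D
        in_dim = D if cfg.pooling == "mean" else D * pat.cfg.patch.N
        if cfg.head_hidden:
            self.hidden = nn.Linear(in_dim, cfg.head_hidden, rng)
            self.out = nn.Linear(cfg.head_hidden, 1, rng)
        else:
            self.hidden = None
            self.out = nn.Linear(in_dim, 1, rng)
        frozen = cfg.mode == "LP"
        for p in self.pat.parameters():
            p.requires_grad = not frozen

    def named_parameters(self, prefix: str = ""):
        yield from self.pat.named_parameters(prefix=prefix + "pat.")
        if self.hidden is not None:
            yield from self.hidden.named_parameters(prefix=prefix + "hidden.")
        yield from self.out.named_parameters(prefix=prefix + "out.")

    def trainable_parameters(self) -> list[nn.Parameter]:
        return [p for p in self.parameters() if p.requires_grad]

    def logits(self, batch: np.ndarray,
               collect_attention: bool = False):
        tokens, atts = self.pat(batch, collect_attention=collect_attention)
        B, N, D = tokens.shape
        if self.clf_cfg.pooling == "mean":
            pooled = tokens.mean(axis=1)
        else:
            pooled = tokens.reshape(B, N * D)
        if self.hidden is not None:
            pooled = self.hidden(pooled).relu()
        z = self.out(pooled).reshape(B)
        return z, atts

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        z, _ = self.logits(batch)
        return z.sigmoid().data


def build_classifier(enc: PATEncoder, cfg: ClassifierConfig) -> Classifier:
    """Attach a sigmoid head; LP mode freezes every encoder weight."""
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2 ** 31))
    return Classifier(enc, cfg, rng)


def _bce_loss(logits: nn.Tensor, y: np.ndarray) -> nn.Tensor:
    # BCE with logits: mean(softplus(z) - y*z), numerically stable
    return (nn.softplus(logits) - nn.Tensor(y) * logits).mean()


def train_classifier(clf: Classifier, train: ActigraphyDataset,
                     val: ActigraphyDataset,
                     cfg: Optional[ClassifierConfig] = None) -> dict:
    """Train with Adam on BCE; early-stop on validation AUC.

    Returns a history dict with per-epoch train loss and validation AUC;
    the best-epoch weights are restored before returning.
    """
    cfg = cfg or clf.clf_cfg
    y_train = train.label_vector()
    y_val = val.label_vector()
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training labels contain a single class")
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2 ** 31) + 1)
    opt = nn.Adam(clf.trainable_parameters(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_auc": []}
    best_auc, best_state, bad = -np.inf, None, 0
    for epoch in range(cfg.epochs):
        idx = rng.permutation(train.n)
        losses = []
        for start in range(0, train.n, cfg.batch_size):
            sel = idx[start:start + cfg.batch_size]
            if len(sel) < 2:
                continue
            z, _ = clf.logits(train.values[sel])
            loss = _bce_loss(z, y_train[sel].astype(np.float64))
            if not np.isfinite(loss.data):
                raise NumericalError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        scores = clf.predict_proba(val.values)
        vauc = auc(y_val, scores)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_auc"].append(vauc)
        if vauc > best_auc + 1e-12:
            best_auc, best_state, bad = vauc, clf.state_dict(), 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    if best_state is not None:
        clf.load_state_dict(best_state)
    history["best_val_auc"] = float(best_auc)
    return history


def predict_proba(clf: Classifier, ds: ActigraphyDataset) -> np.ndarray:
    """Per-participant scores in (0, 1), in dataset order."""
    if ds.T != clf.pat.cfg.patch.T:
        raise ValidationError(
            f"dataset T={ds.T} does not match model T={clf.pat.cfg.patch.T}")
    # chunked to bound memory on large cohorts
    chunks = [clf.predict_proba(ds.values[i:i + 256])
              for i in range(0, ds.n, 256)]
    return np.concatenate(chunks)


# -------------------------------------------------------------- checkpoints
def save_classifier(clf: Classifier, path, provenance: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["encoder_config_json"] = clf.pat.cfg.to_json()
        f.attrs["classifier_config_json"] = clf.clf_cfg.to_json()
        f.attrs["provenance_json"] = json.dumps(provenance or {})
        grp = f.create_group("params")
        for name, arr in clf.state_dict().items():
            grp.create_dataset(name, data=arr)


def load_classifier(path) -> tuple[Classifier, dict]:
    with h5py.File(path, "r") as f:
        if "encoder_config_json" not in f.attrs:
            raise ValidationError(f"corrupted classifier checkpoint {path}")
        ecfg = ModelConfig.from_json(f.attrs["encoder_config_json"])
        ccfg = ClassifierConfig.from_json(f.attrs["classifier_config_json"])
        provenance = json.loads(f.attrs["provenance_json"])
        state = _flatten_h5_group(f["params"])
    enc = PATEncoder(ATEncoder(ecfg, np.random.default_rng(0)))
    clf = Classifier(enc, ccfg, np.random.default_rng(0))
    clf.load_state_dict(state)
    return clf, provenance
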