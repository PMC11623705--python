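"""Reusable end-to-end workflows: split/standardize, fine-tune, benchmark
scorers, and the desk-scale transfer experiment.

These are the procedures the CLI, the test suite and the reproduction
script all share, so experiments are defined in exactly one place.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .actigraphy_io import (ActigraphyDataset, MINUTES_PER_DAY,
                            standardize_per_minute)
from .errors import ValidationError
from .evaluation import auc
from .finetune import (Classifier, ClassifierConfig, PATEncoder,
                       build_classifier, predict_proba, train_classifier)
from .pretraining import MAEConfig, PretrainedModel, pretrain
from .synthetic_data import CohortSpec, generate_cohort, generate_pretrain_corpus
from .transformer_core import ATEncoder, ModelConfig, make_config

__all__ = ["derive_seeds", "stratified_split", "tiny_mae_config",
           "fresh_encoder", "finetune_on_cohort", "make_pat_scorer",
           "daily_profile_logreg_scorer", "pretrain_synthetic",
           "transfer_experiment"]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Fan one global seed out into n independent sub-seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFF_FFFF) for s in state]


def stratified_split(ds: ActigraphyDataset, frac: float,
                     seed: int) -> tuple[ActigraphyDataset, ActigraphyDataset]:
    """Split off a stratified fraction (e.g. 20% validation)."""
    y = ds.label_vector()
    rng = np.random.default_rng(seed)
    hold = []
    for cls in np.unique(y):
        members = np.where(y == cls)[0]
        k = int(round(frac * len(members)))
        hold.append(rng.choice(members, size=k, replace=False))
    hold = np.concatenate(hold)
    mask = np.zeros(ds.n, dtype=bool)
    mask[hold] = True
    return ds.subset(np.where(~mask)[0]), ds.subset(np.where(mask)[0])


def tiny_mae_config(seed: int = 0, epochs: int = 5, mask_ratio: float = 0.90,
                    loss_mode: str = "all", T: int = 10_080,
                    embed_mode: str = "linear") -> MAEConfig:
    """Desk-scale autoencoder config (N=56 patches, D=16, one block)."""
    enc = make_config("tiny", T=T, embed_mode=embed_mode)
    return MAEConfig(encoder=enc, decoder_layers=1, decoder_heads=2,
                     decoder_D=8, mask_ratio=mask_ratio, loss_mode=loss_mode,
                     epochs=epochs, batch_size=32, learning_rate=1e-3,
                     seed=seed)


def fresh_encoder(ecfg: ModelConfig, seed: int,
                  state: Optional[dict] = None) -> PATEncoder:
    """New encoder from config; optionally load pretrained encoder weights."""
    enc = ATEncoder(ecfg, np.random.default_rng(seed))
    if state is not None:
        enc.load_state_dict(state)
    return PATEncoder(enc)


def finetune_on_cohort(cohort: ActigraphyDataset, ccfg: ClassifierConfig,
                       ecfg: ModelConfig,
                       encoder_state: Optional[dict] = None,
                       val_frac: float = 0.2) -> tuple[Classifier, dict]:
    """Split raw cohort 80/20 stratified, standardize each split separately
    per minute, and train a classifier (FT by default)."""
    train_raw, val_raw = stratified_split(cohort, val_frac, ccfg.seed)
    train = standardize_per_minute(train_raw)
    val = standardize_per_minute(val_raw)
    enc = fresh_encoder(ecfg, ccfg.seed, state=encoder_state)
    clf = build_classifier(enc, ccfg)
    history = train_classifier(clf, train, val, ccfg)
    return clf, history


def make_pat_scorer(ecfg: ModelConfig, ccfg: ClassifierConfig,
                    encoder_state: Optional[dict] = None):
    """Benchmark scorer: train a (possibly pretrained) PAT and score a test set.

    Conforms to the ``f(train, val, test) -> scores`` benchmark contract;
    each split is standardized separately, per the evaluation protocol.
    """

    def scorer(train_raw: ActigraphyDataset, val_raw: ActigraphyDataset,
               test_raw: ActigraphyDataset) -> np.ndarray:
        train = standardize_per_minute(train_raw)
        val = standardize_per_minute(val_raw)
        test = standardize_per_minute(test_raw)
        enc = fresh_encoder(ecfg, ccfg.seed, state=encoder_state)
        clf = build_classifier(enc, dataclasses.replace(ccfg))
        train_classifier(clf, train, val, clf.clf_cfg)
        return predict_proba(clf, test)

    return scorer


def daily_profile_logreg_scorer(train_raw: ActigraphyDataset,
                                val_raw: ActigraphyDataset,
                                test_raw: ActigraphyDataset) -> np.ndarray:
    """Simple baseline: logistic regression on hourly day-averaged profiles."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    def features(ds: ActigraphyDataset) -> np.ndarray:
        days = ds.values.reshape(ds.n, -1, MINUTES_PER_DAY)
        daily = days.mean(axis=1)                       # (n, 1440)
        return daily.reshape(ds.n, 24, 60).mean(axis=2)  # hourly means

    scaler = StandardScaler().fit(features(train_raw))
    model = LogisticRegression(max_iter=1000)
    model.fit(scaler.transform(features(train_raw)), train_raw.label_vector())
    return model.predict_proba(scaler.transform(features(test_raw)))[:, 1]


def pretrain_synthetic(n_corpus: int, seed: int, epochs: int = 5,
                       mask_ratio: float = 0.90, loss_mode: str = "all",
                       T: int = 10_080) -> PretrainedModel:
    """Generate a heterogeneous corpus, standardize per minute, pretrain."""
    corpus_seed, mae_seed = derive_seeds(seed, 2)
    corpus = generate_pretrain_corpus(n_corpus, T=T, seed=corpus_seed)
    corpus = standardize_per_minute(corpus)
    cfg = tiny_mae_config(seed=mae_seed, epochs=epochs,
                          mask_ratio=mask_ratio, loss_mode=loss_mode, T=T)
    return pretrain(corpus, cfg)


def transfer_experiment(seed: int, n_seeds: int = 5, corpus_n: int = 2_000,
                        labeled_n: int = 100, wake_shift: float = 180.0,
                        pretrain_epochs: int = 5,
                        finetune_epochs: int = 20) -> dict:
    """Does pretraining help at small labelled n?  Paired across seeds.

    One encoder is pretrained on ``corpus_n`` synthetic weeks; for each of
    ``n_seeds`` replicate seeds a fresh labelled cohort of ``labeled_n``
    participants is drawn and fine-tuned twice with identical settings —
    once from the pretrained encoder, once from random init.  Returns the
    per-seed validation AUCs and their means.
    """
    seeds = derive_seeds(seed, 1 + n_seeds)
    pm = pretrain_synthetic(corpus_n, seeds[0], epochs=pretrain_epochs)
    enc_state = pm.model.encoder.state_dict()
    ecfg = pm.config.encoder
    pre_aucs, rand_aucs = [], []
    for s in seeds[1:]:
        cohort = generate_cohort(CohortSpec(n=labeled_n, base_rate=0.3,
                                            wake_shift_minutes=wake_shift,
                                            seed=s))
        ccfg = ClassifierConfig(mode="FT", epochs=finetune_epochs,
                                batch_size=16, seed=s)
        _, hist_pre = finetune_on_cohort(cohort, ccfg, ecfg,
                                         encoder_state=enc_state)
        _, hist_rand = finetune_on_cohort(cohort, dataclasses.replace(ccfg),
                                          ecfg, encoder_state=None)
        pre_aucs.append(hist_pre["best_val_auc"])
        rand_aucs.append(hist_rand["best_val_auc"])
    return {"seeds": seeds[1:],
            "pretrained_aucs": pre_aucs,
            "random_init_aucs": rand_aucs,
            "pretrained_mean": float(np.mean(pre_aucs)),
            "random_init_mean": float(np.mean(rand_aucs)),
            "pretrain_loss_history": pm.loss_history}
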