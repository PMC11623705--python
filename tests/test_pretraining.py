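"""Masked-autoencoder mechanics: masks, forward contracts, losses, training."""

import numpy as np
import pytest

from patlite.errors import ValidationError
from patlite.pretraining import (MAEConfig, MAEModel, MaskSpec, load_pretrained,
                                 mae_forward, pretrain, reconstruction_loss,
                                 sample_mask, save_pretrained)
from patlite.synthetic_data import generate_pretrain_corpus
from patlite.actigraphy_io import standardize_per_minute
from patlite.workflows import tiny_mae_config

T2 = 2_880          # two days -> N=16 patches of 180 under the tiny config


@pytest.fixture(scope="module")
def tiny_model():
    cfg = tiny_mae_config(seed=1, T=T2)
    return MAEModel(cfg, np.random.default_rng(1)), cfg


# -------------------------------------------------------------------- masks
def test_sample_mask_counts_at_paper_ratio():
    m = sample_mask(560, 0.90, seed=0)
    assert len(m.masked_idx) == 504 and len(m.visible_idx) == 56


def test_sample_mask_ratio_zero_boundary():
    m = sample_mask(10, 0.0, seed=0)
    assert len(m.masked_idx) == 0
    np.testing.assert_array_equal(m.visible_idx, np.arange(10))


def test_sample_mask_rejects_bad_ratio():
    for ratio in (-0.1, 1.0, 1.5):
        with pytest.raises(ValidationError):
            sample_mask(10, ratio, seed=0)


def test_mask_partition_invariant():
    with pytest.raises(ValidationError):
        MaskSpec(N=4, ratio=0.5, masked_idx=[0, 1], visible_idx=[1, 2])


def test_mask_uniformity_monte_carlo():
    """Over 10,000 seeded draws at N=10, ratio=0.5, each index is masked in
    50% +/- 2% of draws (uniform sampling without replacement)."""
    rng = np.random.default_rng(123)
    counts = np.zeros(10)
    for _ in range(10_000):
        counts[sample_mask(10, 0.5, rng).masked_idx] += 1
    np.testing.assert_allclose(counts / 10_000, 0.5, atol=0.02)


# ------------------------------------------------------------ forward pass
def test_mae_forward_token_counts_and_length(tiny_model):
    model, cfg = tiny_model
    N = cfg.encoder.patch.N
    mask = sample_mask(N, 0.75, seed=3)
    x = np.random.default_rng(4).standard_normal((2, T2))
    recon, info = mae_forward(model, x, mask)
    assert info["n_encoder_tokens"] == N - int(0.75 * N) == len(mask.visible_idx)
    assert info["n_decoder_tokens"] == N
    assert recon.shape == (2, T2)
    assert np.all(np.isfinite(recon))


def test_mae_forward_accepts_per_example_masks(tiny_model):
    model, cfg = tiny_model
    N = cfg.encoder.patch.N
    masks = [sample_mask(N, 0.5, seed=s) for s in (1, 2)]
    x = np.random.default_rng(5).standard_normal((2, T2))
    recon, info = mae_forward(model, x, masks)
    assert recon.shape == (2, T2)
    assert info["n_visible"] == N - N // 2


def test_masked_information_property(tiny_model):
    """Permuting the values inside masked patches leaves the encoder input
    bit-identical: the reconstruction cannot peek at masked minutes."""
    model, cfg = tiny_model
    N, S = cfg.encoder.patch.N, cfg.encoder.patch.S
    mask = sample_mask(N, 0.5, seed=7)
    rng = np.random.default_rng(8)
    x = rng.standard_normal(T2)
    x_perm = x.copy()
    for k in mask.masked_idx:
        seg = slice(k * S, (k + 1) * S)
        x_perm[seg] = rng.permutation(x_perm[seg])
    from patlite import nn
    vis = np.tile(mask.visible_idx, (1, 1))
    t1 = nn.gather_tokens(model.encoder.embed_series(x[None]), vis)
    t2 = nn.gather_tokens(model.encoder.embed_series(x_perm[None]), vis)
    assert t1.data.tobytes() == t2.data.tobytes()


# --------------------------------------------------------------------- loss
def test_reconstruction_loss_identity_and_offset():
    mask = sample_mask(8, 0.5, seed=1)
    x = np.random.default_rng(2).standard_normal(8 * 5)
    assert reconstruction_loss(x, x, mask, "all") == 0.0
    assert reconstruction_loss(x, x, mask, "masked_only") == 0.0
    c = 0.7
    assert reconstruction_loss(x, x + c, mask, "all") == pytest.approx(c ** 2)


def test_reconstruction_loss_masked_only_brute_force():
    rng = np.random.default_rng(3)
    mask = sample_mask(8, 0.6, seed=4)
    S = 5
    x, x_hat = rng.standard_normal(40), rng.standard_normal(40)
    expected = np.mean([(x[m] - x_hat[m]) ** 2
                        for k in mask.masked_idx
                        for m in range(k * S, (k + 1) * S)])
    assert reconstruction_loss(x, x_hat, mask, "masked_only") == \
        pytest.approx(expected, abs=1e-12)


def test_loss_decomposition():
    """mode=all equals the |masked|/N-weighted mix of masked and visible MSE."""
    rng = np.random.default_rng(5)
    mask = sample_mask(10, 0.7, seed=6)
    S = 4
    x, x_hat = rng.standard_normal(40), rng.standard_normal(40)
    mm = mask.minute_mask(S)
    masked_mse = np.mean((x[mm] - x_hat[mm]) ** 2)
    visible_mse = np.mean((x[~mm] - x_hat[~mm]) ** 2)
    w = len(mask.masked_idx) / mask.N
    assert reconstruction_loss(x, x_hat, mask, "all") == \
        pytest.approx(w * masked_mse + (1 - w) * visible_mse, abs=1e-12)


def test_masked_only_empty_mask_errors():
    mask = sample_mask(8, 0.0, seed=0)
    x = np.zeros(16)
    with pytest.raises(ValidationError):
        reconstruction_loss(x, x, mask, "masked_only")


def test_decoder_asymmetry_for_shipped_presets():
    """The default lightweight decoder is under a quarter of the encoder."""
    from patlite.transformer_core import make_config
    for preset in ("PAT-S", "PAT-M", "PAT-L"):
        cfg = MAEConfig(encoder=make_config(preset), decoder_layers=1,
                        decoder_heads=4, decoder_D=64)
        model = MAEModel(cfg, np.random.default_rng(0))
        assert model.decoder_param_count() < 0.25 * model.encoder_param_count()


# ----------------------------------------------------------------- training
def test_pretrain_deterministic_and_boundary_ratio():
    corpus = standardize_per_minute(generate_pretrain_corpus(40, T=T2, seed=9))
    cfg = tiny_mae_config(seed=5, epochs=2, T=T2)
    h1 = pretrain(corpus, cfg).loss_history
    h2 = pretrain(corpus, cfg).loss_history
    assert h1 == h2
    corpus64 = standardize_per_minute(generate_pretrain_corpus(64, T=T2, seed=9))
    cfg0 = tiny_mae_config(seed=5, epochs=15, mask_ratio=0.0, T=T2)
    h0 = pretrain(corpus64, cfg0).loss_history
    assert np.all(np.isfinite(h0)) and h0[-1] < h0[0]


def test_checkpoint_round_trip(tmp_path):
    corpus = standardize_per_minute(generate_pretrain_corpus(40, T=T2, seed=9))
    pm = pretrain(corpus, tiny_mae_config(seed=5, epochs=1, T=T2))
    path = tmp_path / "mae.h5"
    save_pretrained(pm, path)
    back = load_pretrained(path)
    assert back.config.to_json() == pm.config.to_json()
    assert back.loss_history == pytest.approx(pm.loss_history)
    for (n1, a1), (n2, a2) in zip(sorted(pm.model.state_dict().items()),
                                  sorted(back.model.state_dict().items())):
        assert n1 == n2
        np.testing.assert_array_equal(a1, a2)
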