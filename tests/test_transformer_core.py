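"""Patching, embeddings, positional encodings and the encoder stack."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patlite import nn
from patlite.errors import ValidationError
from patlite.transformer_core import (ATEncoder, LinearPatchEmbed, PRESETS,
                                      closed_form_encoder_params, make_config,
                                      num_patches, patchify,
                                      positional_encoding, unpatchify)


# ------------------------------------------------------------------ patching
@pytest.mark.parametrize("T,S,expected", [(10_080, 18, 560),
                                          (10_080, 10_080, 1),
                                          (10_080, 60, 168)])
def test_num_patches(T, S, expected):
    assert num_patches(T, S) == expected


def test_num_patches_rejects_non_divisors():
    with pytest.raises(ValidationError):
        num_patches(10_080, 17)
    with pytest.raises(ValidationError):
        num_patches(0, 1)


def test_patchify_definition_and_degenerate_case():
    x = np.arange(36.0)
    p = patchify(x, 18)
    np.testing.assert_array_equal(p[0], np.arange(18.0))
    np.testing.assert_array_equal(p[1], np.arange(18.0, 36.0))
    np.testing.assert_array_equal(patchify(x, 36)[0], x)


@settings(derandomize=True, max_examples=25)
@given(st.integers(1, 8), st.integers(1, 12), st.integers(0, 2 ** 31 - 1))
def test_unpatchify_inverts_patchify(N, S, seed):
    x = np.random.default_rng(seed).standard_normal(N * S)
    np.testing.assert_array_equal(unpatchify(patchify(x, S)), x)


# -------------------------------------------------------------- positional
def test_positional_encoding_row_zero_and_range():
    pe = positional_encoding(560, 64)
    np.testing.assert_array_equal(pe[0, 0::2], 0.0)   # sin 0
    np.testing.assert_array_equal(pe[0, 1::2], 1.0)   # cos 0
    assert pe.min() >= -1.0 and pe.max() <= 1.0


def test_positional_encoding_matches_scalar_formula():
    pe = positional_encoding(8, 8)
    pos, i, D = 3, 1, 8
    angle = pos / 10_000 ** (2 * i / D)
    assert pe[pos, 2 * i] == pytest.approx(math.sin(angle), abs=1e-15)
    assert pe[pos, 2 * i + 1] == pytest.approx(math.cos(angle), abs=1e-15)


def test_positional_encoding_rejects_odd_dim():
    with pytest.raises(ValidationError):
        positional_encoding(4, 7)


# -------------------------------------------------------------- embeddings
def test_linear_embed_zero_weights_gives_bias():
    emb = LinearPatchEmbed(6, 4, np.random.default_rng(0))
    emb.proj.weight.data[:] = 0.0
    emb.proj.bias.data[:] = np.array([1.0, 2.0, 3.0, 4.0])
    out = emb(nn.Tensor(np.random.default_rng(1).random((1, 5, 6))))
    np.testing.assert_allclose(out.data, np.tile([1, 2, 3, 4], (1, 5, 1)))


def test_identical_patches_share_embedding():
    cfg = make_config("tiny", T=2_880)
    enc = ATEncoder(cfg, np.random.default_rng(0))
    patch = np.random.default_rng(1).random(cfg.patch.S)
    series = np.tile(patch, cfg.patch.N)
    tokens = enc.embed(nn.Tensor(patchify(series, cfg.patch.S)[None]))
    np.testing.assert_allclose(tokens.data[0] - tokens.data[0, 0],
                               0.0, atol=1e-12)


def test_conv_embed_output_shape():
    cfg = make_config("tiny", T=2_880, embed_mode="conv")
    enc = ATEncoder(cfg, np.random.default_rng(0))
    out, _ = enc(np.random.default_rng(1).standard_normal((2, 2_880)))
    assert out.shape == (2, cfg.patch.N, cfg.D)


# ------------------------------------------------------------------ encoder
def test_encoder_shape_and_attention_rows():
    cfg = make_config("tiny", T=2_880)
    enc = ATEncoder(cfg, np.random.default_rng(0))
    x = np.random.default_rng(1).standard_normal((3, 2_880))
    out, atts = enc(x, collect_attention=True)
    assert out.shape == (3, cfg.patch.N, cfg.D)
    assert len(atts) == cfg.layers
    assert atts[0].shape == (3, cfg.heads, cfg.patch.N, cfg.patch.N)
    np.testing.assert_allclose(atts[0].sum(axis=-1), 1.0, atol=1e-5)


def test_encoder_rejects_non_finite_input():
    cfg = make_config("tiny", T=2_880)
    enc = ATEncoder(cfg, np.random.default_rng(0))
    bad = np.zeros((1, 16, 16))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValidationError):
        enc.forward_tokens(nn.Tensor(bad))


def test_permutation_equivariance_without_positions():
    """With positional embeddings omitted, mean-pooled encoder output is
    invariant under token permutation (self-attention has no order prior)."""
    cfg = make_config("tiny", T=2_880)
    enc = ATEncoder(cfg, np.random.default_rng(0))
    tokens = np.random.default_rng(1).standard_normal((1, 16, cfg.D))
    perm = np.random.default_rng(2).permutation(16)
    out1, _ = enc.forward_tokens(nn.Tensor(tokens))
    out2, _ = enc.forward_tokens(nn.Tensor(tokens[:, perm]))
    np.testing.assert_allclose(out1.data.mean(axis=1), out2.data.mean(axis=1),
                               atol=1e-5)


def test_forward_deterministic_given_seed():
    cfg = make_config("tiny", T=2_880)
    x = np.random.default_rng(1).standard_normal((2, 2_880))
    out1, _ = ATEncoder(cfg, np.random.default_rng(7))(x)
    out2, _ = ATEncoder(cfg, np.random.default_rng(7))(x)
    np.testing.assert_array_equal(out1.data, out2.data)


# ------------------------------------------------------------ param counts
@pytest.mark.parametrize("preset", ["tiny", "PAT-S"])
@pytest.mark.parametrize("embed_mode", ["linear", "conv"])
def test_param_count_matches_closed_form(preset, embed_mode):
    cfg = make_config(preset, embed_mode=embed_mode)
    enc = ATEncoder(cfg, np.random.default_rng(0))
    assert enc.num_params() == closed_form_encoder_params(cfg)


def test_preset_parameter_monotonicity():
    counts = [closed_form_encoder_params(make_config(p))
              for p in ("PAT-S", "PAT-M", "PAT-L")]
    assert counts[0] < counts[1] < counts[2]
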