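"""Dataset I/O and preprocessing: layouts, z-scoring, smoothing."""

import numpy as np
import pandas as pd
import pytest

from patlite.actigraphy_io import (ActigraphyDataset, apply_stats, from_hdf5,
                                   read_actigraphy, smooth_savgol,
                                   standardize_per_minute, to_hdf5,
                                   write_actigraphy)
from patlite.errors import FormatError, ValidationError


def toy_ds(values, labels=None):
    values = np.asarray(values, dtype=float)
    ids = [f"p{i}" for i in range(values.shape[0])]
    return ActigraphyDataset(ids, values, labels=labels)


# ------------------------------------------------------------------ layouts
@pytest.mark.parametrize("layout", ["wide", "long"])
def test_csv_round_trip(tmp_path, layout):
    rng = np.random.default_rng(0)
    ds = toy_ds(rng.gamma(2.0, 10.0, size=(3, 36)))
    path = tmp_path / f"{layout}.csv"
    write_actigraphy(ds, path, layout=layout)
    back = read_actigraphy(path, layout=layout)
    assert back.ids == ds.ids
    np.testing.assert_allclose(back.values, ds.values, atol=1e-12)


def test_long_layout_infers_T(tmp_path):
    path = tmp_path / "long.csv"
    write_actigraphy(toy_ds(np.arange(36.0)[None, :]), path, layout="long")
    assert read_actigraphy(path, layout="long").T == 36


def test_long_layout_missing_minute_names_participant(tmp_path):
    df = pd.DataFrame({"participant_id": ["a"] * 36, "minute": range(36),
                       "value": 1.0})
    df = df[df["minute"] != 17]
    path = tmp_path / "long.csv"
    df.to_csv(path, index=False)
    with pytest.raises(FormatError, match="a"):
        read_actigraphy(path, layout="long")


def test_long_layout_duplicate_minute_rejected(tmp_path):
    df = pd.DataFrame({"participant_id": ["a"] * 4, "minute": [0, 1, 1, 2],
                       "value": 1.0})
    path = tmp_path / "dup.csv"
    df.to_csv(path, index=False)
    with pytest.raises(FormatError, match="duplicate"):
        read_actigraphy(path, layout="long")


def test_negative_raw_intensity_names_participant(tmp_path):
    ds = toy_ds([[1.0, 2.0], [3.0, -1.0]])
    path = tmp_path / "neg.csv"
    write_actigraphy(ds, path, layout="wide")
    with pytest.raises(ValidationError, match="p1"):
        read_actigraphy(path, layout="wide")


def test_hdf5_round_trip(tmp_path):
    ds = standardize_per_minute(toy_ds(np.random.default_rng(1).random((4, 10)),
                                       labels={"p0": 1, "p1": 0, "p2": 0, "p3": 1}))
    path = tmp_path / "ds.h5"
    to_hdf5(ds, path)
    back = from_hdf5(path)
    assert back.ids == ds.ids and back.labels == ds.labels
    np.testing.assert_array_equal(back.values, ds.values)
    np.testing.assert_array_equal(back.stats[0], ds.stats[0])


# ------------------------------------------------------------ z-scoring
def test_standardize_per_minute_moments_and_stats():
    rng = np.random.default_rng(2)
    ds = standardize_per_minute(toy_ds(rng.gamma(2.0, 5.0, size=(50, 20))))
    assert np.abs(ds.values.mean(axis=0)).max() < 1e-9
    assert np.abs(ds.values.std(axis=0) - 1).max() < 1e-9   # population sd


def test_standardize_zero_variance_minute_maps_to_zero():
    vals = np.random.default_rng(3).random((5, 4))
    vals[:, 2] = 5.0
    ds = standardize_per_minute(toy_ds(vals))
    assert np.all(ds.values[:, 2] == 0.0)
    assert ds.stats[1][2] == 0.0                            # flagged degenerate


def test_standardize_two_point_column_population_convention():
    ds = standardize_per_minute(toy_ds([[0.0], [2.0]]))
    np.testing.assert_allclose(np.sort(ds.values[:, 0]), [-1.0, 1.0])


def test_standardize_idempotent_on_standard_data():
    rng = np.random.default_rng(4)
    once = standardize_per_minute(toy_ds(rng.random((30, 8))))
    twice = standardize_per_minute(once)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


def test_apply_stats_identity_and_consistency():
    rng = np.random.default_rng(5)
    ds = toy_ds(rng.random((10, 6)))
    ident = apply_stats(ds, (np.zeros(6), np.ones(6)))
    np.testing.assert_array_equal(ident.values, ds.values)
    std = standardize_per_minute(ds)
    np.testing.assert_allclose(apply_stats(ds, std.stats).values, std.values)
    zero_sd = apply_stats(ds, (np.zeros(6), np.zeros(6)))
    assert np.all(zero_sd.values == 0.0)
    with pytest.raises(ValidationError):
        apply_stats(ds, (np.zeros(5), np.ones(5)))


# ------------------------------------------------------------- smoothing
def test_savgol_preserves_constants_and_cubics():
    const = smooth_savgol(toy_ds(np.full((1, 200), 7.0)))
    np.testing.assert_allclose(const.values, 7.0, atol=1e-9)
    t = np.arange(200.0)
    cubic = smooth_savgol(toy_ds((t ** 3)[None, :]))
    np.testing.assert_allclose(cubic.values[0, 25:175], (t ** 3)[25:175],
                               atol=1e-6)


def test_savgol_reduces_noise_variance():
    noise = np.random.default_rng(6).standard_normal((1, 500))
    out = smooth_savgol(toy_ds(noise))
    assert out.values.var() < noise.var()


def test_savgol_commutes_with_constant_shift():
    x = np.random.default_rng(7).random((2, 120))
    base = smooth_savgol(toy_ds(x)).values
    shifted = smooth_savgol(toy_ds(x + 3.5)).values
    np.testing.assert_allclose(shifted, base + 3.5, atol=1e-9)


@pytest.mark.parametrize("window,polyorder", [(50, 3), (51, 51), (51, 60)])
def test_savgol_parameter_validation(window, polyorder):
    with pytest.raises(ValueError):
        smooth_savgol(toy_ds(np.zeros((1, 200))), window=window,
                      polyorder=polyorder)
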