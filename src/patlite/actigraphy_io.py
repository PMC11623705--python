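"""Actigraphy dataset containers, CSV/HDF5 I/O, and preprocessing.

A dataset holds one week (T minutes, default 10,080) of minute-level
activity-intensity counts per participant.  Preprocessing follows the
standard actigraphy-transformer recipe: per-minute z-scoring (each minute
position standardised across participants, population standard deviation)
and optional Savitzky-Golay smoothing (window 51, order 3).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Mapping

import h5py
import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import FormatError, ValidationError

__all__ = ["ActigraphySeries", "ActigraphyDataset", "read_actigraphy",
           "write_actigraphy", "read_labels", "write_labels",
           "standardize_per_minute", "standardize_global", "apply_stats",
           "smooth_savgol", "to_hdf5", "from_hdf5"]

MINUTES_PER_WEEK = 10_080
MINUTES_PER_DAY = 1_440


@dataclasses.dataclass
class ActigraphySeries:
    """One participant's length-T activity-intensity vector."""

    participant_id: str
    values: np.ndarray

    @property
    def T(self) -> int:
        return len(self.values)


@dataclasses.dataclass
class ActigraphyDataset:
    """An ordered cohort of same-length series with optional labels/stats.

    ``values`` is the (n, T) matrix; ``stats`` records the per-minute
    (mean, sd) used for standardisation, with sd == 0 flagging degenerate
    minute positions.
    """

    ids: list[str]
    values: np.ndarray                       # (n, T) float
    labels: dict[str, int] | None = None
    stats: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a (n, T) matrix")
        if len(self.ids) != self.values.shape[0]:
            raise ValidationError("one id per row required")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("participant ids must be unique")
        if self.labels is not None:
            unknown = set(self.labels) - set(self.ids)
            if unknown:
                raise ValidationError(f"labels for unknown ids: {sorted(unknown)[:5]}")
        if self.stats is not None:
            mean, sd = (np.asarray(a, dtype=np.float64) for a in self.stats)
            if mean.shape != (self.T,) or sd.shape != (self.T,):
                raise ValidationError("stats vectors must have length T")
            if np.any(sd < 0):
                raise ValidationError("standard deviations must be >= 0")
            self.stats = (mean, sd)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    def series(self) -> Iterator[ActigraphySeries]:
        for pid, row in zip(self.ids, self.values):
            yield ActigraphySeries(pid, row)

    def label_vector(self) -> np.ndarray:
        if self.labels is None:
            raise ValidationError("dataset has no labels")
        missing = [pid for pid in self.ids if pid not in self.labels]
        if missing:
            raise ValidationError(f"missing labels for ids: {missing[:5]}")
        return np.array([self.labels[pid] for pid in self.ids], dtype=int)

    def subset(self, indices) -> "ActigraphyDataset":
        """Positional subset; duplicated indices get suffixed ids."""
        indices = list(indices)
        seen: dict[str, int] = {}
        ids = []
        for i in indices:
            pid = self.ids[i]
            k = seen.get(pid, 0)
            seen[pid] = k + 1
            ids.append(pid if k == 0 else f"{pid}#dup{k}")
        labels = None
        if self.labels is not None:
            labels = {nid: self.labels[self.ids[i]] for nid, i in zip(ids, indices)}
        return ActigraphyDataset(ids, self.values[indices].copy(), labels=labels,
                                 stats=self.stats)

    def validate_raw(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("raw values must be finite")
        bad = np.where((self.values < 0).any(axis=1))[0]
        if bad.size:
            raise ValidationError(
                f"negative raw intensity for participant(s): "
                f"{[self.ids[i] for i in bad[:5]]}")


# ------------------------------------------------------------------ CSV I/O
def read_actigraphy(path, layout: str = "wide") -> ActigraphyDataset:
    """Read a wide or long CSV of minute-level actigraphy.

    Wide layout: header ``participant_id,m0,...,m{T-1}``, one row per
    participant.  Long layout: columns ``participant_id,minute,value`` with
    0-based minute indices covering 0..T-1 exactly once per participant.
    """
    path = Path(path)
    if layout == "wide":
        try:
            df = pd.read_csv(path, dtype={0: str})
        except pd.errors.ParserError as exc:
            raise FormatError(f"ragged or malformed wide CSV {path}: {exc}") from exc
        if df.shape[1] < 2:
            raise FormatError("wide CSV needs an id column plus value columns")
        ids = df.iloc[:, 0].astype(str).tolist()
        values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
        if np.isnan(values).any():
            raise FormatError(f"missing values in wide CSV {path}")
        ds = ActigraphyDataset(ids, values)
    elif layout == "long":
        df = pd.read_csv(path, dtype={"participant_id": str})
        required = {"participant_id", "minute", "value"}
        if not required.issubset(df.columns):
            raise FormatError(f"long CSV must have columns {sorted(required)}")
        T = int(df["minute"].max()) + 1
        rows, ids = [], []
        for pid, grp in df.groupby("participant_id", sort=False):
            minutes = grp["minute"].to_numpy(dtype=int)
            if len(np.unique(minutes)) != len(minutes):
                raise FormatError(f"duplicate (id, minute) rows for participant {pid}")
            expected = np.arange(T)
            if len(minutes) != T or not np.array_equal(np.sort(minutes), expected):
                raise FormatError(
                    f"participant {pid} does not cover minutes 0..{T - 1} exactly once")
            vec = np.empty(T)
            vec[minutes] = grp["value"].to_numpy(dtype=np.float64)
            ids.append(str(pid))
            rows.append(vec)
        ds = ActigraphyDataset(ids, np.vstack(rows))
    else:
        raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")
    ds.validate_raw()
    return ds


def write_actigraphy(ds: ActigraphyDataset, path, layout: str = "wide") -> None:
    path = Path(path)
    if layout == "wide":
        cols = [f"m{t}" for t in range(ds.T)]
        df = pd.DataFrame(ds.values, columns=cols)
        df.insert(0, "participant_id", ds.ids)
        df.to_csv(path, index=False)
    elif layout == "long":
        n, T = ds.values.shape
        df = pd.DataFrame({
            "participant_id": np.repeat(ds.ids, T),
            "minute": np.tile(np.arange(T), n),
            "value": ds.values.ravel(),
        })
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_labels(path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    if not {"participant_id", "label"}.issubset(df.columns):
        raise FormatError("label CSV must have columns participant_id,label")
    labels = dict(zip(df["participant_id"].astype(str), df["label"].astype(int)))
    if not set(labels.values()) <= {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    return labels


def write_labels(labels: Mapping[str, int], path) -> None:
    pd.DataFrame({"participant_id": list(labels),
                  "label": list(labels.values())}).to_csv(path, index=False)


# ------------------------------------------------------------ preprocessing
def standardize_per_minute(ds: ActigraphyDataset) -> ActigraphyDataset:
    """Z-score each minute position across participants (population sd).

    A minute position with zero variance maps to 0 for every participant and
    is flagged by sd == 0 in the recorded stats.  Matches the behaviour of a
    column-wise standard scaler fit on this dataset alone.
    """
    if ds.n < 2:
        raise ValidationError("per-minute standardization needs n >= 2")
    mean = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0)            # population (divide-by-n) convention
    safe = np.where(sd > 0, sd, 1.0)
    z = (ds.values - mean) / safe
    z[:, sd == 0] = 0.0
    return ActigraphyDataset(list(ds.ids), z, labels=ds.labels, stats=(mean, sd))


def standardize_global(ds: ActigraphyDataset) -> ActigraphyDataset:
    """Z-score the whole dataset by its overall mean and population sd.

    The coarser alternative for heterogeneous pretraining corpora, where each
    corpus is standardised with respect to itself rather than per minute
    position.
    """
    mu = float(ds.values.mean())
    sd = float(ds.values.std())
    z = (ds.values - mu) / (sd if sd > 0 else 1.0)
    stats = (np.full(ds.T, mu), np.full(ds.T, sd))
    return ActigraphyDataset(list(ds.ids), z, labels=ds.labels, stats=stats)


def apply_stats(ds: ActigraphyDataset,
                stats: tuple[np.ndarray, np.ndarray]) -> ActigraphyDataset:
    """Z-score with externally supplied per-minute stats (e.g. train-set stats)."""
    mean, sd = (np.asarray(a, dtype=np.float64) for a in stats)
    if mean.shape != (ds.T,) or sd.shape != (ds.T,):
        raise ValidationError(f"stats length must equal T={ds.T}")
    safe = np.where(sd > 0, sd, 1.0)
    z = (ds.values - mean) / safe
    z[:, sd == 0] = 0.0
    return ActigraphyDataset(list(ds.ids), z, labels=ds.labels, stats=(mean, sd))


def smooth_savgol(ds: ActigraphyDataset, window: int = 51,
                  polyorder: int = 3) -> ActigraphyDataset:
    """Savitzky-Golay smoothing of each series (default window 51, order 3).

    Edge handling fits a polynomial to the boundary windows ("interp" mode)
    rather than wrapping across the week boundary.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if window > ds.T:
        raise ValueError(f"window {window} exceeds series length {ds.T}")
    smoothed = savgol_filter(ds.values, window, polyorder, axis=1, mode="interp")
    return ActigraphyDataset(list(ds.ids), smoothed, labels=ds.labels, stats=ds.stats)


# ----------------------------------------------------------------- HDF5 I/O
def to_hdf5(ds: ActigraphyDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ids", data=np.array(ds.ids, dtype=h5py.string_dtype()))
        f.create_dataset("values", data=ds.values)
        if ds.labels is not None:
            f.attrs["labels_json"] = json.dumps(ds.labels)
        if ds.stats is not None:
            f.create_dataset("stats_mean", data=ds.stats[0])
            f.create_dataset("stats_sd", data=ds.stats[1])


def from_hdf5(path) -> ActigraphyDataset:
    with h5py.File(path, "r") as f:
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][()]]
        values = f["values"][()]
        labels = json.loads(f.attrs["labels_json"]) if "labels_json" in f.attrs else None
        stats = None
        if "stats_mean" in f:
            stats = (f["stats_mean"][()], f["stats_sd"][()])
    return ActigraphyDataset(ids, values, labels=labels, stats=stats)
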