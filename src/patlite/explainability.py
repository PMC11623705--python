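"""Attention-based importance profiles.

The attention matrices of the last transformer block are aggregated into a
per-patch importance profile: for each key position (patch), sum the
attention it *receives* over all query positions, average over heads, and
normalise to sum to 1.  The profile is expanded to minutes (each patch
value repeated S times) and foldable into a single 1,440-minute day by
averaging the seven day-slices, ready to overlay on the raw actigraphy as
a red (high) to blue (low) heatmap.

Note on the query-side variant: summing attention across key positions for
each *query* returns exactly 1 for every query (softmax rows are
normalised), i.e. a uniform, information-free profile.  That literal
variant is available via ``mode="query_sum"`` for fidelity checks; the
default is attention received per key, which yields the non-uniform
profiles seen in practice.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .actigraphy_io import MINUTES_PER_DAY
from .errors import ValidationError
from .finetune import Classifier
from .transformer_core import PatchConfig

__all__ = ["ImportanceProfile", "last_block_attention", "patch_importance",
           "importance_to_minutes", "daily_average", "render_importance",
           "profile_to_csv"]


@dataclasses.dataclass
class ImportanceProfile:
    per_patch: np.ndarray            # length N, non-negative, sums to 1

    def __post_init__(self):
        self.per_patch = np.asarray(self.per_patch, dtype=np.float64)
        if np.any(self.per_patch < -1e-12):
            raise ValidationError("importance must be non-negative")
        total = self.per_patch.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValidationError(f"importance must sum to 1, got {total}")

    @property
    def N(self) -> int:
        return len(self.per_patch)


def last_block_attention(clf: Classifier, series: np.ndarray) -> np.ndarray:
    """Attention tensor (heads, N, N) of the last block for one series."""
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValidationError("one series at a time")
    _, atts = clf.logits(series[None, :], collect_attention=True)
    if not atts:
        raise ValidationError("model was run without attention collection")
    return atts[-1][0]               # (heads, N, N)


def patch_importance(att: np.ndarray, mode: str = "received") -> ImportanceProfile:
    """Aggregate a (heads, N, N) attention tensor to per-patch importance.

    mode="received" (default): per key, sum attention over queries, average
    over heads, normalise.  mode="query_sum": the literal query-side sum,
    which is provably uniform for softmax attention.
    """
    att = np.asarray(att, dtype=np.float64)
    if att.ndim != 3 or att.shape[1] != att.shape[2]:
        raise ValidationError("attention tensor must be (heads, N, N)")
    if mode == "received":
        agg = att.sum(axis=1).mean(axis=0)       # sum over queries, mean heads
    elif mode == "query_sum":
        agg = att.sum(axis=2).mean(axis=0)       # sums to 1 per query: uniform
    else:
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    return ImportanceProfile(per_patch=agg / agg.sum())


def importance_to_minutes(profile: ImportanceProfile,
                          patch_cfg: PatchConfig) -> np.ndarray:
    """Length-T vector: each patch value repeated S times."""
    if profile.N != patch_cfg.N:
        raise ValidationError(
            f"profile has {profile.N} patches, config expects {patch_cfg.N}")
    return np.repeat(profile.per_patch, patch_cfg.S)


def daily_average(per_minute: np.ndarray) -> np.ndarray:
    """Fold a week-long minute profile into one 1,440-minute day (mean)."""
    per_minute = np.asarray(per_minute, dtype=np.float64)
    if per_minute.size % MINUTES_PER_DAY != 0:
        raise ValidationError(
            f"length {per_minute.size} is not a multiple of {MINUTES_PER_DAY}")
    return per_minute.reshape(-1, MINUTES_PER_DAY).mean(axis=0)


def profile_to_csv(per_minute: np.ndarray, path) -> None:
    import pandas as pd
    pd.DataFrame({"minute": np.arange(len(per_minute)),
                  "importance": per_minute}).to_csv(path, index=False)


def render_importance(series: np.ndarray, profile: ImportanceProfile,
                      patch_cfg: PatchConfig, out_prefix) -> tuple[str, str]:
    """Write week-view and day-view heatmap figures; headless-safe.

    The activity trace is drawn over a red-to-blue diverging background
    encoding attention importance (red = high).  Returns the two file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = np.asarray(series, dtype=np.float64)
    per_minute = importance_to_minutes(profile, patch_cfg)
    if len(series) != len(per_minute):
        raise ValidationError("series and profile lengths differ")
    daily_imp = daily_average(per_minute)
    daily_act = series.reshape(-1, MINUTES_PER_DAY).mean(axis=0)

    paths = []
    for tag, act, imp in (("week", series, per_minute),
                          ("daily", daily_act, daily_imp)):
        fig, ax = plt.subplots(figsize=(12, 3))
        t = np.arange(len(act))
        lo, hi = float(act.min()), float(act.max())
        pad = 0.05 * (hi - lo + 1e-9)
        mesh = ax.imshow(imp[None, :], aspect="auto", cmap="RdBu_r",
                         extent=(0, len(act), lo - pad, hi + pad),
                         origin="lower")
        ax.plot(t, act, color="black", linewidth=0.5)
        ax.set_xlabel("minute" if tag == "week" else "minute of day")
        ax.set_ylabel("activity")
        fig.colorbar(mesh, ax=ax, label="attention importance")
        path = f"{out_prefix}_{tag}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return tuple(paths)
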