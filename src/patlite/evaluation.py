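"""Supervised evaluation protocol: held-out test set, stratified subsample
sizes, AUC, average-AUC ranking, and percentage-point improvement reporting.

The protocol holds out a fixed test set (2,000 participants at full scale),
then draws stratified training subsets of increasing size — by default 500,
1,000, 2,500 and the whole remaining pool — *with replacement*, carves 20%
of each subset into a validation split, scores every model on the common
test set at every size, and ranks models by the arithmetic mean of their
per-size AUCs.
"""

from __future__ import annotations

import dataclasses
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .actigraphy_io import ActigraphyDataset
from .errors import ValidationError

__all__ = ["EvalPlan", "ResultsLedger", "make_eval_plan", "auc",
           "average_auc", "improvement_pp", "round_half_up", "run_benchmark"]


# -------------------------------------------------------------------- plans
@dataclasses.dataclass
class EvalPlan:
    """Index-level evaluation plan over a labelled dataset.

    ``subsets`` maps requested size -> (train_positions, val_positions) into
    the source dataset; positions may repeat (sampling with replacement)
    but never include test positions.
    """

    test_idx: np.ndarray
    subsets: dict[int, tuple[np.ndarray, np.ndarray]]
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "test_idx": self.test_idx.tolist(),
            "subsets": {str(k): [tr.tolist(), va.tolist()]
                        for k, (tr, va) in self.subsets.items()},
        })

    @classmethod
    def from_json(cls, s: str) -> "EvalPlan":
        d = json.loads(s)
        return cls(test_idx=np.asarray(d["test_idx"], dtype=int),
                   subsets={int(k): (np.asarray(tr, dtype=int),
                                     np.asarray(va, dtype=int))
                            for k, (tr, va) in d["subsets"].items()},
                   seed=d["seed"])


def _stratified_counts(y_pool: np.ndarray, size: int) -> dict[int, int]:
    """Per-class draw counts proportional to pool rates (largest remainder)."""
    classes, counts = np.unique(y_pool, return_counts=True)
    exact = counts / counts.sum() * size
    base = np.floor(exact).astype(int)
    rem = size - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    return dict(zip(classes.tolist(), base.tolist()))


def _stratified_sample(pool: np.ndarray, y: np.ndarray, size: int,
                       rng: np.random.Generator, replace: bool) -> np.ndarray:
    wants = _stratified_counts(y[pool], size)
    picks = []
    for cls, k in wants.items():
        members = pool[y[pool] == cls]
        if not replace and k > len(members):
            raise ValidationError(
                f"cannot draw {k} of class {cls} from {len(members)} without replacement")
        picks.append(rng.choice(members, size=k, replace=replace))
    out = np.concatenate(picks)
    rng.shuffle(out)
    return out


def make_eval_plan(ds: ActigraphyDataset, test_n: int = 2_000,
                   sizes: Optional[Sequence[int]] = None,
                   val_frac: float = 0.2, seed: int = 0,
                   replace: bool = True) -> EvalPlan:
    """Build the held-out test split and per-size stratified training subsets.

    Subsets are sampled with replacement from the non-test pool (duplicates
    allowed within a subset, never crossing into the test set); 20% of each
    subset, stratified, becomes its validation split.  The final default
    size is the whole remaining pool ("N").
    """
    y = ds.label_vector()
    if ds.n <= test_n:
        raise ValidationError(f"need more than test_n={test_n} participants")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(ds.n)
    # stratified held-out test (without replacement)
    test_idx = _stratified_sample(all_idx, y, test_n, rng, replace=False)
    test_idx = np.sort(np.unique(test_idx))
    pool = np.setdiff1d(all_idx, test_idx)
    if sizes is None:
        sizes = [500, 1_000, 2_500, len(pool)]
    subsets: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for size in sizes:
        subset = _stratified_sample(pool, y, size, rng, replace=replace)
        n_val = int(round(val_frac * len(subset)))
        val_pos = _stratified_sample(np.arange(len(subset)), y[subset], n_val,
                                     rng, replace=False)
        val_mask = np.zeros(len(subset), dtype=bool)
        val_mask[val_pos] = True
        subsets[int(size)] = (subset[~val_mask], subset[val_mask])
    return EvalPlan(test_idx=test_idx, subsets=subsets, seed=seed)


# ------------------------------------------------------------------ metrics
def auc(labels, scores) -> float:
    """Area under the ROC curve (ties counted one-half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def round_half_up(x: float, decimals: int) -> float:
    # snap float representation noise (e.g. 0.6964999999999999 for the exact
    # decimal 0.6965) to 10 places before the display rounding
    d = Decimal(repr(float(x))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def average_auc(per_size_aucs: Sequence[float]) -> float:
    """Arithmetic mean of per-size AUCs (the ranking metric), unrounded.

    Display with three decimals via :func:`round_half_up`.
    """
    vals = np.asarray(list(per_size_aucs), dtype=np.float64)
    if vals.size == 0:
        raise ValidationError("average_auc needs at least one value")
    return float(vals.mean())


def improvement_pp(model_auc: float, baseline_auc: float) -> float:
    """Absolute improvement in percentage points, half-up to one decimal."""
    return round_half_up(100.0 * (float(model_auc) - float(baseline_auc)), 1)


# ---------------------------------------------------------------- benchmark
@dataclasses.dataclass
class ResultsLedger:
    """Rows of (model, size, auc) plus derived average-AUC ranking."""

    rows: pd.DataFrame                      # columns: model, size, auc

    def avg_auc(self) -> pd.Series:
        return (self.rows.groupby("model")["auc"].mean()
                .sort_values(ascending=False))

    def improvement(self, model: str, baseline: str) -> float:
        avg = self.rows.groupby("model")["auc"].mean()
        return improvement_pp(avg[model], avg[baseline])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def render_table(self) -> str:
        wide = self.rows.pivot(index="model", columns="size", values="auc")
        wide.insert(0, "Avg AUC", self.rows.groupby("model")["auc"].mean())
        wide = wide.sort_values("Avg AUC", ascending=False)
        headers = ["model", "Avg AUC"] + [f"n={c}" for c in wide.columns[1:]]
        lines = ["| " + " | ".join(headers) + " |",
                 "|" + "|".join("---" for _ in headers) + "|"]
        for model, row in wide.iterrows():
            cells = [f"{round_half_up(v, 3):.3f}" if np.isfinite(v) else "--"
                     for v in row]
            lines.append("| " + " | ".join([str(model)] + cells) + " |")
        return "\n".join(lines)


def run_benchmark(plan: EvalPlan, scorers: Mapping[str, Callable],
                  ds: ActigraphyDataset, verbose: bool = False) -> ResultsLedger:
    """Evaluate each scorer at each training size on the fixed test set.

    Each scorer is ``f(train_ds, val_ds, test_ds) -> scores`` over the test
    rows.  A scorer failure at one size is recorded as a missing (NaN) cell
    and the run continues.
    """
    y = ds.label_vector()
    test_ds = ds.subset(plan.test_idx)
    y_test = y[plan.test_idx]
    records = []
    for name, scorer in scorers.items():
        for size, (tr, va) in plan.subsets.items():
            try:
                scores = scorer(ds.subset(tr), ds.subset(va), test_ds)
                value = auc(y_test, scores)
            except Exception as exc:      # noqa: BLE001 — recorded, run continues
                if verbose:
                    print(f"scorer {name!r} failed at size {size}: {exc}")
                value = float("nan")
            records.append({"model": name, "size": size, "auc": value})
    return ResultsLedger(rows=pd.DataFrame.from_records(records))
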