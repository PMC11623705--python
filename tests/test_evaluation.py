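"""Evaluation protocol: plans, AUC, reporting arithmetic, benchmark runner."""

import numpy as np
import pytest

from patlite.actigraphy_io import ActigraphyDataset
from patlite.errors import ValidationError
from patlite.evaluation import (EvalPlan, auc, average_auc, improvement_pp,
                                make_eval_plan, round_half_up, run_benchmark)
from patlite.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="module")
def labelled_ds():
    return generate_cohort(CohortSpec(n=600, T=1_440, base_rate=0.3, seed=17))


# -------------------------------------------------------------------- plans
def test_plan_sizes_and_disjointness(labelled_ds):
    plan = make_eval_plan(labelled_ds, test_n=200, sizes=[50, 100], seed=1)
    assert len(plan.test_idx) == 200
    test_set = set(plan.test_idx.tolist())
    for size, (tr, va) in plan.subsets.items():
        assert len(tr) + len(va) == size
        assert len(va) == int(round(0.2 * size))
        assert test_set.isdisjoint(tr.tolist() + va.tolist())


def test_plan_stratification_within_two_points(labelled_ds):
    y = labelled_ds.label_vector()
    plan = make_eval_plan(labelled_ds, test_n=200, sizes=[100, 300], seed=2)
    pool = np.setdiff1d(np.arange(labelled_ds.n), plan.test_idx)
    pool_rate = y[pool].mean()
    for size, (tr, va) in plan.subsets.items():
        subset_rate = y[np.concatenate([tr, va])].mean()
        assert abs(subset_rate - pool_rate) <= 0.02


def test_plan_default_sizes_include_remaining_pool(labelled_ds):
    plan = make_eval_plan(labelled_ds, test_n=200, seed=3)
    assert labelled_ds.n - 200 in plan.subsets      # the "N" size
    assert set(plan.subsets) == {500, 1_000, 2_500, 400}


def test_plan_errors(labelled_ds):
    with pytest.raises(ValidationError):
        make_eval_plan(labelled_ds, test_n=600)
    with pytest.raises(ValidationError):
        make_eval_plan(labelled_ds, test_n=100, sizes=[900], replace=False)


def test_plan_json_round_trip(labelled_ds):
    plan = make_eval_plan(labelled_ds, test_n=200, sizes=[50], seed=4)
    back = EvalPlan.from_json(plan.to_json())
    np.testing.assert_array_equal(back.test_idx, plan.test_idx)
    for size in plan.subsets:
        np.testing.assert_array_equal(back.subsets[size][0],
                                      plan.subsets[size][0])


def test_plan_reproducible_from_seed(labelled_ds):
    p1 = make_eval_plan(labelled_ds, test_n=200, sizes=[50], seed=5)
    p2 = make_eval_plan(labelled_ds, test_n=200, sizes=[50], seed=5)
    np.testing.assert_array_equal(p1.test_idx, p2.test_idx)
    np.testing.assert_array_equal(p1.subsets[50][0], p2.subsets[50][0])


# ---------------------------------------------------------------------- AUC
def test_auc_perfect_and_inverted():
    y = np.array([0, 0, 1, 1])
    assert auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
    assert auc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0


def test_auc_ties_match_pairwise_brute_force():
    y = np.array([1, 0, 1, 0])
    s = np.array([0.9, 0.8, 0.8, 0.1])
    total, wins = 0, 0.0
    for i in np.where(y == 1)[0]:
        for j in np.where(y == 0)[0]:
            total += 1
            wins += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
    assert auc(y, s) == pytest.approx(wins / total, abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValidationError):
        auc(np.ones(4), np.arange(4.0))


# ------------------------------------------------------------- reporting
def test_average_auc_identity_and_display_rounding():
    assert average_auc([0.7, 0.7, 0.7, 0.7]) == pytest.approx(0.7)
    assert round_half_up(average_auc((0.771, 0.765, 0.760, 0.771)), 3) == 0.767
    assert round_half_up(average_auc((0.677, 0.695, 0.695, 0.719)), 3) == 0.697


def test_improvement_pp_examples():
    assert improvement_pp(0.767, 0.697) == 7.0
    assert improvement_pp(0.771, 0.683) == 8.8
    assert improvement_pp(0.5, 0.5) == 0.0


# ---------------------------------------------------------------- benchmark
def _feature_scorer(train, val, test):
    return test.values.mean(axis=1)


def _constant_scorer(train, val, test):
    return np.zeros(test.n)


def _broken_scorer(train, val, test):
    raise RuntimeError("boom")


def test_run_benchmark_contracts(labelled_ds):
    plan = make_eval_plan(labelled_ds, test_n=200, sizes=[50, 100], seed=6)
    scorers = {"feature": _feature_scorer, "constant": _constant_scorer,
               "broken": _broken_scorer}
    ledger = run_benchmark(plan, scorers, labelled_ds)
    assert len(ledger.rows) == len(scorers) * 2
    const = ledger.rows.query("model == 'constant'")["auc"]
    assert np.allclose(const, 0.5)                     # constant scores tie
    assert ledger.rows.query("model == 'broken'")["auc"].isna().all()
    # reproducible
    ledger2 = run_benchmark(plan, scorers, labelled_ds)
    assert ledger.rows.equals(ledger2.rows)
    table = ledger.render_table()
    assert "feature" in table and "Avg AUC" in table
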