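"""Model search: metrics, subset enumeration, pooled CV, winner selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from aeroee import (FeatureMatrix, compute_metrics, cross_validate,
                    enumerate_feature_sets, search_best)
from aeroee.search import kfold_indices


def toy_matrix(n=20, p=3, seed=0, noise=0.05, duplicate=False):
    """Small regression instance with a planted linear target (y > 0)."""
    rng = np.random.default_rng(seed)
    cols = [f"f{i}" for i in range(p)]
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=cols,
                     index=[f"id{i}" for i in range(n)])
    coef = np.linspace(1.0, 0.2, p)
    y = pd.Series(20.0 + X.to_numpy() @ coef + rng.normal(0, noise, n),
                  index=X.index, name="ee")
    if duplicate:
        X["f_dup"] = X[cols[0]]
    return FeatureMatrix(activity="running", group="both", X=X, y=y)


# ---------------------------------------------------------------- metrics

def test_metrics_perfect_fit():
    m = compute_metrics([1, 2, 3], [1, 2, 3])
    assert (m.r2, m.mape, m.rmse) == (1.0, 0.0, 0.0)


def test_metrics_worked_pair():
    m = compute_metrics([100, 200], [110, 180])
    assert m.mape == pytest.approx(0.10)
    assert m.rmse == pytest.approx(math.sqrt(250))
    assert m.r2 == pytest.approx(0.9)


def test_metrics_constant_prediction_gives_zero_r2():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    m = compute_metrics(y, np.full_like(y, y.mean()))
    assert m.r2 == pytest.approx(0.0)


def test_metrics_rejections():
    with pytest.raises(ValueError):
        compute_metrics([0.0, 1.0], [1.0, 1.0])  # MAPE undefined at y=0
    with pytest.raises(ValueError):
        compute_metrics([1.0], [1.0])  # too short
    with pytest.raises(ValueError):
        compute_metrics([1.0, 2.0], [1.0, float("nan")])


# ------------------------------------------------------------ enumeration

def test_enumerate_counts_and_canonical_order():
    subsets = enumerate_feature_sets(["a", "b", "c"])
    assert len(subsets) == 7
    assert subsets == [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"),
                       ("b", "c"), ("a", "b", "c")]
    assert len(enumerate_feature_sets(["a", "b", "c"], max_size=1)) == 3
    assert len(enumerate_feature_sets(list("abcdefghijklmno"))) == 2**15 - 1
    with pytest.raises(ValueError):
        enumerate_feature_sets([])
    with pytest.raises(ValueError):
        enumerate_feature_sets(["a", "a"])


# ------------------------------------------------------------------- CV

def _lstsq_predict(Xtr, ytr, Xte):
    A = np.column_stack([np.ones(len(Xtr)), Xtr])
    beta = np.linalg.lstsq(A, ytr, rcond=None)[0]
    return np.column_stack([np.ones(len(Xte)), Xte]) @ beta


def _pooled_cv_oracle(fm, subset, k, seed):
    """Independent pooled-CV oracle: per-fold least-squares refit, metrics
    computed directly from the numpy formulas."""
    X = fm.X[list(subset)].to_numpy()
    y = fm.y.to_numpy()
    yhat = np.empty_like(y)
    for tr, te in kfold_indices(len(y), k, seed):
        yhat[te] = _lstsq_predict(X[tr], y[tr], X[te])
    resid = y - yhat
    mape = np.mean(np.abs(resid) / y)
    rmse = math.sqrt(np.mean(resid**2))
    r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
    return r2, mape, rmse


def test_pooled_cv_matches_per_fold_refit_oracle():
    fm = toy_matrix(n=10, p=2, seed=1)
    m = cross_validate("linear_regression", fm, ("f0", "f1"), k=5, seed=9)
    r2, mape, rmse = _pooled_cv_oracle(fm, ("f0", "f1"), k=5, seed=9)
    assert m.r2 == pytest.approx(r2, abs=1e-9)
    assert m.mape == pytest.approx(mape, abs=1e-12)
    assert m.rmse == pytest.approx(rmse, abs=1e-9)


def test_leave_one_out_equals_per_row_refit():
    fm = toy_matrix(n=6, p=2, seed=2)
    m = cross_validate("linear_regression", fm, ("f0", "f1"), k=6, seed=0)
    r2, mape, rmse = _pooled_cv_oracle(fm, ("f0", "f1"), k=6, seed=0)
    assert m.r2 == pytest.approx(r2, abs=1e-9)
    assert m.mape == pytest.approx(mape, abs=1e-12)


def test_noiseless_linear_target_recovered_perfectly():
    fm = toy_matrix(n=25, p=2, seed=3, noise=0.0)
    m = cross_validate("linear_regression", fm, ("f0", "f1"), k=5, seed=1)
    assert m.r2 == pytest.approx(1.0, abs=1e-9)
    assert m.mape == pytest.approx(0.0, abs=1e-9)


def test_pure_noise_target_yields_nonpositive_r2_in_expectation():
    """When the target is independent of the features, pooled out-of-fold
    R² is negative on average (Monte-Carlo over 200 seeded replicates)."""
    r2s = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"f0": rng.normal(size=15)})
        y = pd.Series(10 + rng.normal(size=15), index=X.index, name="ee")
        fm = FeatureMatrix(activity="running", group="both", X=X, y=y)
        r2s.append(cross_validate("linear_regression", fm, ("f0",),
                                  k=5, seed=seed).r2)
    assert np.mean(r2s) < 0


def test_cv_rejects_too_few_rows_and_unknown_subset():
    fm = toy_matrix(n=4, p=1)
    with pytest.raises(ValueError):
        cross_validate("linear_regression", fm, ("f0",), k=5)
    with pytest.raises(ValueError):
        cross_validate("linear_regression", toy_matrix(), ("nope",), k=5)


# ---------------------------------------------------------------- search

def _brute_force_search(fm, families, k, seed):
    """Independent double-loop oracle with the documented selection rule."""
    best = None
    subsets = []
    cols = list(fm.X.columns)
    for size in range(1, len(cols) + 1):
        subsets += sorted(itertools.combinations(cols, size))
    for s_rank, subset in enumerate(subsets):
        for f_rank, family in enumerate(families):
            m = cross_validate(family, fm, subset, k=k, seed=seed)
            key = (-round(m.r2, 10), round(m.mape, 10), round(m.rmse, 10),
                   len(subset), s_rank, f_rank)
            if best is None or key < best[0]:
                best = (key, family, subset, m)
    return best[1], best[2], best[3]


def test_search_matches_bruteforce_double_loop():
    fm = toy_matrix(n=20, p=5, seed=4, noise=0.3)
    families = ("linear_regression", "decision_tree")
    result = search_best(fm, families=families, k=5, seed=11)
    family, subset, metrics = _brute_force_search(fm, families, k=5, seed=11)
    assert result.model == family
    assert result.feature_set == subset
    assert result.metrics == metrics


def test_single_candidate_single_family_returned():
    fm = toy_matrix(n=12, p=1, seed=5)
    result = search_best(fm, families=("linear_regression",), k=5, seed=0)
    assert result.model == "linear_regression"
    assert result.feature_set == ("f0",)


def test_duplicate_column_tiebreak_prefers_smaller_subset():
    fm = toy_matrix(n=15, p=1, seed=6, duplicate=True)
    result = search_best(fm, families=("linear_regression",), k=5, seed=0)
    assert len(result.feature_set) == 1


def test_search_is_deterministic():
    fm = toy_matrix(n=18, p=3, seed=7, noise=0.3)
    a = search_best(fm, families=("linear_regression", "decision_tree"),
                    k=5, seed=2)
    b = search_best(fm, families=("linear_regression", "decision_tree"),
                    k=5, seed=2)
    assert a == b
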