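"""Exhaustive feature-subset model search with pooled k-fold cross-validation.

Seven regression families are evaluated over every candidate feature subset
(optionally size-capped).  For each (family, subset) pair a seeded shuffled
k-fold split is used; out-of-fold predictions are pooled across folds and
the three metrics — R², MAPE and RMSE — are computed once on the pooled
vector.  The winner is the pair with the best R², then smallest MAPE, then
smallest RMSE, with deterministic tie-breaks (smaller subset, canonical
subset order, family list order).

Hyperparameters are pinned to an explicit versioned set rather than
whatever a library release happens to default to, so results reproduce
across environments.  Scale-sensitive families (SVR, Bayesian ridge) are
z-scored inside each training fold; tree families see raw features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge, LinearRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .config import KNOWN_FAMILIES
from .features import FeatureMatrix

__all__ = [
    "HYPERPARAMETER_VERSION",
    "MODEL_ALPHA",
    "EvalMetrics",
    "SearchResult",
    "make_estimator",
    "compute_metrics",
    "enumerate_feature_sets",
    "kfold_indices",
    "cross_validate",
    "search_best",
]

HYPERPARAMETER_VERSION = "1.0"

#: complexity penalty α by family: 0 for linear models, 0.1 for single
#: nonlinear learners, 0.2 for tree ensembles
MODEL_ALPHA = {
    "linear_regression": 0.0,
    "bayesian_ridge": 0.0,
    "decision_tree": 0.1,
    "svr": 0.1,
    "random_forest": 0.2,
    "xgboost_style_boosting": 0.2,
    "gradient_boosting": 0.2,
}

_STANDARDIZED_FAMILIES = frozenset({"svr", "bayesian_ridge"})


def make_estimator(family: str, seed: int = 0):
    """Instantiate a family with the pinned version-1.0 hyperparameters."""
    if family == "linear_regression":
        est = LinearRegression()
    elif family == "bayesian_ridge":
        est = BayesianRidge(max_iter=300)
    elif family == "random_forest":
        est = RandomForestRegressor(n_estimators=50, random_state=seed,
                                    n_jobs=1)
    elif family == "gradient_boosting":
        est = GradientBoostingRegressor(n_estimators=50, learning_rate=0.1,
                                        max_depth=3, random_state=seed)
    elif family == "svr":
        est = SVR(kernel="rbf", C=10.0, epsilon=0.01)
    elif family == "xgboost_style_boosting":
        est = XGBRegressor(n_estimators=50, max_depth=3, learning_rate=0.1,
                           random_state=seed, n_jobs=1, verbosity=0,
                           tree_method="hist")
    elif family == "decision_tree":
        est = DecisionTreeRegressor(random_state=seed)
    else:
        raise ValueError(f"unknown model family {family!r}")
    if family in _STANDARDIZED_FAMILIES:
        est = make_pipeline(StandardScaler(), est)
    return est


@dataclass(frozen=True)
class EvalMetrics:
    """R², MAPE (fraction) and RMSE (kcal/min) for one fitted model."""

    r2: float
    mape: float  # fraction; multiply by 100 for percent
    rmse: float

    @property
    def mape_pct(self) -> float:
        return 100.0 * self.mape


@dataclass(frozen=True)
class SearchResult:
    activity: str
    group: str
    model: str
    feature_set: tuple[str, ...]
    metrics: EvalMetrics
    n: int
    cv_seed: int


def compute_metrics(y, yhat) -> EvalMetrics:
    """Compute R², MAPE and RMSE from targets and predictions.

        mape = mean(|y − ŷ| / y)          (y must be strictly positive)
        rmse = sqrt(mean((y − ŷ)²))
        r2   = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²  (may be negative)
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("targets and predictions must have equal length")
    if y.size < 2:
        raise ValueError("at least 2 observations are required")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("targets and predictions must be finite")
    if np.any(y == 0):
        raise ValueError("MAPE undefined: some targets are zero")
    resid = y - yhat
    mape = float(np.mean(np.abs(resid) / np.abs(y)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return EvalMetrics(r2=r2, mape=mape, rmse=rmse)


def enumerate_feature_sets(candidates, max_size: int | None = None
                           ) -> list[tuple[str, ...]]:
    """All non-empty subsets of ``candidates`` up to ``max_size``.

    Canonical deterministic order: by subset size, then lexicographic within
    a size; subsets themselves keep candidate order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate feature list must be non-empty")
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate features must be unique")
    cap = len(candidates) if max_size is None else min(max_size, len(candidates))
    subsets = []
    for size in range(1, cap + 1):
        level = [tuple(c) for c in itertools.combinations(candidates, size)]
        level.sort()
        subsets.extend(level)
    return subsets


def kfold_indices(n: int, k: int, seed: int):
    """Seeded shuffled k-fold split, as (train_idx, test_idx) pairs."""
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def cross_validate(family: str, fm: FeatureMatrix,
                   subset: tuple[str, ...] | None = None,
                   k: int = 5, seed: int = 0) -> EvalMetrics:
    """Pooled k-fold cross-validation of one family on one feature subset.

    Out-of-fold predictions are pooled across folds and the metrics are
    computed once on the pooled vector (one metric evaluation, not a
    per-fold average).  Deterministic given (seed, data, hyperparameters).
    """
    cols = list(subset) if subset is not None else list(fm.X.columns)
    missing = [c for c in cols if c not in fm.X.columns]
    if missing:
        raise ValueError(f"subset not in feature matrix: {missing}")
    X = fm.X[cols].to_numpy(dtype=float)
    y = fm.y.to_numpy(dtype=float)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    yhat = np.empty(n)
    for train_idx, test_idx in kfold_indices(n, k, seed):
        est = make_estimator(family, seed=seed)
        est.fit(X[train_idx], y[train_idx])
        yhat[test_idx] = est.predict(X[test_idx])
    return compute_metrics(y, yhat)


def _result_key(metrics: EvalMetrics, subset: tuple[str, ...],
                subset_rank: int, family_rank: int):
    # maximise r2; minimise mape, rmse; then prefer smaller subsets, earlier
    # canonical order, earlier family; metrics rounded to 10 decimals so
    # duplicate-information subsets tie instead of splitting on float dust
    return (-round(metrics.r2, 10), round(metrics.mape, 10),
            round(metrics.rmse, 10), len(subset), subset_rank, family_rank)


def search_best(fm: FeatureMatrix, families=KNOWN_FAMILIES,
                max_size: int | None = None, k: int = 5, seed: int = 0,
                subsets=None) -> SearchResult:
    """Evaluate every (family, subset) pair and return the winner.

    ``subsets`` overrides the exhaustive enumeration (used by sensor-budget
    ablations); otherwise all subsets of the matrix's columns up to
    ``max_size`` are searched.  Winner by (R² desc, MAPE asc, RMSE asc),
    ties broken by smaller subset, canonical subset order, family order.
    """
    families = list(families)
    if not families:
        raise ValueError("at least one model family is required")
    if subsets is None:
        subsets = enumerate_feature_sets(list(fm.X.columns), max_size)
    else:
        subsets = [tuple(s) for s in subsets]
    if not subsets:
        raise ValueError("empty feature-subset space")

    best = None
    for subset_rank, subset in enumerate(subsets):
        for family_rank, family in enumerate(families):
            metrics = cross_validate(family, fm, subset, k=k, seed=seed)
            key = _result_key(metrics, subset, subset_rank, family_rank)
            if best is None or key < best[0]:
                best = (key, family, subset, metrics)
    _, family, subset, metrics = best
    return SearchResult(activity=fm.activity, group=fm.group, model=family,
                        feature_set=subset, metrics=metrics, n=fm.n,
                        cv_seed=seed)
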