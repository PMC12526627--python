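"""The three studies run on a cohort: per-group best-model search, the
sensor-count ablation at fixed sample size, the sample-size ablation with
heart-rate-only sensing, and the Triple-E configuration comparison.

Every experiment is a pure function of (cohort, settings, seed): identical
inputs reproduce identical outputs.  Sensor budgets are enforced by
enumerating exactly the feature subsets whose wearable requirement equals
the budget; the heart-rate-only studies restrict wearables to the strap
(HR, ΔHR, resting HR) while demographic covariates remain available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .cohort import SITES, Cohort
from .config import JsonlLogger, SearchSettings, derive_seed
from .features import (DEMOGRAPHIC_FEATURES, FeatureMatrix, assemble_features,
                       filter_complete)
from .search import EvalMetrics, SearchResult, cross_validate, search_best
from .triple_e import (SensorConfiguration, TripleEScore, alpha_for,
                       score_configuration, sensors_required)

__all__ = [
    "AblationPoint",
    "AblationCurve",
    "ConfigSpec",
    "ConfigurationEntry",
    "ConfigurationReport",
    "HR_ONLY_CANDIDATES",
    "budget_subsets",
    "run_group_search",
    "sensor_count_ablation",
    "sample_size_ablation",
    "evaluate_configurations",
]

#: candidate features when only the heart-rate strap is worn: demographics
#: plus the three strap-served features (no accelerometer VM columns)
HR_ONLY_CANDIDATES = tuple(DEMOGRAPHIC_FEATURES) + ("resting_hr", "hr",
                                                    "delta_hr")

#: default feature pools for sensor-budget enumeration; kept deliberately
#: small so budget sweeps stay tractable (fully overridable)
DEFAULT_HR_POOL = ("delta_hr", "hr")
DEFAULT_DEMO_POOL = ("height", "body_mass", "sex")
DEFAULT_DEMO_CAP = 2


@dataclass(frozen=True)
class AblationPoint:
    level: int  # sensor count or sample size
    metrics: EvalMetrics  # replicate-averaged
    result: SearchResult  # the winning configuration behind this point


@dataclass(frozen=True)
class AblationCurve:
    axis: str  # "sensor_count" | "sample_size"
    activity: str
    scope: str
    points: tuple[AblationPoint, ...]
    seed: int

    def __post_init__(self) -> None:
        levels = [p.level for p in self.points]
        if levels != sorted(set(levels)):
            raise ValueError("ablation levels must be strictly increasing")


@dataclass(frozen=True)
class ConfigSpec:
    """A (label, sample size, sensor budget) configuration to score."""

    label: str
    n: int
    budget: int
    scope: str = "elite"
    site_pool: tuple[str, ...] | None = None  # None -> all five sites


@dataclass(frozen=True)
class ConfigurationEntry:
    label: str
    config: SensorConfiguration
    metrics: EvalMetrics
    score: TripleEScore


@dataclass(frozen=True)
class ConfigurationReport:
    entries: tuple[ConfigurationEntry, ...]
    ranking: tuple[str, ...] = field(default=())  # labels, best area first

    def __post_init__(self) -> None:
        if not self.ranking:
            order = sorted(self.entries, key=lambda e: -e.score.area)
            object.__setattr__(self, "ranking",
                               tuple(e.label for e in order))
        if sorted(self.ranking) != sorted(e.label for e in self.entries):
            raise ValueError("ranking must be a permutation of the entries")


def budget_subsets(budget: int, hr_pool=DEFAULT_HR_POOL, site_pool=SITES,
                   demo_pool=DEFAULT_DEMO_POOL, demo_cap=DEFAULT_DEMO_CAP
                   ) -> list[tuple[str, ...]]:
    """Feature subsets whose wearable requirement equals ``budget`` exactly.

    A subset is (optional demographics) ∪ (optional strap features) ∪ (VM
    features of chosen sites); the strap contributes one sensor when any of
    its features is present.  Returns [] when the budget is infeasible.
    """
    if budget < 1:
        raise ValueError("sensor budget must be >= 1")
    demo_options = [()]
    for size in range(1, min(demo_cap, len(demo_pool)) + 1):
        demo_options += list(itertools.combinations(demo_pool, size))
    hr_options = []
    for size in range(1, len(hr_pool) + 1):
        hr_options += list(itertools.combinations(hr_pool, size))

    subsets = []
    for strap in (0, 1):
        n_sites = budget - strap
        if n_sites < 0 or n_sites > len(site_pool):
            continue
        site_choices = list(itertools.combinations(site_pool, n_sites))
        strap_choices = hr_options if strap else [()]
        for sites in site_choices:
            vm = tuple(f"vm_{s}" for s in sites)
            for hr_part in strap_choices:
                for demo in demo_options:
                    subset = demo + hr_part + vm
                    if subset:
                        subsets.append(subset)
    return subsets


def run_group_search(cohort: Cohort, activity: str, group: str,
                     settings: SearchSettings | None = None,
                     seed: int = 0) -> SearchResult:
    """Best (model, feature subset) for one activity × group.

    The cohort is completeness-filtered first; the group must retain at
    least 10 complete members for the 5-fold search to be meaningful.
    """
    settings = settings or SearchSettings()
    complete = filter_complete(cohort)
    n_members = sum(1 for p in complete.profiles if p.group == group)
    if n_members < 10:
        raise ValueError(
            f"group {group!r} has only {n_members} complete members (need 10)")
    fm = assemble_features(complete, activity, group)
    return search_best(fm, families=settings.families,
                       max_size=settings.max_size, k=settings.cv_folds,
                       seed=derive_seed(seed, f"group_search:{activity}:{group}"))


def _subsample_ids(ids: list[str], size: int, rng: np.random.Generator
                   ) -> list[str]:
    chosen = rng.choice(len(ids), size=size, replace=False)
    return [ids[i] for i in sorted(chosen)]


def _stratified_subsample(cohort: Cohort, scope: str, size: int,
                          rng: np.random.Generator) -> list[str]:
    if scope != "both":
        ids = [p.id for p in cohort.profiles if p.group == scope]
        if size > len(ids):
            raise ValueError(f"requested {size} of {len(ids)} {scope} members")
        return _subsample_ids(ids, size, rng)
    # stratify by group: proportional allocation, remainder by group order
    groups = {}
    for p in cohort.profiles:
        groups.setdefault(p.group, []).append(p.id)
    names = list(groups)
    base = size // len(names)
    counts = {g: base for g in names}
    for g in names[: size - base * len(names)]:
        counts[g] += 1
    picked = []
    for g in names:
        if counts[g] > len(groups[g]):
            raise ValueError(f"requested {counts[g]} of {len(groups[g])} "
                             f"{g} members")
        picked += _subsample_ids(groups[g], counts[g], rng)
    order = {pid: i for i, pid in enumerate(cohort.participant_ids)}
    return sorted(picked, key=order.__getitem__)


def sensor_count_ablation(cohort: Cohort, activity: str, n_fixed: int = 20,
                          budgets=(1, 2, 3, 4, 5, 6), scope: str = "elite",
                          settings: SearchSettings | None = None,
                          seed: int = 0,
                          hr_pool=DEFAULT_HR_POOL, site_pool=SITES,
                          demo_pool=DEFAULT_DEMO_POOL,
                          demo_cap=DEFAULT_DEMO_CAP,
                          logger: JsonlLogger | None = None) -> AblationCurve:
    """Best achievable metrics at each sensor budget, fixed sample size.

    The same seeded subsample of ``n_fixed`` complete participants is reused
    across budgets; at each budget X the search is restricted to feature
    subsets needing exactly X wearables.  Infeasible budgets are skipped
    with a log entry.
    """
    settings = settings or SearchSettings()
    complete = filter_complete(cohort)
    rng = np.random.default_rng(derive_seed(seed, f"sensor_ablation:{activity}"))
    ids = _stratified_subsample(complete, scope, n_fixed, rng)
    fm = assemble_features(complete.subset(ids), activity,
                           scope if scope != "both" else "both")

    points = []
    for budget in budgets:
        subsets = budget_subsets(budget, hr_pool=hr_pool, site_pool=site_pool,
                                 demo_pool=demo_pool, demo_cap=demo_cap)
        if not subsets:
            if logger:
                logger.log("sensor_ablation", activity=activity, budget=budget,
                           skipped="infeasible budget")
            continue
        result = search_best(fm, families=settings.families,
                             max_size=None, k=settings.cv_folds,
                             seed=derive_seed(seed, "sensor_ablation_cv",
                                              budget),
                             subsets=subsets)
        assert sensors_required(result.feature_set) == budget
        points.append(AblationPoint(level=budget, metrics=result.metrics,
                                    result=result))
        if logger:
            logger.log("sensor_ablation", activity=activity, budget=budget,
                       n=len(ids), r2=result.metrics.r2,
                       mape=result.metrics.mape, model=result.model)
    return AblationCurve(axis="sensor_count", activity=activity, scope=scope,
                         points=tuple(points), seed=seed)


def _mean_metrics(metrics_list) -> EvalMetrics:
    return EvalMetrics(
        r2=float(np.mean([m.r2 for m in metrics_list])),
        mape=float(np.mean([m.mape for m in metrics_list])),
        rmse=float(np.mean([m.rmse for m in metrics_list])),
    )


def sample_size_ablation(cohort: Cohort, activity: str, sizes=(20, 30, 40),
                         settings: SearchSettings | None = None,
                         seed: int = 0, replicates: int = 20,
                         logger: JsonlLogger | None = None) -> AblationCurve:
    """Heart-rate-only performance as a function of sample size.

    Wearable features are restricted to the strap (demographics still
    allowed).  The winning (model, subset) is selected once on the full
    complete cohort; for each smaller n it is re-cross-validated on seeded
    group-stratified subsamples and the metrics averaged over replicates.
    """
    settings = settings or SearchSettings(max_size=2)
    complete = filter_complete(cohort)
    fm_full = assemble_features(complete, activity, "both")
    n_complete = fm_full.n
    if max(sizes) > n_complete:
        raise ValueError(
            f"largest size {max(sizes)} exceeds the {n_complete} complete "
            "participants")

    hr_fm = FeatureMatrix(activity=activity, group="both",
                          X=fm_full.X[list(HR_ONLY_CANDIDATES)], y=fm_full.y)
    winner = search_best(hr_fm, families=settings.families,
                         max_size=settings.max_size, k=settings.cv_folds,
                         seed=derive_seed(seed, f"sample_ablation:{activity}"))

    points = []
    for n in sizes:
        if n == n_complete:
            reps = [winner.metrics]
        else:
            reps = []
            for r in range(replicates):
                rng = np.random.default_rng(
                    derive_seed(seed, f"sample_ablation_draw:{activity}:{n}", r))
                ids = _stratified_subsample(complete, "both", n, rng)
                sub = hr_fm.restrict(ids)
                reps.append(cross_validate(
                    winner.model, sub, winner.feature_set,
                    k=settings.cv_folds,
                    seed=derive_seed(seed, f"sample_ablation_cv:{n}", r)))
        metrics = _mean_metrics(reps)
        points.append(AblationPoint(level=n, metrics=metrics, result=winner))
        if logger:
            logger.log("sample_ablation", activity=activity, n=n,
                       replicates=len(reps), r2=metrics.r2, mape=metrics.mape,
                       model=winner.model,
                       feature_set=";".join(winner.feature_set))
    return AblationCurve(axis="sample_size", activity=activity, scope="both",
                         points=tuple(points), seed=seed)


def _default_config_specs() -> tuple[ConfigSpec, ...]:
    return (
        ConfigSpec(label="N20_S3", n=20, budget=3, scope="elite"),
        ConfigSpec(label="N20_S2", n=20, budget=2, scope="elite",
                   site_pool=("right_wrist",)),
        ConfigSpec(label="N40_S1", n=40, budget=1, scope="both"),
    )


def evaluate_configurations(cohort: Cohort, activity: str,
                            configs: tuple[ConfigSpec, ...] | None = None,
                            settings: SearchSettings | None = None,
                            seed: int = 0, y_max: int = 6, n_ref: int = 40,
                            logger: JsonlLogger | None = None
                            ) -> ConfigurationReport:
    """Triple-E comparison of representative (N, sensor) configurations.

    Defaults mirror the three canonical setups: the best three-sensor elite
    configuration at N=20, the strap plus right-wrist accelerometer at N=20,
    and heart-rate-only sensing at the full N=40.  Infeasible configurations
    are excluded with a log entry; entries are ranked by composite area.
    """
    settings = settings or SearchSettings()
    configs = configs if configs is not None else _default_config_specs()
    complete = filter_complete(cohort)

    entries = []
    for spec in configs:
        site_pool = spec.site_pool if spec.site_pool is not None else SITES
        subsets = budget_subsets(spec.budget, site_pool=site_pool)
        available = (len(complete.profiles) if spec.scope == "both" else
                     sum(1 for p in complete.profiles if p.group == spec.scope))
        if not subsets or spec.n > available:
            if logger:
                logger.log("evaluate_configurations", label=spec.label,
                           skipped="infeasible configuration")
            continue
        rng = np.random.default_rng(
            derive_seed(seed, f"config:{activity}:{spec.label}"))
        ids = _stratified_subsample(complete, spec.scope, spec.n, rng)
        fm = assemble_features(
            complete.subset(ids), activity,
            spec.scope if spec.scope != "both" else "both")
        result = search_best(fm, families=settings.families, max_size=None,
                             k=settings.cv_folds,
                             seed=derive_seed(seed, f"config_cv:{spec.label}"),
                             subsets=subsets)
        config = SensorConfiguration(x_sensors=spec.budget, n=spec.n,
                                     model=result.model, y_max=y_max,
                                     n_ref=n_ref)
        score = score_configuration(config, result.metrics.r2,
                                    result.metrics.mape)
        entries.append(ConfigurationEntry(label=spec.label, config=config,
                                          metrics=result.metrics, score=score))
        if logger:
            logger.log("evaluate_configurations", label=spec.label,
                       n=spec.n, x=spec.budget, model=result.model,
                       alpha=alpha_for(result.model), area=score.area)
    return ConfigurationReport(entries=tuple(entries))
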