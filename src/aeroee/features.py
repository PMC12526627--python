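"""Steady-state feature extraction: the per-participant predictor table.

One activity trace is reduced to its steady-state (penultimate) minute:
heart rate, ΔHR (activity minus resting heart rate), and the vector
magnitude (VM) of triaxial counts at each of the five accelerometer sites.
Together with demographic and body-composition covariates these form the
fixed 15-column candidate feature set; the criterion energy expenditure of
the same minute is the regression target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ACTIVITIES, GROUPS, SITES, ActivityTrace, Cohort

__all__ = [
    "FEATURE_COLUMNS",
    "HR_FEATURES",
    "VM_FEATURES",
    "DEMOGRAPHIC_FEATURES",
    "MinuteSummary",
    "FeatureMatrix",
    "vector_magnitude",
    "steady_state_minute",
    "filter_complete",
    "assemble_features",
]

#: canonical, ordered candidate feature set
FEATURE_COLUMNS = (
    "age", "sex", "height", "body_mass", "bmi", "fat_pct", "skeletal_muscle",
    "resting_hr", "hr", "delta_hr",
    "vm_waist", "vm_left_wrist", "vm_right_wrist", "vm_left_ankle",
    "vm_right_ankle",
)

#: features served by the heart-rate strap (one sensor for all three)
HR_FEATURES = frozenset({"hr", "delta_hr", "resting_hr"})
#: features requiring an accelerometer at the named site
VM_FEATURES = {f"vm_{site}": site for site in SITES}
#: covariates requiring no wearable at all
DEMOGRAPHIC_FEATURES = tuple(
    c for c in FEATURE_COLUMNS
    if c not in HR_FEATURES and c not in VM_FEATURES
)

_SEX_CODE = {"male": 1.0, "female": 0.0}


def vector_magnitude(x, y, z):
    """Euclidean norm of triaxial counts: VM = sqrt(x² + y² + z²).

    Accepts scalars or arrays; axes must be non-negative and finite.  Zero
    iff all axes are zero; monotone in each axis and permutation-invariant.
    """
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    for axis in (x, y, z):
        if not np.all(np.isfinite(axis)):
            raise ValueError("axis counts must be finite")
        if np.any(axis < 0):
            raise ValueError("axis counts must be non-negative")
    vm = np.sqrt(x**2 + y**2 + z**2)
    return float(vm) if vm.ndim == 0 else vm


@dataclass(frozen=True)
class MinuteSummary:
    """Steady-state summary of a single minute of one trace."""

    hr: float
    delta_hr: float
    vm: dict  # site -> counts/min
    ee: float  # kcal/min


def steady_state_minute(trace: ActivityTrace, resting_hr: float) -> MinuteSummary:
    """Summarise the penultimate minute (index duration − 1, 1-based).

    The last full minute can be contaminated by task termination, and early
    minutes by the on-transient, so the minute before last is taken as the
    steady-state representative.  Requires a complete trace of ≥ 2 minutes.
    """
    if not trace.complete:
        raise ValueError(
            f"trace {trace.participant_id}/{trace.activity} is incomplete")
    if trace.duration < 2:
        raise ValueError("steady-state extraction needs at least 2 minutes")
    row = trace.minutes.iloc[trace.duration - 2]  # 1-based minute duration-1
    vm = {
        site: vector_magnitude(row[f"{site}_x"], row[f"{site}_y"],
                               row[f"{site}_z"])
        for site in SITES
    }
    hr = float(row["hr"])
    return MinuteSummary(hr=hr, delta_hr=hr - resting_hr, vm=vm,
                         ee=float(row["ee"]))


def filter_complete(cohort: Cohort) -> Cohort:
    """Retain exactly the participants whose every trace is complete.

    This is the study's Bluetooth-dropout filter (50 enrolled → 40 analysed
    under the default planting); participant order is preserved.
    """
    keep = [
        p.id for p in cohort.profiles
        if all(cohort.traces[(p.id, a)].complete
               for a in ACTIVITIES if (p.id, a) in cohort.traces)
        and all((p.id, a) in cohort.traces for a in ACTIVITIES)
    ]
    return cohort.subset(keep)


@dataclass(eq=False)
class FeatureMatrix:
    """Candidate predictors plus criterion EE for one activity × group scope."""

    activity: str
    group: str  # "elite", "enthusiast" or "both"
    X: pd.DataFrame  # columns == FEATURE_COLUMNS, index = participant id
    y: pd.Series  # criterion EE, kcal/min

    @property
    def n(self) -> int:
        return len(self.X)

    def restrict(self, participant_ids) -> "FeatureMatrix":
        ids = [i for i in self.X.index if i in set(participant_ids)]
        return FeatureMatrix(activity=self.activity, group=self.group,
                             X=self.X.loc[ids], y=self.y.loc[ids])


def assemble_features(cohort: Cohort, activity: str,
                      group: str = "both") -> FeatureMatrix:
    """Build the per-participant feature table for one activity.

    The cohort must already be completeness-filtered; one row per
    participant, columns in the fixed canonical order, the penultimate-minute
    EE as target.  Row order follows cohort order (deterministic).
    """
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}")
    if group not in GROUPS + ("both",):
        raise ValueError(f"unknown group {group!r}")

    rows, targets, index = [], [], []
    for prof in cohort.profiles:
        if group != "both" and prof.group != group:
            continue
        summary = steady_state_minute(cohort.traces[(prof.id, activity)],
                                      prof.resting_hr)
        row = {
            "age": prof.age,
            "sex": _SEX_CODE[prof.sex],
            "height": prof.height,
            "body_mass": prof.body_mass,
            "bmi": prof.bmi,
            "fat_pct": prof.fat_pct,
            "skeletal_muscle": prof.skeletal_muscle,
            "resting_hr": prof.resting_hr,
            "hr": summary.hr,
            "delta_hr": summary.delta_hr,
        }
        for site in SITES:
            row[f"vm_{site}"] = summary.vm[site]
        rows.append(row)
        targets.append(summary.ee)
        index.append(prof.id)

    X = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS),
                     index=pd.Index(index, name="participant_id"))
    y = pd.Series(targets, index=X.index, name="ee")
    if X.size and X.isna().any().any():
        raise ValueError("feature matrix contains missing cells; "
                         "apply filter_complete first")
    return FeatureMatrix(activity=activity, group=group, X=X, y=y)
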