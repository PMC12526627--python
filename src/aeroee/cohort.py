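"""Seeded synthetic cohorts of badminton players for energy-expenditure modelling.

The generator emulates the statistical structure of a two-group training
study: 25 elite players and 25 enthusiasts, each performing four aerobic
tasks (treadmill running, cycling, rope skipping, stair walking) while
wearing five accelerometers (waist, both wrists, both ankles) and a
heart-rate strap, with indirect-calorimetry energy expenditure (EE) as the
criterion.  Group demographics are calibrated to published means/SDs; the
sensor-signal architecture is planted so that elite signal concentrates on
the dominant (right) side with low noise, while enthusiast signal is
dispersed across sites with high per-site variability that cancels when
sites are combined.

Generative model (per participant i, activity a, site s, minute t):

    I_a,i      = base_MET_a * (1 + u_i),          u_i ~ N(0, intensity_sd)
    EE*_a,i,t  = I_a,i * m_t * 3.5 * body_mass_i / 200        [kcal/min]
    hr_a,i,t   = resting_hr_i + slope_i * EE*_a,i,t + N(0, hr_minute_sd)
    S_s,t      = lambda[g,a,s] * I_a,i * m_t * (1 + e_i,s)
    VM_s,t     = count_scale * S_s,t   (allocated to x/y/z axes)
    ee_a,i,t   = EE*_a,i,t * (1 + N(0, ee_obs_sd))

where m_t is a short warm-up ramp (0.85, 0.95, then 1.0), slope_i is the
individual heart-rate response (bpm per kcal/min) with group-specific
coefficient of variation, and e_i,s is the site-noise term: independent
per-site noise for elites, and for enthusiasts a mean-centred allocation
component shared across the five sites (modelling erratic redistribution of
effort between limbs) plus a small independent term.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import derive_seed

__all__ = [
    "GROUPS",
    "SITES",
    "ACTIVITIES",
    "ACTIVITY_DURATIONS",
    "ParticipantProfile",
    "GeneratorConfig",
    "ActivityTrace",
    "Cohort",
    "SchemaError",
    "generate_cohort",
    "apply_missingness",
    "write_cohort",
    "read_cohort",
    "cohorts_equal",
]

GROUPS = ("elite", "enthusiast")
SITES = ("waist", "left_wrist", "right_wrist", "left_ankle", "right_ankle")
ACTIVITIES = ("running", "cycling", "rope_skipping", "stair_walking")

#: protocol durations in minutes (rope skipping is the short 3-minute task)
ACTIVITY_DURATIONS = {
    "running": 5,
    "cycling": 5,
    "rope_skipping": 3,
    "stair_walking": 5,
}

_WARMUP_RAMP = (0.85, 0.95)  # minutes 1..2; steady state afterwards

# fixed per-site axis orientations (unit vectors, positive components) so the
# vector magnitude, not any single axis, is the informative quantity
_AXIS_DIRECTIONS = {
    "waist": (0.30, 0.90, 0.32),
    "left_wrist": (0.60, 0.55, 0.58),
    "right_wrist": (0.60, 0.55, 0.58),
    "left_ankle": (0.45, 0.80, 0.40),
    "right_ankle": (0.45, 0.80, 0.40),
}


@dataclass
class ParticipantProfile:
    """Subject-level covariates: demographics, body composition, resting HR."""

    id: str
    group: str
    sex: str
    age: float
    height: float  # cm
    body_mass: float  # kg
    bmi: float  # kg/m^2, derived from height and mass
    fat_pct: float
    skeletal_muscle: float  # kg
    resting_hr: float  # beats/min
    dominant_side: str = "right"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (self.height > 0 and self.body_mass > 0):
            raise ValueError("height and body_mass must be positive")
        if not (0 <= self.fat_pct < 100):
            raise ValueError("fat_pct must be in [0, 100)")
        if not (35 <= self.resting_hr <= 100):
            raise ValueError("resting_hr must lie in [35, 100] beats/min")
        expected_bmi = self.body_mass / (self.height / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 0.05:
            raise ValueError(
                f"bmi {self.bmi:.3f} inconsistent with mass/height ({expected_bmi:.3f})"
            )


def _default_table1() -> dict:
    # published group means +/- SDs for the demographic / body-composition block
    return {
        "elite": {
            "age": (21.1, 1.8),
            "height": (174.1, 6.3),
            "body_mass": (70.8, 9.6),
            "fat_pct": (17.3, 7.7),
            "skeletal_muscle": (33.2, 5.9),
        },
        "enthusiast": {
            "age": (22.4, 2.2),
            "height": (172.8, 6.6),
            "body_mass": (65.3, 6.8),
            "fat_pct": (16.5, 8.8),
            "skeletal_muscle": (30.9, 6.0),
        },
    }


def _default_loading_matrix() -> dict:
    """Per (group, activity, site) signal loadings lambda.

    Built from a per-activity site profile (which body segments move most in
    each task) modulated per group: elite loading is concentrated on the
    dominant right side; enthusiast loading is evenly dispersed.
    """
    activity_profile = {
        "running": {"waist": 1.0, "left_wrist": 0.7, "right_wrist": 0.7,
                    "left_ankle": 1.2, "right_ankle": 1.2},
        "cycling": {"waist": 0.5, "left_wrist": 0.3, "right_wrist": 0.3,
                    "left_ankle": 1.2, "right_ankle": 1.2},
        "rope_skipping": {"waist": 0.8, "left_wrist": 1.1, "right_wrist": 1.1,
                          "left_ankle": 1.1, "right_ankle": 1.1},
        "stair_walking": {"waist": 0.9, "left_wrist": 0.5, "right_wrist": 0.5,
                          "left_ankle": 1.1, "right_ankle": 1.1},
    }
    group_modulation = {
        "elite": {"waist": 1.0, "left_wrist": 0.7, "right_wrist": 1.4,
                  "left_ankle": 0.8, "right_ankle": 1.2},
        "enthusiast": {site: 1.0 for site in SITES},
    }
    return {
        (g, a, s): activity_profile[a][s] * group_modulation[g][s]
        for g in GROUPS for a in ACTIVITIES for s in SITES
    }


def _default_site_noise() -> dict:
    # independent per-site multiplicative noise SD; elite noise is low on the
    # dominant side and high on the non-dominant side, enthusiasts carry a
    # moderate independent term on top of the shared allocation component
    return {
        "elite": {"waist": 0.12, "left_wrist": 0.20, "right_wrist": 0.04,
                  "left_ankle": 0.20, "right_ankle": 0.08},
        "enthusiast": {site: 0.05 for site in SITES},
    }


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator; defaults define the study conditions."""

    n_per_group: int = 25
    seed: int = 0
    sex_p_male: float = 0.5
    #: anthropometric height-mass correlation; calibrated so the derived
    #: group BMI centres on the published means (independent sampling
    #: biases BMI upward via E[1/height²])
    height_mass_corr: float = 0.55
    table1_calibration: dict = field(default_factory=_default_table1)
    resting_hr_params: dict = field(
        default_factory=lambda: {"elite": (58.0, 6.0), "enthusiast": (68.0, 6.0)}
    )
    activity_mets: dict = field(
        default_factory=lambda: {
            "running": 9.8, "cycling": 8.0, "rope_skipping": 11.0,
            "stair_walking": 7.5,
        }
    )
    intensity_sd: float = 0.10
    loading_matrix: dict = field(default_factory=_default_loading_matrix)
    site_noise_sd: dict = field(default_factory=_default_site_noise)
    allocation_sd: dict = field(
        default_factory=lambda: {"elite": 0.0, "enthusiast": 0.075}
    )
    ee_obs_sd: float = 0.015
    hr_slope: float = 5.0  # bpm per kcal/min
    hr_slope_cv: dict = field(
        default_factory=lambda: {"elite": 0.010, "enthusiast": 0.024}
    )
    hr_minute_sd: float = 0.5  # bpm, minute-to-minute measurement jitter
    count_scale: float = 800.0  # counts/min per unit of site signal
    axis_jitter_sd: float = 0.05
    n_dropout_per_group: int = 5
    dropout_mechanism: str = "stream_loss"

    def __post_init__(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")
        if self.n_dropout_per_group < 0:
            raise ValueError("n_dropout_per_group must be >= 0")
        for group, fields_ in self.table1_calibration.items():
            for name, (mean, sd) in fields_.items():
                if not (np.isfinite(mean) and np.isfinite(sd)):
                    raise ValueError(f"non-finite calibration for {group}/{name}")
                if sd < 0:
                    raise ValueError(f"negative SD for {group}/{name}")
        for sds in (self.intensity_sd, self.ee_obs_sd, self.hr_minute_sd):
            if sds < 0:
                raise ValueError("all noise SDs must be >= 0")
        if any(lam < 0 for lam in self.loading_matrix.values()):
            raise ValueError("loadings must be >= 0")
        for group in GROUPS:
            if any(sd < 0 for sd in self.site_noise_sd[group].values()):
                raise ValueError("site noise SDs must be >= 0")
            if self.allocation_sd[group] < 0:
                raise ValueError("allocation SDs must be >= 0")


@dataclass(eq=False)
class ActivityTrace:
    """Per-minute records for one participant x activity.

    ``minutes`` is a wide DataFrame with one row per minute and columns
    ``minute``, ``hr``, ``ee`` plus ``{site}_x/_y/_z`` triaxial counts for
    each of the five sites.  ``complete`` is False when Bluetooth dropout
    struck any stream of this trace.
    """

    participant_id: str
    activity: str
    minutes: pd.DataFrame
    complete: bool = True

    @property
    def duration(self) -> int:
        return len(self.minutes)


@dataclass(eq=False)
class Cohort:
    """An ordered set of participant profiles plus their activity traces."""

    profiles: list[ParticipantProfile]
    traces: dict  # (participant_id, activity) -> ActivityTrace

    @property
    def participant_ids(self) -> list[str]:
        return [p.id for p in self.profiles]

    def profile(self, participant_id: str) -> ParticipantProfile:
        for p in self.profiles:
            if p.id == participant_id:
                return p
        raise KeyError(participant_id)

    def trace(self, participant_id: str, activity: str) -> ActivityTrace:
        return self.traces[(participant_id, activity)]

    def subset(self, participant_ids: list[str]) -> "Cohort":
        keep = set(participant_ids)
        profiles = [p for p in self.profiles if p.id in keep]
        traces = {k: v for k, v in self.traces.items() if k[0] in keep}
        return Cohort(profiles=profiles, traces=traces)


def _minute_columns() -> list[str]:
    cols = ["minute", "hr", "ee"]
    for site in SITES:
        cols += [f"{site}_x", f"{site}_y", f"{site}_z"]
    return cols


def _sample_profiles(config: GeneratorConfig, rng: np.random.Generator
                     ) -> list[ParticipantProfile]:
    profiles = []
    for group in GROUPS:
        cal = config.table1_calibration[group]
        hr_mean, hr_sd = config.resting_hr_params[group]
        prefix = "E" if group == "elite" else "H"
        rho = config.height_mass_corr
        for i in range(config.n_per_group):
            age = rng.normal(*cal["age"])
            z_h, z_m = rng.normal(size=2)
            height = max(cal["height"][0] + cal["height"][1] * z_h, 120.0)
            mass = max(cal["body_mass"][0] + cal["body_mass"][1]
                       * (rho * z_h + np.sqrt(1 - rho**2) * z_m), 35.0)
            fat = float(np.clip(rng.normal(*cal["fat_pct"]), 1.0, 60.0))
            muscle = max(rng.normal(*cal["skeletal_muscle"]), 10.0)
            rhr = float(np.clip(rng.normal(hr_mean, hr_sd), 35.0, 100.0))
            sex = "male" if rng.random() < config.sex_p_male else "female"
            profiles.append(ParticipantProfile(
                id=f"{prefix}{i + 1:02d}",
                group=group,
                sex=sex,
                age=float(age),
                height=float(height),
                body_mass=float(mass),
                bmi=float(mass / (height / 100.0) ** 2),
                fat_pct=fat,
                skeletal_muscle=float(muscle),
                resting_hr=rhr,
            ))
    return profiles


def _axis_direction(site: str, rng: np.random.Generator, jitter_sd: float
                    ) -> np.ndarray:
    base = np.array(_AXIS_DIRECTIONS[site], dtype=float)
    d = base + rng.normal(0.0, jitter_sd, size=3)
    d = np.clip(d, 0.01, None)
    return d / np.linalg.norm(d)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a seeded cohort: profiles plus all four activity traces each.

    Identical config (including seed) yields a field-by-field identical
    cohort.  Profile marginals converge to ``table1_calibration`` as
    replicate cohorts accumulate.
    """
    rng = np.random.default_rng(config.seed)
    profiles = _sample_profiles(config, rng)

    # participant-level latent factors, drawn in profile order
    u = rng.normal(0.0, config.intensity_sd, size=len(profiles))
    slopes = np.array([
        config.hr_slope * (1.0 + rng.normal(0.0, config.hr_slope_cv[p.group]))
        for p in profiles
    ])

    traces: dict = {}
    for idx, prof in enumerate(profiles):
        for activity in ACTIVITIES:
            duration = ACTIVITY_DURATIONS[activity]
            ramp = np.array([
                _WARMUP_RAMP[t] if t < len(_WARMUP_RAMP) else 1.0
                for t in range(duration)
            ])
            intensity = config.activity_mets[activity] * (1.0 + u[idx])
            true_ee = intensity * ramp * 3.5 * prof.body_mass / 200.0

            hr = (prof.resting_hr + slopes[idx] * true_ee
                  + rng.normal(0.0, config.hr_minute_sd, size=duration))
            hr = np.maximum(hr, prof.resting_hr + 1.0)

            ee = true_ee * (1.0 + rng.normal(0.0, config.ee_obs_sd, size=duration))
            ee = np.maximum(ee, 0.01)

            # site noise: shared mean-centred allocation + independent term
            alloc = rng.normal(0.0, 1.0, size=len(SITES))
            alloc = (alloc - alloc.mean()) * config.allocation_sd[prof.group]
            data = {"minute": np.arange(1, duration + 1), "hr": hr, "ee": ee}
            for j, site in enumerate(SITES):
                e_site = alloc[j] + rng.normal(
                    0.0, config.site_noise_sd[prof.group][site])
                gain = max(1.0 + e_site, 0.02)
                lam = config.loading_matrix[(prof.group, activity, site)]
                vm = config.count_scale * lam * intensity * ramp * gain
                direction = _axis_direction(site, rng, config.axis_jitter_sd)
                for k, axis in enumerate("xyz"):
                    data[f"{site}_{axis}"] = vm * direction[k]
            minutes = pd.DataFrame(data, columns=_minute_columns())
            traces[(prof.id, activity)] = ActivityTrace(
                participant_id=prof.id, activity=activity,
                minutes=minutes, complete=True,
            )
    return Cohort(profiles=profiles, traces=traces)


def apply_missingness(cohort: Cohort, config: GeneratorConfig) -> Cohort:
    """Plant Bluetooth-dropout missingness: per group, a seeded draw without
    replacement marks ``n_dropout_per_group`` participants incomplete by
    erasing one whole stream (HR, EE, or one site's counts) in one activity.

    Returns a new cohort; the input is not modified.
    """
    if config.n_dropout_per_group > config.n_per_group:
        raise ValueError("n_dropout_per_group cannot exceed n_per_group")
    out = copy.deepcopy(cohort)
    rng = np.random.default_rng(derive_seed(config.seed, "dropout"))
    streams = ["hr", "ee"] + list(SITES)
    for group in GROUPS:
        ids = [p.id for p in out.profiles if p.group == group]
        if config.n_dropout_per_group > len(ids):
            raise ValueError("n_dropout_per_group exceeds group size")
        struck = rng.choice(len(ids), size=config.n_dropout_per_group,
                            replace=False)
        for pos in sorted(struck):
            pid = ids[pos]
            activity = ACTIVITIES[rng.integers(len(ACTIVITIES))]
            stream = streams[rng.integers(len(streams))]
            trace = out.traces[(pid, activity)]
            if stream in ("hr", "ee"):
                trace.minutes[stream] = np.nan
            else:
                for axis in "xyz":
                    trace.minutes[f"{stream}_{axis}"] = np.nan
            trace.complete = False
    return out


# ---------------------------------------------------------------------------
# on-disk schema: profiles.csv (wide) + traces.csv (long) + meta.json


class SchemaError(ValueError):
    """A cohort file does not match the documented CSV schema."""


_PROFILE_COLUMNS = ["id", "group", "sex", "age", "height", "body_mass", "bmi",
                    "fat_pct", "skeletal_muscle", "resting_hr", "dominant_side"]
_TRACE_COLUMNS = ["participant_id", "activity", "minute", "hr", "site",
                  "axis_x", "axis_y", "axis_z", "ee", "complete"]


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write ``profiles.csv``, long-format ``traces.csv`` and ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    prof_rows = [{c: getattr(p, c) for c in _PROFILE_COLUMNS}
                 for p in cohort.profiles]
    pd.DataFrame(prof_rows, columns=_PROFILE_COLUMNS).to_csv(
        path / "profiles.csv", index=False)

    trace_rows = []
    for prof in cohort.profiles:
        for activity in ACTIVITIES:
            key = (prof.id, activity)
            if key not in cohort.traces:
                continue
            trace = cohort.traces[key]
            for _, row in trace.minutes.iterrows():
                for site in SITES:
                    trace_rows.append({
                        "participant_id": prof.id,
                        "activity": activity,
                        "minute": int(row["minute"]),
                        "hr": row["hr"],
                        "site": site,
                        "axis_x": row[f"{site}_x"],
                        "axis_y": row[f"{site}_y"],
                        "axis_z": row[f"{site}_z"],
                        "ee": row["ee"],
                        "complete": trace.complete,
                    })
    pd.DataFrame(trace_rows, columns=_TRACE_COLUMNS).to_csv(
        path / "traces.csv", index=False)

    from . import __version__

    meta = {"version": __version__, "n_participants": len(cohort.profiles)}
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (round-trip identity)."""
    path = Path(path)
    prof_df = pd.read_csv(path / "profiles.csv",
                          float_precision="round_trip")
    for col in _PROFILE_COLUMNS:
        if col not in prof_df.columns:
            raise SchemaError(f"profiles.csv is missing column {col!r}")
    profiles = [ParticipantProfile(**{c: row[c] for c in _PROFILE_COLUMNS})
                for _, row in prof_df.iterrows()]

    trace_df = pd.read_csv(path / "traces.csv",
                           float_precision="round_trip")
    for col in _TRACE_COLUMNS:
        if col not in trace_df.columns:
            raise SchemaError(f"traces.csv is missing column {col!r}")

    traces: dict = {}
    if len(trace_df):
        for (pid, activity), part in trace_df.groupby(
                ["participant_id", "activity"], sort=False):
            minutes_idx = sorted(part["minute"].unique())
            data = {"minute": minutes_idx}
            first_site = SITES[0]
            by_site = {s: part[part["site"] == s].set_index("minute")
                       for s in SITES}
            for s in SITES:
                if len(by_site[s]) != len(minutes_idx):
                    raise SchemaError(
                        f"traces.csv: site {s!r} incomplete for participant "
                        f"{pid!r}, activity {activity!r}")
            data["hr"] = [by_site[first_site].loc[m, "hr"] for m in minutes_idx]
            data["ee"] = [by_site[first_site].loc[m, "ee"] for m in minutes_idx]
            for s in SITES:
                for axis in "xyz":
                    data[f"{s}_{axis}"] = [
                        by_site[s].loc[m, f"axis_{axis}"] for m in minutes_idx]
            complete = bool(part["complete"].iloc[0])
            minutes = pd.DataFrame(data, columns=_minute_columns())
            minutes["minute"] = minutes["minute"].astype(np.int64)
            traces[(pid, activity)] = ActivityTrace(
                participant_id=pid, activity=activity,
                minutes=minutes, complete=complete)
    return Cohort(profiles=profiles, traces=traces)


def cohorts_equal(a: Cohort, b: Cohort) -> bool:
    """Field-by-field equality, treating NaNs in the same cell as equal."""
    if [dataclass_to_tuple(p) for p in a.profiles] != \
            [dataclass_to_tuple(p) for p in b.profiles]:
        return False
    if set(a.traces) != set(b.traces):
        return False
    for key, ta in a.traces.items():
        tb = b.traces[key]
        if ta.complete != tb.complete:
            return False
        ma, mb = ta.minutes, tb.minutes
        if list(ma.columns) != list(mb.columns) or len(ma) != len(mb):
            return False
        if not np.array_equal(ma.to_numpy(dtype=float),
                              mb.to_numpy(dtype=float), equal_nan=True):
            return False
    return True


def dataclass_to_tuple(p: ParticipantProfile) -> tuple:
    return (p.id, p.group, p.sex, p.age, p.height, p.body_mass, p.bmi,
            p.fat_pct, p.skeletal_muscle, p.resting_hr, p.dominant_side)
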