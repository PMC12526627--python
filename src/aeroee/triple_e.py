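"""The Triple-E scoring frame: Effectiveness, Efficiency, Extension, and the
triangle-area composite.

A deployment configuration — a model family, a sensor budget X out of a
maximum Y, and a sample size N against a reference N_ref — is scored on
three axes:

    Effectiveness = R² · (1 − MAPE)                    (accuracy; MAPE a fraction)
    Efficiency    = 1 − X/Y − α                        (parsimony; α the family penalty)
    Extension     = (N/N_ref · R²) / (1 + (N/N_ref − 1) · R²)
                                                       (sample-size-adjusted generality)

and combined into a single composite: the scores are laid out as radial
coordinates on three radar axes 120° apart (clamped below at zero — a
polygon radius cannot be negative) and the area of the resulting triangle
is the composite, (√3/4)·(ab + bc + ca).  Larger area = more balanced,
stronger overall performance.  Negative Efficiency (full deployment of a
heavily penalised model) and negative R² propagate unclamped into the
stored scores; clamping happens only inside the area geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .features import DEMOGRAPHIC_FEATURES, HR_FEATURES, VM_FEATURES
from .search import MODEL_ALPHA

__all__ = [
    "SensorConfiguration",
    "TripleEScore",
    "effectiveness",
    "efficiency",
    "extension",
    "alpha_for",
    "composite_area",
    "sensors_required",
    "score_configuration",
]


@dataclass(frozen=True)
class SensorConfiguration:
    """A (sensor count, sample size, model) deployment configuration.

    The heart-rate strap counts as one sensor; each accelerometer site
    counts as one.  ``y_max`` defaults to 6 (five sites plus the strap).
    """

    x_sensors: int
    n: int
    model: str
    y_max: int = 6
    n_ref: int = 40

    def __post_init__(self) -> None:
        if not (1 <= self.x_sensors <= self.y_max):
            raise ValueError("need 1 <= X <= Y")
        if self.n < 1 or self.n_ref < 1:
            raise ValueError("N and N_ref must be >= 1")
        if self.model not in MODEL_ALPHA:
            raise ValueError(f"unknown model family {self.model!r}")


@dataclass(frozen=True)
class TripleEScore:
    effectiveness: float
    efficiency: float
    extension: float
    area: float
    geometry: str = "radar_120"


def effectiveness(r2: float, mape: float) -> float:
    """Effectiveness = R² × (1 − MAPE), with MAPE as a fraction.

    A MAPE that looks like a percent value (> 1.5) triggers a unit warning
    but is computed as given.
    """
    if mape < 0:
        raise ValueError("mape must be >= 0")
    if r2 > 1:
        raise ValueError("r2 cannot exceed 1")
    if mape > 1.5:
        warnings.warn(
            f"mape={mape} looks like a percent value; Effectiveness expects "
            "a fraction (1.07% -> 0.0107)", stacklevel=2)
    return r2 * (1.0 - mape)


def efficiency(x_sensors: int, y_max: int, alpha: float) -> float:
    """Efficiency = 1 − X/Y − α; may be negative (e.g. X=Y with α=0.2)."""
    if x_sensors > y_max:
        raise ValueError("sensor count X cannot exceed maximum Y")
    if x_sensors < 1 or y_max < 1:
        raise ValueError("need 1 <= X <= Y")
    return 1.0 - x_sensors / y_max - alpha


def extension(n: int, n_ref: int, r2: float) -> float:
    """Extension = (k·R²) / (1 + (k−1)·R²) with k = N/N_ref.

    Identity at k=1; fixed point 1 at R²=1; monotone non-decreasing in N for
    R² in (0, 1].
    """
    if n < 1 or n_ref < 1:
        raise ValueError("N and N_ref must be >= 1")
    k = n / n_ref
    denom = 1.0 + (k - 1.0) * r2
    if abs(denom) < 1e-12:
        raise ValueError(
            f"extension undefined: denominator ~0 (N={n}, N_ref={n_ref}, "
            f"r2={r2})")
    return k * r2 / denom


def alpha_for(model: str) -> float:
    """The fixed complexity penalty α of a model family."""
    try:
        return MODEL_ALPHA[model]
    except KeyError:
        raise ValueError(f"unknown model family {model!r}") from None


def composite_area(eff: float, effc: float, ext: float,
                   geometry: str = "radar_120") -> float:
    """Triangle area of the three scores on a 120°-spaced radar layout.

    Each score is a radial coordinate clamped below at 0; the polygon area
    is (√3/4)·(ab + bc + ca).  Symmetric in the three scores; zero whenever
    two of them are ≤ 0 (degenerate polygon).
    """
    scores = (eff, effc, ext)
    if not all(math.isfinite(s) for s in scores):
        raise ValueError("scores must be finite")
    if geometry != "radar_120":
        raise ValueError(f"unknown composite geometry {geometry!r}")
    # sort so the pairwise-product sum associates identically under any
    # permutation of the inputs (exact symmetry, not just up to rounding)
    a, b, c = sorted(max(s, 0.0) for s in scores)
    return (math.sqrt(3.0) / 4.0) * (a * b + b * c + c * a)


def sensors_required(feature_set) -> int:
    """Number of distinct wearables a feature set needs.

    One heart-rate strap serves all HR-derived features; each accelerometer
    site is one sensor; demographic/body-composition covariates need none.
    """
    needs_strap = False
    sites = set()
    for name in feature_set:
        if name in HR_FEATURES:
            needs_strap = True
        elif name in VM_FEATURES:
            sites.add(VM_FEATURES[name])
        elif name in DEMOGRAPHIC_FEATURES:
            continue
        else:
            raise ValueError(f"unknown feature {name!r}")
    return int(needs_strap) + len(sites)


def score_configuration(config: SensorConfiguration, r2: float, mape: float
                        ) -> TripleEScore:
    """Score one configuration from its cross-validated R² and MAPE."""
    eff = effectiveness(r2, mape)
    effc = efficiency(config.x_sensors, config.y_max, alpha_for(config.model))
    ext = extension(config.n, config.n_ref, r2)
    return TripleEScore(
        effectiveness=eff, efficiency=effc, extension=ext,
        area=composite_area(eff, effc, ext),
    )
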