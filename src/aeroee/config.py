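"""Run configuration, seed management and structured logging.

All pipeline randomness flows from a single master seed through
:func:`derive_seed`; no stage touches global RNG state.  Run configuration is
a plain dataclass tree loadable from YAML or JSON, with unknown keys rejected
so typos surface as errors rather than silently ignored settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, IO

import yaml

__all__ = [
    "SearchSettings",
    "TripleESettings",
    "ExperimentSettings",
    "RunConfig",
    "load_config",
    "derive_seed",
    "JsonlLogger",
]

#: the seven regression families of the model zoo, in canonical order
KNOWN_FAMILIES = (
    "linear_regression",
    "bayesian_ridge",
    "random_forest",
    "gradient_boosting",
    "svr",
    "xgboost_style_boosting",
    "decision_tree",
)


def derive_seed(master_seed: int, stage_label: str, replicate_index: int = 0) -> int:
    """Derive a stage seed from the master seed, deterministically.

    Uses a keyed BLAKE2b digest of ``"master|label|index"`` reduced to the
    31-bit non-negative range accepted by every RNG in the stack.  Stable
    across platforms and Python versions (no reliance on ``hash()``).
    """
    payload = f"{master_seed}|{stage_label}|{replicate_index}".encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass(frozen=True)
class SearchSettings:
    """Settings for the exhaustive feature-subset model search."""

    families: tuple[str, ...] = KNOWN_FAMILIES
    max_size: int | None = 3
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if not self.families:
            raise ValueError("at least one model family is required")
        for name in self.families:
            if name not in KNOWN_FAMILIES:
                raise ValueError(
                    f"unknown model family {name!r}; known: {KNOWN_FAMILIES}"
                )
        if self.max_size is not None and self.max_size < 1:
            raise ValueError("max_size must be >= 1 or None")


@dataclass(frozen=True)
class TripleESettings:
    """Constants of the Triple-E scoring frame.

    ``y_max`` is the maximum deployable sensor count (five accelerometer
    sites plus one heart-rate strap); ``n_ref`` the reference sample size in
    the Extension term; ``geometry`` names the composite-area construction.
    """

    y_max: int = 6
    n_ref: int = 40
    geometry: str = "radar_120"

    def __post_init__(self) -> None:
        if self.y_max < 1 or self.n_ref < 1:
            raise ValueError("y_max and n_ref must be >= 1")
        if self.geometry != "radar_120":
            raise ValueError(f"unknown composite geometry {self.geometry!r}")


@dataclass(frozen=True)
class ExperimentSettings:
    replicates: int = 20
    sizes: tuple[int, ...] = (20, 30, 40)
    budgets: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(s < 1 for s in self.sizes) or list(self.sizes) != sorted(self.sizes):
            raise ValueError("sizes must be positive and strictly increasing")
        if any(b < 1 for b in self.budgets):
            raise ValueError("sensor budgets must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for a full pipeline run."""

    generator: "Any" = None  # GeneratorConfig; filled in __post_init__
    search: SearchSettings = field(default_factory=SearchSettings)
    triple_e: TripleESettings = field(default_factory=TripleESettings)
    experiments: ExperimentSettings = field(default_factory=ExperimentSettings)
    master_seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.generator is None:
            from .cohort import GeneratorConfig

            object.__setattr__(self, "generator", GeneratorConfig())


def _build_section(cls, data: dict, path: str):
    """Instantiate a settings dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) at {path}: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    An empty file yields the all-defaults configuration.  Unknown keys raise
    ``ValueError`` naming the offending key path.
    """
    from .cohort import GeneratorConfig

    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    sections = {
        "generator": GeneratorConfig,
        "search": SearchSettings,
        "triple_e": TripleESettings,
        "experiments": ExperimentSettings,
    }
    known_top = set(sections) | {"master_seed", "out_dir"}
    unknown = set(data) - known_top
    if unknown:
        raise ValueError(f"unknown key(s) at <root>: {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    for name, cls in sections.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise ValueError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    if "master_seed" in data:
        kwargs["master_seed"] = int(data["master_seed"])
    if "out_dir" in data:
        kwargs["out_dir"] = str(data["out_dir"])
    return RunConfig(**kwargs)


class JsonlLogger:
    """Append-only JSON-lines event log (stage, seed, row counts, ...)."""

    def __init__(self, sink: str | Path | IO[str] | None = None):
        self._own = False
        if sink is None:
            self._fh = None
        elif hasattr(sink, "write"):
            self._fh = sink
        else:
            self._fh = open(sink, "a")
            self._own = True
        self.events: list[dict] = []

    def log(self, stage: str, **fields: Any) -> None:
        event = {"stage": stage, **fields}
        self.events.append(event)
        if self._fh is not None:
            self._fh.write(json.dumps(event, default=str) + "\n")
            self._fh.flush()

    def close(self) -> None:
        if self._own and self._fh is not None:
            self._fh.close()
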