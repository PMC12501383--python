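"""Detection configuration: the per-iteration hyperparameter schedule.

The iterative surface detector is driven by an outer-loop schedule: each
outer iteration chooses a fit method (RANSAC plane, fixed-degree polyfit,
or dynamic degree selection), a threshold quantile ``alpha`` (or the marker
``"adaptive"``), a threshold multiplier ``tau``, outlier-band multipliers,
an absolute cap ``h_abs`` and the feasible-range half-widths
``theta_top`` / ``theta_bot`` used to narrow the search range for the next
iteration.

The default schedule below is a set of non-canonical defaults chosen to
realize the documented qualitative behavior (robust linear fits first,
dynamic degree selection later, adaptive quantile in the final iteration,
monotonically narrowing range); every value can be overridden from a YAML
config file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import List, Optional, Sequence, Set, Union

import yaml

__all__ = [
    "FitMethod",
    "IterationParams",
    "DetectionConfig",
    "default_schedule",
    "load_config",
]

UNBOUNDED = "unbounded"
ADAPTIVE = "adaptive"


class FitMethod(str, Enum):
    RANSAC_LINEAR = "RANSAC_linear"
    POLYFIT_FIXED = "Polyfit_fixed"
    POLYFIT_DYNAMIC = "Polyfit_dynamic"


@dataclass
class IterationParams:
    """Hyperparameters of one outer iteration of the surface detector."""

    fit_method: FitMethod
    alpha: Union[float, str]  # quantile in (0,1) or "adaptive"
    tau: float
    sigma_top: float
    sigma_bot: float
    gamma_top: float
    gamma_bot: float
    h_abs: float
    theta_top: Union[float, str] = UNBOUNDED  # voxels or "unbounded"
    theta_bot: Union[float, str] = UNBOUNDED

    def validate(self) -> None:
        self.fit_method = FitMethod(self.fit_method)
        if self.alpha != ADAPTIVE:
            a = float(self.alpha)
            if not (0.0 < a < 1.0):
                raise ValueError(f"alpha must lie in (0, 1), got {a}")
            self.alpha = a
        for name in ("tau", "sigma_top", "sigma_bot", "gamma_top", "gamma_bot", "h_abs"):
            v = float(getattr(self, name))
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be a positive finite real, got {v}")
            setattr(self, name, v)
        for name in ("theta_top", "theta_bot"):
            v = getattr(self, name)
            if v != UNBOUNDED:
                v = float(v)
                if not (v > 0 and math.isfinite(v)):
                    raise ValueError(f"{name} must be positive or 'unbounded', got {v}")
                setattr(self, name, v)


def default_schedule() -> List[IterationParams]:
    """Four-iteration default schedule (non-canonical defaults)."""
    return [
        IterationParams(FitMethod.RANSAC_LINEAR, 0.99, 1.0, 4, 4, 4, 4, 200.0, 150.0, 150.0),
        IterationParams(FitMethod.POLYFIT_FIXED, 0.98, 0.9, 3, 3, 3, 3, 120.0, 80.0, 100.0),
        IterationParams(FitMethod.POLYFIT_DYNAMIC, 0.97, 0.8, 2.5, 2.5, 2.5, 2.5, 80.0, 40.0, 60.0),
        IterationParams(FitMethod.POLYFIT_DYNAMIC, ADAPTIVE, 0.7, 2, 2, 2, 2, 60.0, 40.0, 60.0),
    ]


@dataclass
class DetectionConfig:
    """Full configuration of surface detection and correction.

    ``defaulted_keys`` records which top-level values were not supplied by
    the user and therefore carry package defaults (written to run manifests
    and the detection report so non-canonical defaults are always visible).
    """

    sensitivity: float = 1.0
    n_outer_iterations: int = 4
    iterations: List[IterationParams] = field(default_factory=default_schedule)
    alpha_min: float = 0.90
    alpha_max: float = 0.999
    max_inner_iterations: int = 5
    train_fraction: float = 0.95
    max_degree: int = 4
    ransac_sample_size: int = 10
    ransac_max_distance: float = 30.0
    ransac_trials: int = 200
    zero_level: int = 100
    random_seed: int = 0
    defaulted_keys: Set[str] = field(default_factory=set)

    def validate(self) -> None:
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be positive")
        if not (0.0 < self.alpha_min < self.alpha_max < 1.0):
            raise ValueError("need 0 < alpha_min < alpha_max < 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_outer_iterations < 1:
            raise ValueError("n_outer_iterations must be >= 1")
        if len(self.iterations) < self.n_outer_iterations:
            raise ValueError(
                f"schedule has {len(self.iterations)} iterations, "
                f"config requests {self.n_outer_iterations}"
            )
        if self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        if self.zero_level < 1:
            raise ValueError("zero_level must be a positive depth index")
        for it in self.iterations:
            it.validate()


_TOP_LEVEL_KEYS = {
    "sensitivity",
    "n_outer_iterations",
    "alpha_min",
    "alpha_max",
    "max_inner_iterations",
    "train_fraction",
    "max_degree",
    "ransac_sample_size",
    "ransac_max_distance",
    "ransac_trials",
    "zero_level",
    "random_seed",
}

_ITER_KEYS = {
    "fit_method",
    "alpha",
    "tau",
    "sigma_top",
    "sigma_bot",
    "gamma_top",
    "gamma_bot",
    "h_abs",
    "theta_top",
    "theta_bot",
}


def load_config(path: Optional[Union[str, Path]] = None) -> DetectionConfig:
    """Load a :class:`DetectionConfig` from a YAML file (or defaults).

    The file is a flat mapping of top-level keys plus an optional
    ``iterations`` list of per-iteration mappings; iteration entries only
    need the keys they override (the remainder comes from the default
    schedule, positionally).
    """
    cfg = DetectionConfig()
    cfg.defaulted_keys = set(_TOP_LEVEL_KEYS) | {"iterations"}
    if path is None:
        cfg.validate()
        return cfg

    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")

    unknown = set(raw) - _TOP_LEVEL_KEYS - {"iterations"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    for key in _TOP_LEVEL_KEYS:
        if key in raw:
            setattr(cfg, key, type(getattr(cfg, key))(raw[key]))
            cfg.defaulted_keys.discard(key)

    if "iterations" in raw:
        entries = raw["iterations"]
        if not isinstance(entries, list):
            raise ValueError("'iterations' must be a list of mappings")
        schedule = default_schedule()
        while len(schedule) < len(entries):
            schedule.append(replace(schedule[-1]))
        for i, entry in enumerate(entries):
            if not isinstance(entry, dict):
                raise ValueError(f"iteration {i + 1} must be a mapping")
            bad = set(entry) - _ITER_KEYS
            if bad:
                raise ValueError(f"iteration {i + 1}: unknown keys {sorted(bad)}")
            schedule[i] = replace(schedule[i], **entry)
        cfg.iterations = schedule
        cfg.defaulted_keys.discard("iterations")
    else:
        cfg.defaulted_keys.add("iterations")

    cfg.validate()
    return cfg
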