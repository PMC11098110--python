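"""Structured run configuration: YAML round-trip, validation, hashing.

A :class:`RunConfig` bundles the landscape recipe, species and environment
parameters, and experiment settings.  Defaults follow the standard study
conditions (b=0.2, mu0=ln(1.1), sigma_r2=0.5, extinction cap 5e5).  Every
result file embeds ``config_hash`` so any output can be regenerated from
its config and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .dynamics import EnvParams, SpeciesParams
from .landscape import (
    Landscape,
    make_fragmented,
    make_homogeneous,
    make_regular_grid,
    read_mask,
)

__all__ = [
    "LandscapeConfig",
    "SimConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]

LANDSCAPE_TYPES = ("homogeneous", "fragmented", "grid", "mask")


@dataclass(frozen=True)
class LandscapeConfig:
    type: str = "homogeneous"
    size: int = 60
    alpha_e: float = 3.0
    threshold: float = 1.1
    direction: str = ">"
    patch_side: int = 1
    spacing: int = 3
    seed: int = 0
    mask_path: str | None = None

    def __post_init__(self) -> None:
        if self.type not in LANDSCAPE_TYPES:
            raise ValueError(f"landscape type must be one of {LANDSCAPE_TYPES}")
        if self.type == "mask" and not self.mask_path:
            raise ValueError("landscape type 'mask' requires mask_path")

    def build(self) -> Landscape:
        if self.type == "homogeneous":
            return make_homogeneous(self.size)
        if self.type == "fragmented":
            rng = np.random.default_rng(self.seed)
            return make_fragmented(
                self.size, self.alpha_e, self.threshold, rng, direction=self.direction
            )
        if self.type == "grid":
            return make_regular_grid(self.size, self.patch_side, self.spacing)
        return read_mask(self.mask_path)


@dataclass(frozen=True)
class SimConfig:
    generations: int = 250
    reps: int = 5
    t_max: int = 500_000
    seed: int = 0
    init_density: float = 1000 / 3600
    init_count: int = 5000
    m: int = 2
    distance_bins: tuple[float, ...] = (2.0, 20.0)

    def __post_init__(self) -> None:
        if self.generations < 1 or self.reps < 1 or self.t_max < 1:
            raise ValueError("generations, reps and t_max must be >= 1")
        if self.init_density < 0 or self.init_count < 0:
            raise ValueError("initial density/count must be >= 0")
        object.__setattr__(self, "distance_bins", tuple(self.distance_bins))


@dataclass(frozen=True)
class RunConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    species: SpeciesParams = field(default_factory=SpeciesParams)
    env: EnvParams = field(default_factory=EnvParams)
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["sim"]["distance_bins"] = list(out["sim"]["distance_bins"])
        return out


_SECTIONS = {
    "landscape": LandscapeConfig,
    "species": SpeciesParams,
    "env": EnvParams,
    "sim": SimConfig,
}


def _coerce_inf(value):
    if isinstance(value, str) and value.lower() in ("inf", "infinity", ".inf"):
        return math.inf
    return value


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in section '{section}': {sorted(unknown)}")
    return cls(**{k: _coerce_inf(v) for k, v in data.items()})


def config_from_dict(data: dict | None) -> RunConfig:
    data = data or {}
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, data.get(name) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Parse a YAML config; an empty file yields the all-defaults config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha1(canonical.encode()).hexdigest()[:12]
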