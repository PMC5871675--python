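"""Run configuration: YAML/JSON blocks for organ, stain, design and seeds."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .disector import POLICIES
from .errors import InvalidConfigError
from .synthetic import StainModel

__all__ = ["OrganConfig", "DesignConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class OrganConfig:
    height_um: float = 3000.0
    cross_section_w_um: float = 3200.0
    cross_section_d_um: float = 3200.0
    n_cells: int = 50
    nucleus_diameter_um: float = 8.0
    parent_mean: float = 8.0
    offspring_sigma_um: float = 150.0
    endplate_fraction: float = 0.15
    endplate_factor: float = 4.0

    def __post_init__(self) -> None:
        if min(self.height_um, self.cross_section_w_um,
               self.cross_section_d_um) <= 0:
            raise InvalidConfigError("organ dimensions must be positive")
        if self.n_cells < 0:
            raise InvalidConfigError("n_cells must be >= 0")


@dataclass(frozen=True)
class DesignConfig:
    """Sampling design.  Defaults mirror the mouse pilot: 6 um sections
    collected as pairs every 36 um (sf = 1/6), a 200 x 200 um frame, and
    3 independent samplings of 60 tiles."""

    t_um: float = 6.0
    ns: int = 83
    frame_um: float = 200.0
    n_tiles_per_rep: int = 60
    repetitions: int = 3
    tile_fraction: float = 1.0
    units_per_animal: float = 1.0
    policy: str = "exclude_rescale"

    def __post_init__(self) -> None:
        if self.t_um <= 0 or self.frame_um <= 0 or self.ns <= 0:
            raise InvalidConfigError("t_um, frame_um and ns must be positive")
        if self.repetitions < 2:
            raise InvalidConfigError("repetitions must be >= 2 (3 recommended)")
        if not (0.0 < self.tile_fraction <= 1.0):
            raise InvalidConfigError("tile_fraction must be in (0, 1]")
        if self.policy not in POLICIES:
            raise InvalidConfigError(f"unknown policy {self.policy!r}")


@dataclass(frozen=True)
class RunConfig:
    organ: OrganConfig = field(default_factory=OrganConfig)
    stain: StainModel = field(default_factory=StainModel)
    design: DesignConfig = field(default_factory=DesignConfig)
    seed: int = 0


def _build(cls, block: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise InvalidConfigError(f"unknown {name} keys: {sorted(unknown)}")
    try:
        return cls(**block)
    except TypeError as exc:
        raise InvalidConfigError(f"bad {name} block: {exc}") from exc


def load_config(path: str | Path | None = None, text: str | None = None
                ) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file or literal text."""
    if text is None:
        if path is None:
            return RunConfig()
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError("config must be a mapping")
    unknown = set(raw) - {"organ", "stain", "design", "seed"}
    if unknown:
        raise InvalidConfigError(f"unknown config sections: {sorted(unknown)}")
    return RunConfig(
        organ=_build(OrganConfig, raw.get("organ", {}) or {}, "organ"),
        stain=_build(StainModel, raw.get("stain", {}) or {}, "stain"),
        design=_build(DesignConfig, raw.get("design", {}) or {}, "design"),
        seed=int(raw.get("seed", 0)),
    )
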