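"""Run configuration files and run manifests.

Configuration is YAML with optional sections ``model``, ``run``,
``langevin``, ``ewald`` and ``geometry``; every value is in reduced units
(σ, m, τ_u, e).  An empty file yields the full default parameter set.
Unknown sections or keys are rejected with the offending name.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import yaml

from .electrostatics import EwaldParams
from .geometry import DEFAULT_BOX, DEFAULT_LAYERS, DEFAULT_PORE_LENGTH, DEFAULT_PORE_RADIUS, Geometry, build_wall
from .integrator import LangevinParams
from .model import ModelParams
from .protocol import RunConfig

__all__ = ["GeometrySpec", "FullConfig", "read_config", "write_config", "RunManifest"]


@dataclass(frozen=True)
class GeometrySpec:
    box: tuple = DEFAULT_BOX
    pore_radius: float = DEFAULT_PORE_RADIUS
    pore_length: float = DEFAULT_PORE_LENGTH
    layers: int = DEFAULT_LAYERS

    def build(self) -> Geometry:
        return build_wall(self.box, self.pore_radius, self.pore_length, self.layers)


@dataclass
class FullConfig:
    model: ModelParams = field(default_factory=ModelParams)
    run: RunConfig = field(default_factory=RunConfig)
    langevin: LangevinParams | None = None  # None: dt from the field-strength schedule
    ewald: EwaldParams = field(default_factory=EwaldParams)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)

    def to_dict(self) -> dict:
        d = {
            "model": dataclasses.asdict(self.model),
            "run": dataclasses.asdict(self.run),
            "ewald": dataclasses.asdict(self.ewald),
            "geometry": dataclasses.asdict(self.geometry),
        }
        d["geometry"]["box"] = list(self.geometry.box)
        if self.langevin is not None:
            d["langevin"] = dataclasses.asdict(self.langevin)
        return d


_SECTIONS = {
    "model": ModelParams,
    "run": RunConfig,
    "langevin": LangevinParams,
    "ewald": EwaldParams,
    "geometry": GeometrySpec,
}


def read_config(path) -> FullConfig:
    """Parse a YAML configuration; defaults fill everything not given."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"configuration file not found: {path}")
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name)
        if section is None:
            continue
        bad = set(section) - {f.name for f in dataclasses.fields(cls)}
        if bad:
            raise ValueError(f"unknown keys in section {name!r}: {sorted(bad)}")
        if name == "geometry" and "box" in section:
            section = dict(section, box=tuple(section["box"]))
        if name == "ewald" and "k_max" in section and section["k_max"] is not None:
            section = dict(section, k_max=tuple(section["k_max"]))
        try:
            kwargs[name] = cls(**section)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid value in section {name!r}: {exc}") from exc
    return FullConfig(**kwargs)


def write_config(cfg: FullConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=False)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit on one platform."""

    config: dict
    seed: int
    dt: float
    completed: bool | None = None
    tau: float | None = None
    code_version: str = ""

    def write(self, path) -> None:
        """Atomic JSON write (temp file + rename)."""
        from . import __version__

        if not self.code_version:
            self.code_version = __version__
        tmp = os.fspath(path) + ".tmp"
        with open(tmp, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)
        os.replace(tmp, os.fspath(path))

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as f:
            return cls(**json.load(f))
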