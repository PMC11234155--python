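"""Serializable run configuration.

A :class:`RunConfig` bundles everything a full pipeline run needs —
geometry, fluid constants, region windows, per-regime WSS targets,
classification thresholds, per-regime monolayer specs and seeds — and
round-trips losslessly through YAML, so a run is reproducible from its
emitted config file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import (ChannelGeometry, FlowParams, GeometryError,
                       RegionWindows, REGIMES, default_windows)
from .metrics import RegimeThresholds
from .synthimage import MonolayerSpec, regime_preset
from .synthwss import RegimeSpec, default_regime_specs


class ConfigError(ValueError):
    """Raised for malformed or inconsistent run configuration."""


@dataclass
class MeshConfig:
    nodes_per_mm: float = 16.0
    n_circ: int = 8


@dataclass
class FieldConfig:
    n_steps: int = 200
    period: float = 1.0
    transition_halfwidth: float = 0.2


@dataclass
class RunConfig:
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    flow: FlowParams = field(default_factory=FlowParams)
    windows: RegionWindows | None = None
    regimes: dict[str, RegimeSpec] | None = None
    thresholds: RegimeThresholds = field(default_factory=RegimeThresholds)
    monolayers: dict[str, MonolayerSpec] | None = None
    mesh: MeshConfig = field(default_factory=MeshConfig)
    field_cfg: FieldConfig = field(default_factory=FieldConfig)
    seed: int = 0
    outdir: str = "bypassflow_out"

    def __post_init__(self) -> None:
        if self.windows is None:
            self.windows = default_windows(self.geometry)
        if self.regimes is None:
            self.regimes = default_regime_specs(self.seed)
        if self.monolayers is None:
            self.monolayers = {
                r: regime_preset(r, seed=self.seed + 100 + i)
                for i, r in enumerate(REGIMES)}

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "flow": dataclasses.asdict(self.flow),
            "windows": {k: list(v) for k, v in self.windows.as_dict().items()},
            "regimes": {k: dataclasses.asdict(v)
                        for k, v in self.regimes.items()},
            "thresholds": dataclasses.asdict(self.thresholds),
            "monolayers": {k: dataclasses.asdict(v)
                           for k, v in self.monolayers.items()},
            "mesh": dataclasses.asdict(self.mesh),
            "field": dataclasses.asdict(self.field_cfg),
            "seed": self.seed,
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            kwargs = {}
            if "geometry" in data:
                kwargs["geometry"] = ChannelGeometry(**data["geometry"])
            if "flow" in data:
                kwargs["flow"] = FlowParams(**data["flow"])
            if "windows" in data:
                kwargs["windows"] = RegionWindows(
                    **{k: tuple(v) for k, v in data["windows"].items()})
            if "regimes" in data:
                kwargs["regimes"] = {
                    k: RegimeSpec(**v) for k, v in data["regimes"].items()}
            if "thresholds" in data:
                kwargs["thresholds"] = RegimeThresholds(**data["thresholds"])
            if "monolayers" in data:
                kwargs["monolayers"] = {
                    k: MonolayerSpec(**{
                        **v,
                        "image_size": tuple(v["image_size"])
                        if v.get("image_size") else None})
                    for k, v in data["monolayers"].items()}
            if "mesh" in data:
                kwargs["mesh"] = MeshConfig(**data["mesh"])
            if "field" in data:
                kwargs["field_cfg"] = FieldConfig(**data["field"])
            for key in ("seed", "outdir"):
                if key in data:
                    kwargs[key] = data[key]
            return cls(**kwargs)
        except (TypeError, ValueError, GeometryError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(data)
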