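"""Run configuration: YAML files with nested sections mirroring the model
parameter tables, strict key validation, and round-trippable defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .homeostasis import HomeoParams
from .lesion import LesionSchedule
from .threelayer import EtaPolicy, ThreeLayerParams

__all__ = ["RunSettings", "RunConfig", "load_config", "save_config"]

_MODELS = ("three_layer", "homeostasis")


@dataclass(frozen=True)
class RunSettings:
    """Execution settings shared by both models."""

    master_seed: int = 0
    n_seeds: int = 1
    recovery_steps: int | None = None
    total_morph_steps: int | None = None
    scale: str = "full"  # "full" or "scaled" (N=100, n=20 three-layer preset)
    out_dir: str = "runs"

    def validate(self) -> None:
        if self.n_seeds < 1:
            raise ConfigurationError(f"n_seeds must be >= 1, got {self.n_seeds}")
        if self.scale not in ("full", "scaled"):
            raise ConfigurationError(
                f"scale must be 'full' or 'scaled', got {self.scale!r}"
            )


@dataclass(frozen=True)
class RunConfig:
    model: str = "three_layer"
    three_layer: ThreeLayerParams = field(default_factory=ThreeLayerParams)
    homeostasis: HomeoParams = field(default_factory=HomeoParams)
    eta: EtaPolicy = field(default_factory=EtaPolicy)
    lesion: LesionSchedule = field(default_factory=LesionSchedule)
    run: RunSettings = field(default_factory=RunSettings)

    def validate(self) -> None:
        if self.model not in _MODELS:
            raise ConfigurationError(
                f"model must be one of {_MODELS}, got {self.model!r}"
            )
        self.three_layer.validate()
        self.homeostasis.validate()
        self.eta.validate()
        self.run.validate()
        n_nodes = (
            self.three_layer.N if self.model == "three_layer"
            else self.homeostasis.n_nodes
        )
        self.lesion.validate(n_nodes)

    def effective_three_layer(self) -> ThreeLayerParams:
        """Three-layer parameters after applying the scale preset."""
        if self.run.scale == "scaled":
            return self.three_layer.scaled()
        return self.three_layer


_SECTIONS = {
    "three_layer": ThreeLayerParams,
    "homeostasis": HomeoParams,
    "eta": EtaPolicy,
    "lesion": LesionSchedule,
    "run": RunSettings,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in config section '{name}'; "
            f"known keys: {sorted(known)}"
        )
    return cls(**data)


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - (set(_SECTIONS) | {"model"})
    if unknown:
        raise ConfigurationError(
            f"unknown top-level config key(s): {sorted(unknown)}"
        )
    kwargs = {"model": raw.get("model", "three_layer")}
    for name, cls in _SECTIONS.items():
        section = raw.get(name) or {}
        if not isinstance(section, dict):
            raise ConfigurationError(f"config section '{name}' must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    out = {"model": cfg.model}
    for name in _SECTIONS:
        out[name] = dataclasses.asdict(getattr(cfg, name))
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unspecified keys take the model
    defaults, unknown keys are rejected with the offending key named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    """Write a config such that load_config(path) == cfg."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
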