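"""Run configuration: nested YAML sections mapped onto the per-stage
config dataclasses, with unknown keys rejected by full key path."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .model import ModelConfig
from .synthetic import SyntheticConfig
from .training import TrainConfig

__all__ = ["FbnConfig", "EvalConfig", "RunConfig", "load_config",
           "config_from_mapping"]


@dataclasses.dataclass(frozen=True)
class FbnConfig:
    sparsity: float = 0.9
    per_subject: bool = False

    def __post_init__(self):
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class EvalConfig:
    train_ratio: float = 0.8
    stratified: bool = True
    split_seed: int = 0


_TUPLE_FIELDS = {"channels", "planted_nodes"}


def _build(cls, mapping: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    for key in mapping:
        if key not in names:
            raise ValueError(f"unknown configuration key: {path}.{key}")
    kwargs = {k: tuple(v) if k in _TUPLE_FIELDS and v is not None else v
              for k, v in mapping.items()}
    return cls(**kwargs)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    synthetic: SyntheticConfig = dataclasses.field(
        default_factory=SyntheticConfig)
    fbn: FbnConfig = dataclasses.field(default_factory=FbnConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    eval: EvalConfig = dataclasses.field(default_factory=EvalConfig)
    out_dir: str = "."
    log_level: str = "INFO"


_SECTIONS = {"synthetic": SyntheticConfig, "fbn": FbnConfig,
             "model": ModelConfig, "train": TrainConfig, "eval": EvalConfig}


def config_from_mapping(mapping: dict | None) -> RunConfig:
    mapping = dict(mapping or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = mapping.pop(name, None)
        if section is not None:
            if not isinstance(section, dict):
                raise ValueError(f"configuration section '{name}' must be "
                                 "a mapping")
            kwargs[name] = _build(cls, section, name)
    for key in ("out_dir", "log_level"):
        if key in mapping:
            kwargs[key] = mapping.pop(key)
    if mapping:
        raise ValueError("unknown configuration key: "
                         f"{sorted(mapping)[0]}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        return config_from_mapping(yaml.safe_load(fh))
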