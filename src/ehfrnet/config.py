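"""Run configuration: schema, strict YAML (de)serialization, seed fan-out.

A :class:`RunConfig` nests the architecture, training and data-generation
configurations.  Parsing is strict — unknown keys are rejected by name — and
``parse(serialize(cfg))`` is the identity.  The global seed fans out to
per-module seeds through a fixed name hash so each module is independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .network import NetworkConfig
from .synthetic import SyntheticSpec
from .training import TrainConfig

__all__ = ["RunConfig", "parse_config", "serialize_config", "derive_seed",
           "ConfigError"]

SCHEMA_VERSION = 1

COMMANDS = ("analyze", "train", "eval", "synth-data", "gradcam")


class ConfigError(ValueError):
    pass


def derive_seed(seed: int, module_name: str) -> int:
    """Stable per-module seed below 2**31."""
    return (int(seed) + zlib.crc32(module_name.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    command: str = "analyze"
    seed: int = 0
    out_dir: str = "runs"
    verbosity: int = 1
    schema_version: int = SCHEMA_VERSION
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)

    def __post_init__(self):
        if self.command not in COMMANDS:
            raise ConfigError(f"unknown command {self.command!r}; "
                              f"choose from {COMMANDS}")


_TUPLE_FIELDS = {"patch_size", "motif_counts", "background", "crop_scale"}


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown key {key!r} in {context}")
    kwargs = {}
    for name, value in data.items():
        if name in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def parse_config(text_or_dict) -> RunConfig:
    data = (yaml.safe_load(text_or_dict) if isinstance(text_or_dict, str)
            else dict(text_or_dict))
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    nested = {"network": NetworkConfig, "train": TrainConfig,
              "synthetic": SyntheticSpec}
    top = {k: v for k, v in data.items() if k not in nested}
    cfg = _build(RunConfig, top, "run config")
    for key, cls in nested.items():
        if key in data:
            setattr(cfg, key, _build(cls, data[key], key))
    version = cfg.schema_version
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    return cfg


def serialize_config(cfg: RunConfig) -> str:
    data = asdict(cfg)
    for section in ("network", "synthetic"):
        for key, value in data[section].items():
            if isinstance(value, tuple):
                data[section][key] = list(value)
    return yaml.safe_dump(data, sort_keys=True)


def load_config_file(path) -> RunConfig:
    return parse_config(Path(path).read_text())


def write_resolved(cfg: RunConfig, out_dir) -> Path:
    """Drop a fully resolved config next to a run's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = out / "resolved_config.yaml"
    target.write_text(serialize_config(cfg))
    return target
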