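"""Run configuration: YAML loading, schema validation, logging setup.

A run configuration nests the per-stage parameter dataclasses. Unknown
keys fail fast with :class:`ConfigError` before any stage executes, and
the fully resolved configuration can be serialised back into a run
directory for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .denoise import DenoiseConfig
from .features import FeatureConfig
from .train_eval import TrainConfig

__all__ = ["ConfigError", "AudioConfig", "ModelConfig", "LossConfig",
           "RunConfig", "load_config", "dump_config", "setup_logging"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class AudioConfig:
    sample_rate: int = 44_100
    seg_seconds: float = 60.0


@dataclass
class ModelConfig:
    backbone: str = "tinycnn"
    in_channels: int = 1


@dataclass
class LossConfig:
    gamma: float = 2.0
    lambda_schedule: str = "linear"   # linear | cosine
    alpha: str = "auto"               # auto (inverse class frequency)


@dataclass
class RunConfig:
    audio: AudioConfig = field(default_factory=AudioConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def resolved_train(self) -> TrainConfig:
        """Training config with the loss-section knobs folded in."""
        return dataclasses.replace(self.train, gamma=self.loss.gamma,
                                   lambda_kind=self.loss.lambda_schedule)


def _build_section(cls, data, section: str):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


_SECTIONS = {
    "audio": AudioConfig, "denoise": DenoiseConfig, "features": FeatureConfig,
    "model": ModelConfig, "loss": LossConfig, "train": TrainConfig,
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a validated run config from YAML plus nested override dicts.

    Precedence: overrides > YAML file > built-in defaults.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping at top level")
        data = raw
    for section, values in (overrides or {}).items():
        data.setdefault(section, {})
        if values:
            data[section] = {**(data[section] or {}), **values}
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {name: _build_section(cls, data.get(name), name)
              for name, cls in _SECTIONS.items()}
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Serialise the resolved configuration as YAML."""
    payload = {name: dataclasses.asdict(getattr(config, name))
               for name in _SECTIONS}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def setup_logging(run_dir: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    """Console logging, plus a plain-text log file inside the run directory."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(run_dir / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
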