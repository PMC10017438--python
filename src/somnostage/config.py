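"""YAML application config with strict (unknown-key-rejecting) validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import ModelConfig
from .preprocess import PreprocessConfig
from .training import TrainConfig


class ConfigError(ValueError):
    pass


def _build(cls, section: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in config section {where!r}")
    return cls(**section)


@dataclass
class Montage:
    eeg: list[str] = field(default_factory=list)
    eog: dict | None = None   # {"left": label, "right": label}

    def roles(self) -> dict[str, str]:
        roles = {c: "EEG" for c in self.eeg}
        if self.eog:
            roles[self.eog["left"]] = "EOG_L"
            roles[self.eog["right"]] = "EOG_R"
        return roles


@dataclass
class Augmentation:
    polarity_flips: bool = True


@dataclass
class AppConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    montage: Montage = field(default_factory=Montage)
    augmentation: Augmentation = field(default_factory=Augmentation)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "AppConfig":
        known = {"preprocess", "model", "train", "montage", "augmentation",
                 "seed", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown top-level config key(s) {sorted(unknown)}")
        return cls(
            preprocess=_build(PreprocessConfig, raw.get("preprocess", {}), "preprocess"),
            model=_build(ModelConfig, raw.get("model", {}), "model"),
            train=_build(TrainConfig, raw.get("train", {}), "train"),
            montage=_build(Montage, raw.get("montage", {}), "montage"),
            augmentation=_build(Augmentation, raw.get("augmentation", {}), "augmentation"),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "AppConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
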