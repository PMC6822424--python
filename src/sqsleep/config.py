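"""Declarative configuration for the staging pipeline.

One YAML file with one section per stage; every default is the
pipeline's canonical operating point (0.5-100 Hz band-pass, 50 Hz
notch, 207 Hz rate, 300 µV artifact threshold, 1.5x activation factor,
30-s epochs, 100 trees, 10-observation split minimum). Unknown keys
are rejected by name so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    band_lo: float = 0.5
    band_hi: float = 100.0
    notch: float = 50.0
    artifact_threshold_uV: float = 300.0
    artifact_guard_s: float = 0.5
    target_fs: float = 207.0
    sync_max_lag_s: float = 2.0


@dataclass
class FeatureConfig:
    voices_per_octave: int = 12
    pad_s: float = 5.0
    activation_factor: float = 1.5
    epoch_len: float = 30.0


@dataclass
class ForestConfig:
    n_trees: int = 100
    min_obs_to_split: int = 10
    features_per_split: int | str = "sqrt"


@dataclass
class SynthSection:
    n_patients: int = 4
    nights_per_patient: tuple[int, ...] = (3, 2, 3, 3)
    epochs_per_night: int = 720
    fs: float = 207.0
    subject_gain_sd: float = 0.2
    interchannel_corr: float = 0.7
    artifact_rate_per_hour: float = 2.0


@dataclass
class PipelineConfig:
    seed: int = 0
    schemes: tuple[str, ...] = ("PS", "LONO")
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    synth: SynthSection = field(default_factory=SynthSection)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schemes"] = list(self.schemes)
        d["synth"]["nights_per_patient"] = list(self.synth.nights_per_patient)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {
            "preprocess": PreprocessConfig,
            "features": FeatureConfig,
            "forest": ForestConfig,
            "synth": SynthSection,
        }
        top_keys = {f.name for f in fields(cls)}
        bad = sorted(set(raw) - top_keys)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        kwargs: dict = {}
        for name, section_cls in sections.items():
            sub = raw.get(name, {}) or {}
            known = {f.name for f in fields(section_cls)}
            bad = sorted(set(sub) - known)
            if bad:
                raise ValueError(f"unknown keys in section '{name}': {bad}")
            if "nights_per_patient" in sub:
                sub["nights_per_patient"] = tuple(sub["nights_per_patient"])
            kwargs[name] = section_cls(**sub)
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "schemes" in raw:
            kwargs["schemes"] = tuple(s.upper() for s in raw["schemes"])
        return cls(**kwargs)
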