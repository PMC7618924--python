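"""Declarative pipeline configuration.

One master seed fans out into independent per-module substreams (stable
derivation, so adding a module never shifts another's randomness).  Unknown
keys are rejected; the canonical-JSON SHA-256 hash of a config is recorded
in every output log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import ConfigError, spawn_seeds

_MODULES = ("synth", "preprocess", "segment", "track", "morphometry")


@dataclass
class SynthConfig:
    preset: str = "blastocyst"
    n_outer: int = 12
    n_inner: int = 4
    n_frames: int = 40
    division_schedule: list = field(default_factory=lambda: [6, 12, 18, 24, 30, 36])
    kappa: float = 0.8
    oscillation: list = field(default_factory=lambda: [0.06, 24.0])
    radius: float = 30.0
    drift: float = 1.0
    n_micronuclei: int = 0
    spacing: list = field(default_factory=lambda: [2.0, 1.0, 1.0])
    blur_sigma: list = field(default_factory=lambda: [1.6, 0.8, 0.8])
    noise: list = field(default_factory=lambda: [50.0, 0.05])


@dataclass
class PreprocessConfig:
    target_spacing: list | None = None  # None: keep native grid
    p_low: float = 1.0
    p_high: float = 99.8
    gamma: float = 0.8
    axial_factor: int = 1
    per_movie: bool = False


@dataclass
class SegmentConfig:
    smooth_sigma: list = field(default_factory=lambda: [1.0, 0.6, 0.6])
    threshold: str = "half-max"
    min_seed_distance: float = 6.0
    min_volume: float = 30.0


@dataclass
class TrackConfig:
    epsilon: float | str = 0.0
    lambda_disp: float = 0.01
    min_daughter_fraction: float = 0.2


@dataclass
class MorphometryConfig:
    ks_null: str = "isotropic-axis"
    hull_samples: int = 20000


@dataclass
class PipelineConfig:
    seed: int = 0
    input_path: str | None = None   # None: generate synthetically
    input_layout: str = "auto"
    input_spacing: list | None = None
    verbosity: int = 1
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)

    # -- (de)serialization --------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        kwargs = {}
        blocks = {"synth": SynthConfig, "preprocess": PreprocessConfig,
                  "segment": SegmentConfig, "track": TrackConfig,
                  "morphometry": MorphometryConfig}
        for name, block_cls in blocks.items():
            sub = d.pop(name, {}) or {}
            unknown = set(sub) - {f for f in block_cls.__dataclass_fields__}
            if unknown:
                raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
            kwargs[name] = block_cls(**sub)
        top_fields = {f for f in cls.__dataclass_fields__} - set(blocks)
        unknown = set(d) - top_fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def module_seeds(self) -> dict[str, int]:
        seeds = spawn_seeds(self.seed, len(_MODULES))
        return dict(zip(_MODULES, seeds))
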