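"""Pipeline configuration: YAML file with one section per stage.

Example::

    matching:
      thr_r: 0.60          # region-overlap threshold
      thr_s: 0.90          # appearance (equalized NCC) threshold
      epipolar_tolerance: 1.5
      normal_gate_deg: 1.0
      propagation_threshold: 0.80
    detector:
      threshold_rel: 0.02
      min_separation: 5.0
      max_features: 4000
    tracking:
      confidence_threshold: 0.7
      max_step_px: 20.0
    tps:
      regularization: 0.0
    force:
      fit_baseline: true
      tool_radius_mm: 4.0
    io:
      reference_frame: 0

Unknown sections or keys are rejected; thresholds are validated by the
underlying dataclasses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deformation import TrackerConfig
from .exceptions import ConfigError
from .features import DetectorParams
from .matching import MatchConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class TPSSettings:
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if self.regularization < 0:
            raise ConfigError("tps.regularization must be >= 0")


@dataclass
class ForceSettings:
    fit_baseline: bool = True
    tool_radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.tool_radius_mm < 0:
            raise ConfigError("force.tool_radius_mm must be >= 0")


@dataclass
class IOSettings:
    reference_frame: int = 0

    def __post_init__(self) -> None:
        if self.reference_frame < 0:
            raise ConfigError("io.reference_frame must be >= 0")


_SECTIONS = {
    "matching": MatchConfig,
    "detector": DetectorParams,
    "tracking": TrackerConfig,
    "tps": TPSSettings,
    "force": ForceSettings,
    "io": IOSettings,
}


@dataclass
class PipelineConfig:
    """Validated settings for every pipeline stage, with full defaults."""

    matching: MatchConfig = field(default_factory=MatchConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    tracking: TrackerConfig = field(default_factory=TrackerConfig)
    tps: TPSSettings = field(default_factory=TPSSettings)
    force: ForceSettings = field(default_factory=ForceSettings)
    io: IOSettings = field(default_factory=IOSettings)

    def digest(self) -> str:
        """Short stable hash of the effective configuration, for logs."""
        blob = json.dumps(
            {s: dataclasses.asdict(getattr(self, s)) for s in _SECTIONS},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build_section(name: str, cls, values: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    # tuples serialized as lists in YAML
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in values:
            v = values[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in [{name}]: {exc}") from exc


def load_config(path=None) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration (defaults if None)."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"{path}: unknown section(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"{path}: section [{name}] must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    return PipelineConfig(**kwargs)
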