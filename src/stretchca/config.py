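"""Experiment configuration: schema-validated YAML round trip.

The config carries everything a rerun needs: the phase schedule, the
acquisition rate, the stretch magnitude, the drug condition flags, every
analysis threshold and segmentation parameter, and the input paths.  Unknown
keys are rejected so typos cannot silently fall back to defaults, and the
full resolved parameter set is echoed into the output provenance block.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError
from .schedule import PhaseSchedule
from .traces import AnalysisParams
from .imaging import SegmentationParams

__all__ = ["ExperimentConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScheduleConfig(_Strict):
    phase_durations_s: list[float] = Field(default=[60.0, 60.0, 60.0, 60.0],
                                           min_length=4, max_length=4)
    frame_rate: float = 10.0
    stretch_percent: float = 15.0

    @model_validator(mode="after")
    def _positive(self) -> "ScheduleConfig":
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if any(d < 0 for d in self.phase_durations_s):
            raise ValueError("phase durations must be non-negative")
        return self


class ConditionConfig(_Strict):
    gsmtx4: bool = False
    yoda1: bool = False


_ANALYSIS_DEFAULTS = AnalysisParams()
_SEG_DEFAULTS = SegmentationParams()


class AnalysisConfig(_Strict):
    prominence_threshold: float = _ANALYSIS_DEFAULTS.prominence_threshold
    s0_window_s: float = _ANALYSIS_DEFAULTS.s0_window_s
    spontaneous_min_peaks: int = _ANALYSIS_DEFAULTS.spontaneous_min_peaks
    sustained_delta: float = _ANALYSIS_DEFAULTS.sustained_delta
    retention_fraction: float = _ANALYSIS_DEFAULTS.retention_fraction
    initial_response_window_s: float = _ANALYSIS_DEFAULTS.initial_response_window_s
    baseline_percentile: float = _ANALYSIS_DEFAULTS.baseline_percentile
    elevation_threshold: float = _ANALYSIS_DEFAULTS.elevation_threshold
    spontaneous_includes_PII: bool = _ANALYSIS_DEFAULTS.spontaneous_includes_PII

    def to_params(self) -> AnalysisParams:
        return AnalysisParams(**self.model_dump())


class SegmentationConfig(_Strict):
    threshold: Optional[float] = _SEG_DEFAULTS.threshold
    min_area: int = _SEG_DEFAULTS.min_area
    min_distance: int = _SEG_DEFAULTS.min_distance
    smoothing_sigma: float = _SEG_DEFAULTS.smoothing_sigma

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class PathsConfig(_Strict):
    stack: Optional[str] = None
    dark: Optional[str] = None
    flat: Optional[str] = None


class ExperimentConfig(_Strict):
    sample_id: str = "sample"
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    condition: ConditionConfig = Field(default_factory=ConditionConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)
    seed: int = 0

    def phase_schedule(self) -> PhaseSchedule:
        d = self.schedule.phase_durations_s
        starts = [0.0]
        for x in d[:-1]:
            starts.append(starts[-1] + x)
        ends = [s + x for s, x in zip(starts, d)]
        return PhaseSchedule(starts=tuple(starts), ends=tuple(ends),
                             frame_rate=self.schedule.frame_rate,
                             stretch_percent=self.schedule.stretch_percent,
                             gsmtx4=self.condition.gsmtx4,
                             yoda1=self.condition.yoda1)

    def provenance(self, software_version: str) -> dict:
        """Every numeric threshold used anywhere, plus a config hash."""
        blob = self.model_dump()
        digest = hashlib.sha256(
            json.dumps(blob, sort_keys=True).encode()).hexdigest()[:16]
        return {"software_version": software_version,
                "config_sha256": digest, "config": blob}


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML experiment config."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig.model_validate(data)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) or "<root>"
                           for e in exc.errors())
        raise ConfigurationError(
            f"invalid config {path}: problem fields: {fields}") from exc


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
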