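"""Configuration models for every pipeline stage.

All models are strict (unknown keys rejected) and JSON round-trippable:
``PipelineConfig.from_json(cfg.to_json()) == cfg``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class LatencyParams(StrictModel):
    """Class-conditional distribution of injected bout->event latencies (ms)."""

    mean_ms: float
    sd_ms: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _finite(self) -> "LatencyParams":
        import math

        if not (math.isfinite(self.mean_ms) and math.isfinite(self.sd_ms)):
            raise ValueError("latency distribution parameters must be finite")
        return self


class GeneratorConfig(StrictModel):
    """Parameters of the synthetic mattress-night generator."""

    sampling_rate: float = Field(default=54.0, gt=0.0)
    night_duration: float = Field(default=28800.0, description="seconds")
    n_sensors: int = Field(default=32, ge=1)
    resp_base_freq: float = Field(default=0.366, gt=0.0)
    resp_amplitude: float = Field(default=1.0, gt=0.0)
    bout_recurrence_mean: float = Field(default=120.0, gt=0.0)
    bout_recurrence_jitter_sd: float = Field(default=10.0, ge=0.0)
    bout_duration_range: Tuple[float, float] = (5.0, 15.0)
    bout_band_freq_range: Tuple[float, float] = (0.15, 0.20)
    # movement deflections on a pressure pad are several times larger than
    # breathing excursions
    bout_amplitude: float = Field(default=3.0, gt=0.0)
    bout_attack_s: float = Field(default=1.0, gt=0.0)
    upregulation_magnitude: float = Field(default=0.15, gt=0.0)
    upregulation_duration: float = Field(default=20.0, gt=0.0)
    upregulation_ramp: float = Field(default=2.0, gt=0.0)
    uncoupled_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    noise_sd: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.night_duration <= 600:
            raise ValueError("night_duration must exceed 600 s")
        lo, hi = self.bout_duration_range
        if not (0 < lo <= hi):
            raise ValueError("bout_duration_range must be increasing and positive")
        lo, hi = self.bout_band_freq_range
        if not (0 < lo <= hi):
            raise ValueError("bout_band_freq_range must be increasing and positive")
        if 2 * self.upregulation_ramp > self.upregulation_duration:
            raise ValueError("upregulation ramps longer than the event itself")
        return self


class BandConfig(StrictModel):
    """Zero-phase Butterworth band edges for the two streams (Hz)."""

    sm_band: Tuple[float, float] = (0.01, 0.15)
    rr_band: Tuple[float, float] = (0.25, 0.55)
    order: int = Field(default=4, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "BandConfig":
        for lo, hi in (self.sm_band, self.rr_band):
            if not (0 < lo < hi):
                raise ValueError("band edges must satisfy 0 < low < high")
        return self


class BoutDetectionConfig(StrictModel):
    envelope_smooth_s: float = Field(default=2.0, gt=0.0)
    threshold_mads: float = Field(default=4.0, gt=0.0)
    merge_gap_s: float = Field(default=10.0, ge=0.0)
    min_duration_s: float = Field(default=2.0, ge=0.0)


class RRRateConfig(StrictModel):
    freq_smooth_s: float = Field(default=10.0, gt=0.0)
    bin_s: float = Field(default=120.0, gt=0.0)
    valid_band: Tuple[float, float] = (0.12, 0.60)
    max_freq_jitter_hz: float = Field(default=0.012, gt=0.0)
    min_envelope_frac: float = Field(default=0.30, gt=0.0)
    min_valid_fraction: float = Field(default=0.50, gt=0.0, le=1.0)


class EventDetectionConfig(StrictModel):
    window_s: float = Field(default=600.0, gt=0.0)
    threshold_sds: float = Field(default=1.0, gt=0.0)
    sustain_s: float = Field(default=3.0, gt=0.0)
    merge_gap_s: float = Field(default=5.0, ge=0.0)
    bidirectional: bool = False


class PairingConfig(StrictModel):
    radius_s: float = Field(default=30.0, gt=0.0)
    method: Literal["onset", "xcorr"] = "onset"
    max_mode: Literal["absolute", "signed"] = "absolute"


class HistogramConfig(StrictModel):
    bin_width_ms: float = Field(default=20.0, gt=0.0)
    range_ms: Tuple[float, float] = (-1000.0, 1000.0)
    min_windows: int = Field(default=5, ge=1)


class ClassifierSpec(StrictModel):
    """One classification family plus its (few) hyperparameters."""

    family: Literal["neural_network", "gaussian", "kernel", "latency_threshold"]
    hidden_units: int = Field(default=8, ge=1)
    max_iter: int = Field(default=500, ge=1)
    threshold_ms: float = 70.0
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _seeded(self) -> "ClassifierSpec":
        if self.family == "neural_network" and self.seed is None:
            raise ValueError("neural_network requires an explicit seed")
        return self


class CohortConfig(StrictModel):
    n_per_class: int = Field(default=20, ge=2)
    nights_per_case: int = Field(default=2, ge=1)
    mci_latency: LatencyParams = LatencyParams(mean_ms=-50.0, sd_ms=40.0)
    nc_latency: LatencyParams = LatencyParams(mean_ms=150.0, sd_ms=40.0)


class PipelineConfig(StrictModel):
    """Everything one end-to-end run needs, plus the mandatory global seed."""

    seed: int
    generator: GeneratorConfig = GeneratorConfig(night_duration=7200.0)
    cohort: CohortConfig = CohortConfig()
    bands: BandConfig = BandConfig()
    bouts: BoutDetectionConfig = BoutDetectionConfig()
    rr_rate: RRRateConfig = RRRateConfig()
    events: EventDetectionConfig = EventDetectionConfig()
    pairing: PairingConfig = PairingConfig()
    histogram: HistogramConfig = HistogramConfig()
    classifiers: Tuple[ClassifierSpec, ...] = ()
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None

    def to_json(self, path: Optional[Path] = None) -> str:
        text = json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        return cls.model_validate(json.loads(text))

    def with_classifier_seeds(self) -> "PipelineConfig":
        """Return a copy where classifier specs missing a seed inherit the global one."""
        specs = tuple(
            s if s.seed is not None else s.model_copy(update={"seed": self.seed})
            for s in self.classifiers
        )
        return self.model_copy(update={"classifiers": specs})


def default_classifier_specs(seed: int) -> Tuple[ClassifierSpec, ...]:
    return (
        ClassifierSpec(family="neural_network", seed=seed),
        ClassifierSpec(family="gaussian", seed=seed),
        ClassifierSpec(family="kernel", seed=seed),
        ClassifierSpec(family="latency_threshold", seed=seed),
    )
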