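"""Run configuration: YAML schema, validation and conversion to domain types.

Configuration files use bench units (mm, mL, cm2); everything internal is
SI.  Unknown keys are rejected so typos fail loudly, and schema errors
carry the offending field path.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .dose import DEFAULT_STIMULATION_DURATION, PulseWaveform, standard_settings
from .errors import ConfigurationError
from .geometry import ChamberGeometry2D

__all__ = ["GeometryConfig", "WaveformConfig", "SolverConfig", "RunConfig",
           "load_config", "default_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_StrictModel):
    well_diameter_mm: float = 22.1
    electrode_gap_mm: float = 11.0
    electrode_width_mm: float = 0.42e2 / 3.4  # wetted area over fill level
    electrode_thickness_mm: float = 1.0
    fill_level_mm: float | None = 3.4
    liquid_volume_ml: float | None = None
    effective_area_cm2: float | None = None
    conductivity_S_per_m: float = 1.3

    @model_validator(mode="after")
    def _fill_derivable(self) -> "GeometryConfig":
        if self.fill_level_mm is None and not (
            self.liquid_volume_ml is not None and self.effective_area_cm2
        ):
            raise ValueError(
                "provide fill_level_mm, or liquid_volume_ml with "
                "effective_area_cm2"
            )
        return self

    def to_geometry(self) -> ChamberGeometry2D:
        return ChamberGeometry2D(
            well_diameter=self.well_diameter_mm * 1e-3,
            electrode_gap=self.electrode_gap_mm * 1e-3,
            electrode_width=self.electrode_width_mm * 1e-3,
            electrode_thickness=self.electrode_thickness_mm * 1e-3,
            fill_level=(
                self.fill_level_mm * 1e-3 if self.fill_level_mm is not None
                else None
            ),
            liquid_volume=(
                self.liquid_volume_ml * 1e-6
                if self.liquid_volume_ml is not None
                else None
            ),
            effective_liquid_area=(
                self.effective_area_cm2 * 1e-4
                if self.effective_area_cm2 is not None
                else None
            ),
            conductivity=self.conductivity_S_per_m,
        )


class WaveformConfig(_StrictModel):
    code: str | None = None
    voltage_V: float = Field(ge=0)
    frequency_Hz: float = Field(gt=0)
    pulse_ms: float = Field(gt=0)

    def to_waveform(self) -> PulseWaveform:
        return PulseWaveform(
            amplitude=self.voltage_V,
            frequency=self.frequency_Hz,
            pulse_duration=self.pulse_ms * 1e-3,
            code=self.code or f"{self.voltage_V:g} V_{self.frequency_Hz:g} Hz",
        )


class SolverConfig(_StrictModel):
    edge_length_mm: float = Field(default=0.5, gt=0)
    profile_samples: int = Field(default=201, ge=3)
    homogeneity_bands: list[tuple[float, float]] = Field(
        default_factory=lambda: [(80.0, 100.0), (85.0, 95.0)]
    )


class RunConfig(_StrictModel):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    settings: list[WaveformConfig] | None = None
    solver: SolverConfig = Field(default_factory=SolverConfig)
    stimulation_duration_s: float = Field(
        default=DEFAULT_STIMULATION_DURATION, ge=0
    )
    seed: int = 0

    def waveforms(self) -> list[PulseWaveform]:
        if self.settings is None:
            return standard_settings()
        return [w.to_waveform() for w in self.settings]


def default_config() -> RunConfig:
    """The calibrated default run configuration."""
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Raises :class:`ConfigurationError` with the field path on schema
    violations.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid config {path}: {details}") from exc
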