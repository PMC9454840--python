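"""Biphasic pulse waveforms and per-well dose metrics.

The stimulator delivers charge-balanced biphasic rectangular pulses: in
each period of a pulse train at frequency f, the voltage is +A for the
first half-pulse, -A for the second, and zero for the rest of the
period.  ``pulse_duration`` (tau) is the total biphasic duration covering
BOTH half-pulses, so each polarity lasts tau/2 and the duty cycle is
f * tau.

For rectangular pulses the instantaneous power during the pulse is
constant (V * I_peak regardless of polarity), so the time-averaged power
has the closed form V * I_peak * duty and the deposited energy over a
stimulation session is that power times the session duration.  Dividing
the energy by the liquid heat capacity gives an adiabatic (no losses)
upper bound on the medium temperature rise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidWaveformError
from .geometry import ChamberGeometry2D
from .solver import (
    PotentialField,
    centerline_profile,
    electrode_current_per_depth,
    scale_to_voltage,
    total_current,
)

__all__ = [
    "PulseWaveform",
    "DoseSummary",
    "standard_settings",
    "duty_cycle",
    "sample_waveform",
    "average_power",
    "deposited_energy",
    "adiabatic_temp_rise",
    "dose_table",
    "WATER_DENSITY",
    "WATER_HEAT_CAPACITY",
    "DEFAULT_STIMULATION_DURATION",
]

#: medium thermal defaults (water)
WATER_DENSITY = 1000.0  # kg/m3
WATER_HEAT_CAPACITY = 4184.0  # J/(kg K)
#: default stimulation session length (s); the standard protocol is 10 min
DEFAULT_STIMULATION_DURATION = 600.0


@dataclass(frozen=True)
class PulseWaveform:
    """Symmetric biphasic rectangular stimulus.

    ``amplitude`` is the peak voltage (applied as +-amplitude),
    ``frequency`` the pulse repetition rate (Hz) and ``pulse_duration``
    the total biphasic duration tau (s), both half-pulses together.
    """

    amplitude: float
    frequency: float
    pulse_duration: float
    code: str | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidWaveformError("amplitude must be non-negative")
        if self.frequency <= 0:
            raise InvalidWaveformError("frequency must be positive")
        if not 0 < self.pulse_duration <= 1.0 / self.frequency:
            raise InvalidWaveformError(
                "pulse_duration must satisfy 0 < tau <= 1/f"
            )

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


def standard_settings() -> list[PulseWaveform]:
    """The four stimulator settings: 1 or 5 V at 20 Hz (3.6 ms) or 7.9 Hz
    (10 ms)."""
    return [
        PulseWaveform(1.0, 20.0, 3.6e-3, code="1 V_20 Hz"),
        PulseWaveform(1.0, 7.9, 10.0e-3, code="1 V_7.9 Hz"),
        PulseWaveform(5.0, 20.0, 3.6e-3, code="5 V_20 Hz"),
        PulseWaveform(5.0, 7.9, 10.0e-3, code="5 V_7.9 Hz"),
    ]


@dataclass(frozen=True)
class DoseSummary:
    """One dose-table record for a stimulator setting."""

    code: str
    voltage: float
    frequency: float
    pulse_duration: float
    field_strength: float          # V/m, FEM centerline midpoint
    theoretical_current: float     # A, FEM prediction at the medium sigma
    measured_current: float | None
    duty_cycle: float
    average_power: float           # W, theoretical-current branch
    deposited_energy: float        # J, over the stated duration
    temp_rise_bound: float         # K, adiabatic upper bound
    duration: float                # s, stimulation session length


def duty_cycle(waveform: PulseWaveform) -> float:
    """Fraction of each period during which the stimulus is nonzero: f * tau."""
    duty = waveform.frequency * waveform.pulse_duration
    if duty > 1.0:
        raise InvalidWaveformError("duty cycle f * tau exceeds 1")
    return duty


def sample_waveform(
    waveform: PulseWaveform, sample_rate: float, n_periods: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the ideal waveform; returns (time, voltage) arrays.

    Each period holds +amplitude for tau/2, then -amplitude for tau/2,
    then zero.  The sample count per polarity is matched to within one
    sample, so the series mean vanishes up to one sample per period.
    """
    if sample_rate <= 10.0 / waveform.pulse_duration:
        raise InvalidWaveformError(
            "sample_rate must exceed 10 samples per pulse duration"
        )
    if n_periods < 1:
        raise InvalidWaveformError("n_periods must be at least 1")
    samples_per_period = sample_rate / waveform.frequency
    n = int(round(n_periods * samples_per_period))
    i = np.arange(n)
    phase = i % samples_per_period  # in samples; exact for integer periods
    half = sample_rate * waveform.pulse_duration / 2.0
    v = np.zeros(n)
    v[phase < half] = +waveform.amplitude
    v[(phase >= half) & (phase < 2.0 * half)] = -waveform.amplitude
    t = i / sample_rate
    return t, v


def average_power(waveform: PulseWaveform, peak_current: float) -> float:
    """Time-averaged dissipated power V * I_peak * duty (W)."""
    if peak_current < 0:
        raise InvalidWaveformError("peak_current must be non-negative")
    return waveform.amplitude * peak_current * duty_cycle(waveform)


def deposited_energy(
    waveform: PulseWaveform, peak_current: float, duration: float
) -> float:
    """Energy deposited into the well over a stimulation session (J)."""
    if duration < 0:
        raise InvalidWaveformError("duration must be non-negative")
    return average_power(waveform, peak_current) * duration


def adiabatic_temp_rise(
    energy: float,
    liquid_volume: float,
    density: float = WATER_DENSITY,
    heat_capacity: float = WATER_HEAT_CAPACITY,
) -> float:
    """Upper bound on the liquid temperature rise (K), assuming no losses.

    Delta T = E / (V * rho * c_p).  Real chambers lose heat to the plate
    and incubator air, so measured rises fall below this bound.
    """
    if liquid_volume <= 0 or density <= 0 or heat_capacity <= 0:
        raise ValueError("volume, density and heat capacity must be positive")
    if energy < 0:
        raise ValueError("energy must be non-negative")
    return energy / (liquid_volume * density * heat_capacity)


def dose_table(
    geometry: ChamberGeometry2D,
    settings: list[PulseWaveform],
    field: PotentialField,
    measurements: dict[str, float] | None = None,
    duration: float = DEFAULT_STIMULATION_DURATION,
) -> list[DoseSummary]:
    """Per-setting dose summaries from one reference field solution.

    ``field`` is a solved potential at any nonzero voltage; it is rescaled
    per setting (linearity).  The theoretical current uses the geometry's
    medium conductivity.  ``measurements`` optionally maps setting codes
    to measured peak currents (A); unknown codes are ignored with a note
    in the returned summaries' absence (they do not raise).
    """
    profile = centerline_profile(field, 201)
    midpoint_per_volt = profile.midpoint_field / field.voltage_difference
    per_depth = electrode_current_per_depth(field, geometry.conductivity)
    current_per_volt = (
        total_current(per_depth, geometry.fill_level, geometry.conductivity)
        / field.voltage_difference
    )
    measurements = measurements or {}
    rows = []
    for wf in settings:
        scale_to_voltage(field, wf.amplitude)  # validates rescalability
        code = wf.code or f"{wf.amplitude:g} V_{wf.frequency:g} Hz"
        i_theory = current_per_volt * wf.amplitude
        duty = duty_cycle(wf)
        power = average_power(wf, i_theory)
        energy = deposited_energy(wf, i_theory, duration)
        volume = geometry.liquid_volume
        if volume is None:
            area = geometry.effective_liquid_area
            if not area:  # fall back to the plain well cross-section
                area = np.pi * geometry.well_radius**2
            volume = geometry.fill_level * area
        rows.append(
            DoseSummary(
                code=code,
                voltage=wf.amplitude,
                frequency=wf.frequency,
                pulse_duration=wf.pulse_duration,
                field_strength=midpoint_per_volt * wf.amplitude,
                theoretical_current=i_theory,
                measured_current=measurements.get(code),
                duty_cycle=duty,
                average_power=power,
                deposited_energy=energy,
                temp_rise_bound=adiabatic_temp_rise(energy, volume),
                duration=duration,
            )
        )
    return rows


def dose_frame(summaries: list[DoseSummary]) -> pd.DataFrame:
    """Dose summaries as a DataFrame with the canonical CSV columns."""
    return pd.DataFrame(
        {
            "code": [s.code for s in summaries],
            "voltage_V": [s.voltage for s in summaries],
            "frequency_Hz": [s.frequency for s in summaries],
            "pulse_ms": [s.pulse_duration * 1e3 for s in summaries],
            "field_V_per_m": [s.field_strength for s in summaries],
            "I_theory_A": [s.theoretical_current for s in summaries],
            "I_measured_A": [
                np.nan if s.measured_current is None else s.measured_current
                for s in summaries
            ],
            "duty": [s.duty_cycle for s in summaries],
            "P_avg_W": [s.average_power for s in summaries],
            "E_J": [s.deposited_energy for s in summaries],
            "dT_max_K": [s.temp_rise_bound for s in summaries],
        }
    )
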