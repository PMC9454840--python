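"""Model-measurement comparison for electrode currents.

The measurable observable of the chamber model is the electrode current,
read as the peak of the shunt-resistor voltage (R = 1 Ohm, so volts read
as amperes).  Two diagnostics quantify the comparison:

* the voltage-scaling factor I(V_high)/I(V_low) of the measured currents,
  checked against the ideal ratio V_high/V_low implied by linearity; and
* the prediction ratio measured/predicted per setting.

The packaged measurement fixture holds the published peak currents of
the four stimulator settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dose import PulseWaveform
from .errors import DataError, IncompleteDataError
from .geometry import ChamberGeometry2D
from .solver import PotentialField, electrode_current_per_depth, total_current

__all__ = [
    "MeasurementRecord",
    "ValidationReport",
    "load_measurements",
    "packaged_measurements",
    "voltage_scaling_factor",
    "prediction_ratio",
    "build_report",
    "LINEARITY_FLAG_THRESHOLD",
]

#: relative deviation of the scaling factor from the ideal voltage ratio
#: above which the linearity flag is raised
LINEARITY_FLAG_THRESHOLD = 0.05

_COLUMNS = ["code", "voltage_V", "frequency_Hz", "pulse_ms", "I_measured_A"]


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured peak current for a stimulator setting."""

    code: str
    current: float  # A, pulse-top peak
    voltage: float  # V
    frequency: float  # Hz

    def __post_init__(self) -> None:
        if self.current < 0:
            raise DataError(f"negative current for {self.code!r}")


@dataclass
class ValidationReport:
    """Predicted-vs-measured comparison plus scaling diagnostics."""

    rows: pd.DataFrame
    scaling_factors: dict[float, float]  # frequency -> measured I ratio
    ideal_ratio: float | None
    linearity_flag: bool
    notes: list[str] = dataclass_field(default_factory=list)

    def summary(self) -> str:
        lines = ["Electrode current validation", "=" * 28, ""]
        lines.append(self.rows.to_string(index=False))
        lines.append("")
        if self.ideal_ratio is not None:
            for freq, factor in sorted(self.scaling_factors.items()):
                lines.append(
                    f"measured current scaling at {freq:g} Hz: {factor:.2g} "
                    f"(ideal voltage ratio {self.ideal_ratio:g})"
                )
            lines.append(
                "linearity flag: "
                + ("RAISED (deviation > "
                   f"{LINEARITY_FLAG_THRESHOLD:.0%})" if self.linearity_flag
                   else "not raised")
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def load_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read measurement records from a CSV file.

    Expected columns: ``code, voltage_V, frequency_Hz, pulse_ms,
    I_measured_A``.  A malformed row raises :class:`DataError` naming the
    line number (1-based, header is line 1).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise DataError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{path} lacks columns {missing}", line=1)
    records = []
    codes: set[str] = set()
    for idx, row in frame.iterrows():
        line = idx + 2
        try:
            record = MeasurementRecord(
                code=str(row["code"]).strip(),
                current=float(row["I_measured_A"]),
                voltage=float(row["voltage_V"]),
                frequency=float(row["frequency_Hz"]),
            )
        except (TypeError, ValueError) as exc:
            raise DataError(f"malformed measurement row: {exc}", line=line) from exc
        if record.code in codes:
            raise DataError(f"duplicate code {record.code!r}", line=line)
        codes.add(record.code)
        records.append(record)
    return records


def packaged_measurements() -> list[MeasurementRecord]:
    """The packaged published peak-current table for the four settings."""
    with resources.as_file(
        resources.files("wellfield.data") / "measured_currents.csv"
    ) as path:
        return load_measurements(path)


def voltage_scaling_factor(
    records: list[MeasurementRecord],
    v_low: float,
    v_high: float,
    frequency: float | None = None,
) -> float:
    """Measured current ratio I(v_high) / I(v_low).

    With ``frequency`` given, only that pulse frequency is used; otherwise
    the ratio is averaged over every frequency at which both voltage
    levels were measured.  Raises :class:`IncompleteDataError` when a
    level is missing.
    """
    by_freq: dict[float, dict[float, float]] = {}
    for r in records:
        if frequency is not None and r.frequency != frequency:
            continue
        by_freq.setdefault(r.frequency, {})[r.voltage] = r.current
    ratios = [
        levels[v_high] / levels[v_low]
        for levels in by_freq.values()
        if v_low in levels and v_high in levels and levels[v_low] > 0
    ]
    if not ratios:
        raise IncompleteDataError(
            f"no frequency has measurements at both {v_low} V and {v_high} V"
        )
    return float(np.mean(ratios))


def prediction_ratio(measured: float, predicted: float) -> float:
    """Measured over predicted current."""
    if predicted == 0:
        raise ZeroDivisionError("predicted current is zero")
    return measured / predicted


def build_report(
    geometry: ChamberGeometry2D,
    field: PotentialField,
    waveforms: list[PulseWaveform],
    records: list[MeasurementRecord],
) -> ValidationReport:
    """Assemble the per-setting predicted/measured comparison.

    Predictions come from the FEM per-depth current scaled per setting
    voltage at the geometry's medium conductivity.  The report is
    invariant under permutation of ``records``.
    """
    per_depth = electrode_current_per_depth(field, geometry.conductivity)
    current_per_volt = (
        total_current(per_depth, geometry.fill_level, geometry.conductivity)
        / field.voltage_difference
    )
    measured = {r.code: r for r in records}
    rows = []
    notes: list[str] = []
    matched = set()
    for wf in sorted(waveforms, key=lambda w: (w.amplitude, w.frequency)):
        code = wf.code or f"{wf.amplitude:g} V_{wf.frequency:g} Hz"
        predicted = current_per_volt * wf.amplitude
        record = measured.get(code)
        if record is not None:
            matched.add(code)
        rows.append(
            {
                "code": code,
                "voltage_V": wf.amplitude,
                "frequency_Hz": wf.frequency,
                "I_predicted_A": predicted,
                "I_measured_A": record.current if record else np.nan,
                "ratio_measured_over_predicted": (
                    prediction_ratio(record.current, predicted)
                    if record and predicted > 0
                    else np.nan
                ),
            }
        )
    for code in sorted(set(measured) - matched):
        notes.append(f"measurement code {code!r} matches no configured setting")

    voltages = sorted({w.amplitude for w in waveforms})
    scaling: dict[float, float] = {}
    ideal = None
    flag = False
    if len(voltages) >= 2 and records:
        v_low, v_high = voltages[0], voltages[-1]
        ideal = v_high / v_low
        for freq in sorted({r.frequency for r in records}):
            try:
                scaling[freq] = voltage_scaling_factor(
                    records, v_low, v_high, frequency=freq
                )
            except IncompleteDataError:
                continue
        flag = any(
            abs(factor / ideal - 1.0) > LINEARITY_FLAG_THRESHOLD
            for factor in scaling.values()
        )
    return ValidationReport(
        rows=pd.DataFrame(rows),
        scaling_factors=scaling,
        ideal_ratio=ideal,
        linearity_flag=flag,
        notes=notes,
    )
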