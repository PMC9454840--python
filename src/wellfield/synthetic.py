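"""Synthetic shunt-current traces and perturbed chamber geometries.

The current measurement chain observes the voltage over a 1 Ohm shunt
resistor, so the trace is numerically the electrode current.  The
generator emulates that observable: an ideal biphasic rectangular pulse
train at the stimulator timing with a given pulse-top peak, plus
zero-mean Gaussian amplifier noise and, optionally, a mains-frequency
sinusoidal confounder.  The matching peak detector estimates the
pulse-top level robustly (mean over the top of the amplitude
distribution) rather than taking the single maximum sample.

``perturbed_geometries`` jitters the dimensions the chamber datasheet
does not pin down, for sensitivity studies of the field model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dose import PulseWaveform, sample_waveform
from .errors import InvalidGeometryError
from .geometry import ChamberGeometry2D

__all__ = [
    "CurrentTrace",
    "synth_current_trace",
    "detect_peak_current",
    "perturbed_geometries",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class CurrentTrace:
    """Sampled shunt current with generator metadata."""

    time: np.ndarray  # s, uniform
    current: np.ndarray  # A
    sample_rate: float  # Hz
    true_peak: float  # A, generator ground truth
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.time) != len(self.current):
            raise ValueError("time and current must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6):
                raise ValueError("time stamps do not match sample_rate")


def synth_current_trace(
    waveform: PulseWaveform,
    peak_current: float,
    noise_sd: float,
    sample_rate: float,
    n_periods: int,
    seed: int,
    mains_amplitude: float = 0.0,
    mains_frequency: float = 50.0,
) -> CurrentTrace:
    """Noisy biphasic current trace at the waveform's timing.

    The noise-free samples are exactly the ideal waveform rescaled from
    the voltage amplitude to ``peak_current``; independent Gaussian noise
    of standard deviation ``noise_sd`` (A) is added on top.  Reproducible
    per ``seed``.
    """
    if peak_current < 0 or noise_sd < 0:
        raise ValueError("peak_current and noise_sd must be non-negative")
    t, v = sample_waveform(waveform, sample_rate, n_periods)
    if waveform.amplitude > 0:
        current = v * (peak_current / waveform.amplitude)
    else:
        current = np.zeros_like(v)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=len(current))
    if mains_amplitude > 0:
        current = current + mains_amplitude * np.sin(
            2 * np.pi * mains_frequency * t
        )
    return CurrentTrace(
        time=t,
        current=current,
        sample_rate=float(sample_rate),
        true_peak=float(peak_current),
        seed=seed,
    )


def detect_peak_current(trace: CurrentTrace) -> float:
    """Robust pulse-top peak estimate (A).

    Mean of |I| over all samples at or above 80% of the 99.9th percentile
    of |I| — a pulse-top average rather than the raw maximum, so single
    noise excursions do not bias the estimate.  Returns 0 for an all-zero
    trace.
    """
    if len(trace.current) == 0:
        raise ValueError("trace is empty")
    mags = np.abs(trace.current)
    top = np.percentile(mags, 99.9)
    if top == 0:
        return 0.0
    sel = mags >= 0.8 * top
    return float(mags[sel].mean())


def perturbed_geometries(
    base: ChamberGeometry2D,
    rel_sd: float,
    n: int,
    seed: int,
    max_tries: int = 1000,
) -> list[ChamberGeometry2D]:
    """Chamber variants with jittered gap, width and fill level.

    Each dimension receives an independent multiplicative Gaussian
    perturbation ``1 + N(0, rel_sd)``; draws violating a geometric
    invariant are resampled.  Deterministic per ``seed``.
    """
    if not 0 <= rel_sd < 0.2:
        raise ValueError("rel_sd must lie in [0, 0.2)")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    out: list[ChamberGeometry2D] = []
    tries = 0
    while len(out) < n:
        if tries > max_tries:
            raise InvalidGeometryError(
                "could not draw valid perturbed geometry; rel_sd too large "
                "for this chamber"
            )
        tries += 1
        f_gap, f_width, f_fill = 1.0 + rng.normal(0.0, rel_sd, size=3)
        try:
            out.append(
                base.with_(
                    electrode_gap=base.electrode_gap * f_gap,
                    electrode_width=base.electrode_width * f_width,
                    fill_level=base.fill_level * f_fill,
                    liquid_volume=None,
                    effective_liquid_area=None,
                )
            )
        except InvalidGeometryError:
            continue
    return out


# ---------------------------------------------------------------------------
# trace I/O: two-column CSV plus a JSON sidecar with generator parameters


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"t_s": trace.time, "I_A": trace.current}).to_csv(
        path, index=False
    )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "sample_rate_Hz": trace.sample_rate,
                "true_peak_A": trace.true_peak,
                "seed": trace.seed,
                "n_samples": len(trace.time),
            },
            indent=2,
        )
        + "\n"
    )


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    time = frame["t_s"].to_numpy()
    rate = meta.get("sample_rate_Hz")
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(time))) if len(time) > 1 else 1.0
    return CurrentTrace(
        time=time,
        current=frame["I_A"].to_numpy(),
        sample_rate=rate,
        true_peak=meta.get("true_peak_A", float("nan")),
        seed=meta.get("seed"),
    )
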