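"""Chamber geometry for plate-electrode stimulation wells.

A stimulation well is a circular culture dish holding a conductive liquid
(cell culture medium) and two parallel plate electrodes facing each other
across a gap ``d``.  The 2D field model works on the horizontal liquid
cross-section; the liquid fill level ``h`` converts per-depth quantities
into totals.

All quantities are SI internally (m, m2, m3, S/m); configuration files use
mm / mL / cm2 for convenience (see :mod:`wellfield.config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import InvalidGeometryError

__all__ = [
    "ChamberGeometry2D",
    "default_chamber",
    "fill_level_from_volume",
    "wetted_electrode_area",
]


@dataclass(frozen=True)
class ChamberGeometry2D:
    """Circular well with two parallel plate electrodes.

    Parameters
    ----------
    well_diameter:
        Inner diameter of the circular well (m).
    electrode_gap:
        Inner face-to-face distance ``d`` between the plates (m).
    electrode_width:
        Plate extent across the well, perpendicular to the gap axis (m).
    electrode_thickness:
        Plate thickness along the gap axis (m).
    fill_level:
        Liquid height ``h`` (m).  May be omitted when ``liquid_volume`` and
        ``effective_liquid_area`` are both given, in which case
        ``h = V / A_eff``.
    liquid_volume:
        Filled liquid volume (m3), optional bookkeeping input.
    effective_liquid_area:
        Calibrated horizontal liquid area (m2) used to convert volume to
        fill level.  This is a calibration constant, not the plain well
        cross-section: dead volume under/around the electrode holder makes
        the effective area smaller than pi r^2.
    conductivity:
        Liquid conductivity sigma (S/m).
    """

    well_diameter: float
    electrode_gap: float
    electrode_width: float
    electrode_thickness: float
    fill_level: float | None = None
    liquid_volume: float | None = None
    effective_liquid_area: float | None = None
    conductivity: float = 1.0

    def __post_init__(self) -> None:
        if self.fill_level is None:
            if self.liquid_volume is None or not self.effective_liquid_area:
                raise InvalidGeometryError(
                    "fill_level missing and not derivable: provide fill_level "
                    "or both liquid_volume and effective_liquid_area"
                )
            object.__setattr__(
                self, "fill_level", self.liquid_volume / self.effective_liquid_area
            )
        elif self.liquid_volume is not None and self.effective_liquid_area:
            derived = self.liquid_volume / self.effective_liquid_area
            if not math.isclose(derived, self.fill_level, rel_tol=1e-9):
                raise InvalidGeometryError(
                    f"inconsistent fill level: stated {self.fill_level} m but "
                    f"liquid_volume/effective_liquid_area = {derived} m"
                )
        for name in ("well_diameter", "electrode_gap", "electrode_width",
                     "electrode_thickness"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")
        if self.fill_level <= 0:
            raise InvalidGeometryError("fill_level must be positive")
        if self.conductivity <= 0:
            raise InvalidGeometryError("conductivity must be positive")
        if self.electrode_gap + 2 * self.electrode_thickness >= self.well_diameter:
            raise InvalidGeometryError(
                "electrodes do not fit: gap + 2*thickness must be smaller "
                "than the well diameter"
            )
        # every electrode corner must sit strictly inside the well circle
        r_corner = math.hypot(
            self.electrode_gap / 2 + self.electrode_thickness,
            self.electrode_width / 2,
        )
        if r_corner >= self.well_diameter / 2:
            raise InvalidGeometryError(
                "electrode_width exceeds the chord length of the well circle "
                "at the electrode's outer face"
            )

    # -- convenience -----------------------------------------------------

    @property
    def well_radius(self) -> float:
        return self.well_diameter / 2

    def with_(self, **changes) -> "ChamberGeometry2D":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


def default_chamber() -> ChamberGeometry2D:
    """Calibrated default 12-well stimulation chamber.

    Electrode gap 11 mm and a wetted electrode area of 0.42 cm2 at 1 mL
    fill are the two printed chamber dimensions; the fill level at 1 mL is
    3.4 mm.  The electrode width follows from wetted area / fill level
    (12.35 mm) and the effective liquid area from volume / fill level
    (2.94 cm2).  The well diameter defaults to the nominal 12-well value of
    22.1 mm and the plate thickness to 1 mm; neither is critical for the
    inter-electrode field at leading order, and both are overridable.
    The default conductivity 1.3 S/m is the measured value for complete
    cell culture medium (DMEM + 10% FCS).
    """
    fill = 3.4e-3
    volume = 1.0e-6  # 1 mL
    return ChamberGeometry2D(
        well_diameter=22.1e-3,
        electrode_gap=11.0e-3,
        electrode_width=0.42e-4 / fill,       # 12.35 mm
        electrode_thickness=1.0e-3,
        fill_level=fill,
        liquid_volume=volume,
        effective_liquid_area=volume / fill,  # 2.94 cm2
        conductivity=1.3,
    )


def fill_level_from_volume(volume: float, area: float) -> float:
    """Liquid fill level (m) for ``volume`` (m3) over an effective area (m2).

    Exact ``volume / area``; linear in volume, inversely proportional to
    area.
    """
    if area <= 0:
        raise InvalidGeometryError("effective liquid area must be positive")
    if volume < 0:
        raise InvalidGeometryError("liquid volume must be non-negative")
    return volume / area


def wetted_electrode_area(geometry: ChamberGeometry2D) -> float:
    """Wetted face area (m2) of one electrode: width x fill level."""
    return geometry.electrode_width * geometry.fill_level
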