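"""Output writers: legacy VTK, CSV tables and simple field figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .solver import CenterlineProfile, PotentialField  # noqa: E402

__all__ = [
    "write_vtk",
    "write_profile_csv",
    "write_homogeneity_csv",
    "plot_field_map",
    "plot_profile",
]


def write_vtk(field: PotentialField, path: str | Path) -> None:
    """Write the solution as a legacy ASCII VTK unstructured grid.

    Point data: ``phi`` (V).  Cell data: ``E_x``, ``E_y``, ``E_mag``
    (V/m).  Readable by ParaView and VisIt.
    """
    mesh = field.mesh
    lines = [
        "# vtk DataFile Version 3.0",
        "wellfield potential solution",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_points} double",
    ]
    for x, y in mesh.points:
        lines.append(f"{x:.10e} {y:.10e} 0.0")
    lines.append(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {mesh.n_triangles}")
    lines.extend(["5"] * mesh.n_triangles)
    lines.append(f"POINT_DATA {mesh.n_points}")
    lines.append("SCALARS phi double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{v:.10e}" for v in field.phi)
    lines.append(f"CELL_DATA {mesh.n_triangles}")
    mags = field.field_magnitude()
    for name, values in (
        ("E_x", field.efield[:, 0]),
        ("E_y", field.efield[:, 1]),
        ("E_mag", mags),
    ):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10e}" for v in values)
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile_csv(profile: CenterlineProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "position_mm": profile.positions * 1e3,
            "E_V_per_m": profile.magnitudes,
        }
    ).to_csv(path, index=False)


def write_homogeneity_csv(
    rows: list[tuple[float, float, float]], path: str | Path
) -> None:
    """Rows of (band_low, band_high, area_fraction)."""
    pd.DataFrame(
        rows, columns=["band_low", "band_high", "area_fraction"]
    ).to_csv(path, index=False)


def plot_field_map(
    field: PotentialField,
    path: str | Path,
    isolines: tuple[float, ...] = (80.0, 90.0, 100.0),
) -> None:
    """Field-magnitude map with isolines highlighting the chosen levels."""
    mesh = field.mesh
    fig, ax = plt.subplots(figsize=(5, 4.5))
    tpc = ax.tripcolor(
        mesh.points[:, 0] * 1e3,
        mesh.points[:, 1] * 1e3,
        mesh.triangles,
        facecolors=field.field_magnitude(),
        cmap="viridis",
    )
    nodal = np.hypot(*field.nodal_efield().T)
    levels = [lv for lv in sorted(isolines) if nodal.min() < lv < nodal.max()]
    if levels:
        ax.tricontour(
            mesh.points[:, 0] * 1e3,
            mesh.points[:, 1] * 1e3,
            mesh.triangles,
            nodal,
            levels=levels,
            colors="white",
            linewidths=0.7,
        )
    fig.colorbar(tpc, ax=ax, label="|E| (V/m)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile(profile: CenterlineProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.positions * 1e3, profile.magnitudes)
    ax.set_xlabel("position along centerline (mm)")
    ax.set_ylabel("|E| (V/m)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
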