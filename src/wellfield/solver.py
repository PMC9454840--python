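"""P1 finite-element solution of the electrostatic Laplace equation.

Within the quasi-static, purely conductive approximation the potential in
the liquid obeys Laplace's equation

    div(grad phi) = 0

with Dirichlet conditions phi = +V/2 / -V/2 on the two electrode
boundaries and zero normal current (homogeneous Neumann) on the
insulating well wall.  The electric field is E = -grad phi, constant per
triangle for linear elements.  Because the problem is linear in the
applied voltage, a single 1 V solve can be rescaled to any amplitude.

Electrode currents use the consistent boundary-flux (residual)
formulation: summing the assembled stiffness residual K @ phi over the
Dirichlet nodes of one electrode equals the boundary integral of the
normal flux weighted by the nodal hat functions, which is markedly more
accurate than sampling per-element gradients at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field

import matplotlib.tri as mtri
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, InvalidGeometryError, InvalidScaleError
from .geometry import ChamberGeometry2D
from .meshing import ELECTRODE_A, ELECTRODE_B, Mesh2D, generate_mesh

__all__ = [
    "PotentialField",
    "CenterlineProfile",
    "CurrentResult",
    "solve_potential",
    "scale_to_voltage",
    "centerline_profile",
    "homogeneity_metrics",
    "electrode_current_per_depth",
    "total_current",
    "analytic_plate_field",
    "convergence_study",
]

log = logging.getLogger(__name__)

#: acceptable relative imbalance between the two electrode flux integrals
FLUX_BALANCE_TOL = 0.01


@dataclass
class PotentialField:
    """FEM solution: nodal potential and per-triangle field.

    ``phi`` has one value per mesh node (V); ``efield`` is (m, 2) with the
    constant gradient-based field per triangle (V/m);
    ``voltage_difference`` is the applied electrode voltage difference.
    """

    mesh: Mesh2D
    phi: np.ndarray
    efield: np.ndarray
    voltage_difference: float
    _stiffness: sp.csr_matrix = dataclass_field(repr=False, default=None)

    def field_magnitude(self) -> np.ndarray:
        """|E| per triangle (V/m)."""
        return np.hypot(self.efield[:, 0], self.efield[:, 1])

    def nodal_efield(self) -> np.ndarray:
        """Area-weighted nodal average of the per-triangle field, (n, 2)."""
        mesh = self.mesh
        areas = mesh.triangle_areas()
        acc = np.zeros((mesh.n_points, 2))
        weight = np.zeros(mesh.n_points)
        flat = mesh.triangles.ravel()
        for k in range(2):
            np.add.at(acc[:, k], flat, np.repeat(self.efield[:, k] * areas, 3))
        np.add.at(weight, flat, np.repeat(areas, 3))
        return acc / weight[:, None]

    def efield_at(self, x, y) -> np.ndarray:
        """Linearly interpolated field vectors at query points, (k, 2).

        Uses the nodal-averaged field, so point queries landing on nodes
        return the area-weighted average of the adjacent elements.
        """
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        nodal = self.nodal_efield()
        tri = mtri.Triangulation(
            self.mesh.points[:, 0], self.mesh.points[:, 1], self.mesh.triangles
        )
        ex = mtri.LinearTriInterpolator(tri, nodal[:, 0])(x, y)
        ey = mtri.LinearTriInterpolator(tri, nodal[:, 1])(x, y)
        out = np.stack([np.ma.filled(ex, np.nan), np.ma.filled(ey, np.nan)], axis=1)
        return out


@dataclass(frozen=True)
class CenterlineProfile:
    """|E| sampled along the electrode-to-electrode axis through the center.

    ``positions`` are x-coordinates (m, origin at the well center,
    strictly increasing from electrode B to electrode A face);
    ``magnitudes`` are |E| (V/m).
    """

    positions: np.ndarray
    magnitudes: np.ndarray

    @property
    def midpoint_field(self) -> float:
        """|E| at the geometric midpoint between the electrode faces."""
        mid = 0.5 * (self.positions[0] + self.positions[-1])
        return float(np.interp(mid, self.positions, self.magnitudes))

    @property
    def face_fields(self) -> tuple[float, float]:
        """|E| at the two electrode faces (profile endpoints)."""
        return float(self.magnitudes[0]), float(self.magnitudes[-1])


@dataclass(frozen=True)
class CurrentResult:
    """Per-depth electrode current of the 2D model.

    ``current_per_depth`` is the flux integral sigma * ∮ E.n dl over one
    electrode (A/m); ``conductivity`` the sigma it was evaluated at.
    ``electrode_currents`` holds the signed per-electrode values (source
    positive, sink negative) whose sum is the charge-conservation defect.
    ``fill_level`` / ``total_current`` are populated by
    :func:`total_current`.
    """

    current_per_depth: float
    conductivity: float
    electrode_currents: tuple[float, float]
    fill_level: float | None = None
    total_current: float | None = None

    @property
    def flux_imbalance(self) -> float:
        """|I_A + I_B| relative to the larger electrode magnitude."""
        ia, ib = self.electrode_currents
        return abs(ia + ib) / max(abs(ia), abs(ib))


# ---------------------------------------------------------------------------
# assembly and solve


def _assemble_stiffness(mesh: Mesh2D):
    """Standard P1 stiffness matrix plus the shape-gradient tables."""
    pts = mesh.points
    tri = mesh.triangles
    x = pts[tri, 0]
    y = pts[tri, 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    ke = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (
        4.0 * area[:, None, None]
    )
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_points, mesh.n_points)
    ).tocsr()
    return K, area, b, c


def solve_potential(mesh: Mesh2D, voltage_difference: float) -> PotentialField:
    """Solve Laplace's equation with electrodes at +-V/2.

    Direct sparse factorization; deterministic for a given mesh.  Raises
    :class:`ConfigurationError` when either electrode tag is empty (the
    system would be singular) and verifies the discrete maximum principle
    on every solve.
    """
    if not np.isfinite(voltage_difference):
        raise ConfigurationError("voltage_difference must be finite")
    node_a = mesh.boundary_nodes(ELECTRODE_A)
    node_b = mesh.boundary_nodes(ELECTRODE_B)
    if len(node_a) == 0 or len(node_b) == 0:
        raise ConfigurationError(
            "mesh lacks an electrode boundary tag; Dirichlet data incomplete"
        )
    K, area, b, c = _assemble_stiffness(mesh)
    n = mesh.n_points
    phi = np.zeros(n)
    phi[node_a] = +voltage_difference / 2
    phi[node_b] = -voltage_difference / 2
    fixed = np.concatenate([node_a, node_b])
    free = np.setdiff1d(np.arange(n), fixed)
    if len(free):
        rhs = -K[free][:, fixed] @ phi[fixed]
        phi[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)

    tol = 1e-9 * max(1.0, abs(voltage_difference))
    lo, hi = min(phi[fixed], default=0.0), max(phi[fixed], default=0.0)
    if phi.min() < lo - tol or phi.max() > hi + tol:
        raise ConfigurationError(
            "discrete maximum principle violated; mesh or assembly is broken"
        )

    grad_x = (b * phi[mesh.triangles]).sum(axis=1) / (2.0 * area)
    grad_y = (c * phi[mesh.triangles]).sum(axis=1) / (2.0 * area)
    efield = np.stack([-grad_x, -grad_y], axis=1)
    return PotentialField(
        mesh=mesh,
        phi=phi,
        efield=efield,
        voltage_difference=float(voltage_difference),
        _stiffness=K,
    )


def scale_to_voltage(field: PotentialField, new_voltage: float) -> PotentialField:
    """Rescale a solved field to a different applied voltage (no re-solve).

    Valid because the boundary-value problem is linear in V.
    """
    if field.voltage_difference == 0:
        raise InvalidScaleError("cannot rescale a 0 V solution")
    s = new_voltage / field.voltage_difference
    return PotentialField(
        mesh=field.mesh,
        phi=field.phi * s,
        efield=field.efield * s,
        voltage_difference=float(new_voltage),
        _stiffness=field._stiffness,
    )


# ---------------------------------------------------------------------------
# post-processing


def _electrode_inner_faces(mesh: Mesh2D) -> tuple[float, float]:
    """x-coordinates of the two electrode faces bounding the gap."""
    xa = mesh.points[mesh.boundary_nodes(ELECTRODE_A), 0]
    xb = mesh.points[mesh.boundary_nodes(ELECTRODE_B), 0]
    return float(xb.max()), float(xa.min())


def centerline_profile(field: PotentialField, n_samples: int) -> CenterlineProfile:
    """|E| at equally spaced points between the electrode face midpoints.

    Endpoints are evaluated exactly at the electrode faces.  An odd
    ``n_samples`` places a sample on the geometric midpoint.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be at least 3")
    x_lo, x_hi = _electrode_inner_faces(field.mesh)
    xs = np.linspace(x_lo, x_hi, n_samples)
    vec = field.efield_at(xs, np.zeros_like(xs))
    mags = np.hypot(vec[:, 0], vec[:, 1])
    return CenterlineProfile(positions=xs, magnitudes=mags)


def homogeneity_metrics(
    field: PotentialField, band_low: float, band_high: float
) -> float:
    """Area fraction of the liquid cross-section with |E| inside a band."""
    if not band_low < band_high:
        raise ValueError("band_low must be smaller than band_high")
    areas = field.mesh.triangle_areas()
    mags = field.field_magnitude()
    in_band = (mags >= band_low) & (mags <= band_high)
    return float(areas[in_band].sum() / areas.sum())


def electrode_current_per_depth(
    field: PotentialField, conductivity: float
) -> CurrentResult:
    """Per-depth current sigma * ∮ E.n dl over one electrode (A/m).

    Evaluated with the consistent residual flux on both electrodes; the
    reported value is the source electrode's, and a charge-conservation
    warning is logged when the two magnitudes disagree beyond
    :data:`FLUX_BALANCE_TOL`.
    """
    if conductivity <= 0:
        raise InvalidGeometryError("conductivity must be positive")
    K = field._stiffness
    if K is None:
        K, *_ = _assemble_stiffness(field.mesh)
    residual = K @ field.phi
    i_a = conductivity * residual[field.mesh.boundary_nodes(ELECTRODE_A)].sum()
    i_b = conductivity * residual[field.mesh.boundary_nodes(ELECTRODE_B)].sum()
    result = CurrentResult(
        current_per_depth=float(abs(i_a)),
        conductivity=float(conductivity),
        electrode_currents=(float(i_a), float(i_b)),
    )
    if field.voltage_difference != 0 and result.flux_imbalance > FLUX_BALANCE_TOL:
        log.warning(
            "electrode flux imbalance %.2f%% exceeds %.0f%%",
            100 * result.flux_imbalance,
            100 * FLUX_BALANCE_TOL,
        )
    return result


def total_current(
    result: CurrentResult, fill_level: float, conductivity: float
) -> float:
    """Total electrode current (A): I = I_2D * h, rescaled to ``conductivity``.

    The 2D solve is conductivity-linear, so the per-depth current computed
    at sigma_solve rescales by sigma / sigma_solve.
    """
    if fill_level <= 0:
        raise InvalidGeometryError("fill_level must be positive")
    return (
        result.current_per_depth
        * fill_level
        * (conductivity / result.conductivity)
    )


def analytic_plate_field(voltage_difference: float, gap: float) -> float:
    """Infinite parallel-plate estimate E = V / d (V/m)."""
    if gap <= 0:
        raise InvalidGeometryError("electrode gap must be positive")
    return voltage_difference / gap


def convergence_study(
    geometry: ChamberGeometry2D,
    voltage: float,
    edge_lengths: list[float],
) -> pd.DataFrame:
    """Midpoint |E| and per-depth current across mesh refinements.

    ``edge_lengths`` must be strictly decreasing with at least two
    entries.  Returns one row per refinement with columns ``edge_length``,
    ``n_triangles``, ``midpoint_field`` and ``current_per_depth`` (at
    sigma = 1 S/m).
    """
    lengths = [float(h) for h in edge_lengths]
    if len(lengths) < 2 or any(
        b >= a for a, b in zip(lengths, lengths[1:])
    ):
        raise ValueError("edge_lengths must be >=2 values, strictly decreasing")
    rows = []
    for h in lengths:
        mesh = generate_mesh(geometry, h)
        field = solve_potential(mesh, voltage)
        profile = centerline_profile(field, 201)
        current = electrode_current_per_depth(field, 1.0)
        rows.append(
            {
                "edge_length": h,
                "n_triangles": mesh.n_triangles,
                "midpoint_field": profile.midpoint_field,
                "current_per_depth": current.current_per_depth,
            }
        )
    return pd.DataFrame(rows)
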