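"""Triangular meshing of the 2D liquid cross-section.

The solve domain is the well disc minus the two electrode rectangles.
Points are placed deterministically — boundary walks at a graded local
edge length plus multi-level hexagonal interior lattices — and
triangulated with Delaunay; triangles outside the liquid are discarded by
a centroid test.  The local edge length shrinks to a quarter of the
target near the four electrode corners, where the field has a reentrant
corner singularity.

Boundary edge tags:

``electrode_a``  rectangle boundary of the electrode at positive x
``electrode_b``  rectangle boundary of the electrode at negative x
``wall``         the insulating well wall (circle)

Coordinate convention: origin at the well center, x-axis along the
electrode-to-electrode line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .errors import InvalidGeometryError
from .geometry import ChamberGeometry2D

__all__ = ["Mesh2D", "generate_mesh", "rectangle_mesh"]

ELECTRODE_A = "electrode_a"
ELECTRODE_B = "electrode_b"
WALL = "wall"

#: refinement factor of the local edge length at electrode corners
CORNER_REFINEMENT = 4
#: growth rate of the local edge length with distance from a corner
_GRADING_SLOPE = 0.5


@dataclass
class Mesh2D:
    """Conforming triangulation with tagged boundary edges.

    ``points`` is (n, 2) float64 in meters, ``triangles`` (m, 3) int
    node triples (positively oriented), ``boundary_edges`` maps each tag
    to a (k, 2) int array of node pairs.
    """

    points: np.ndarray
    triangles: np.ndarray
    boundary_edges: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def boundary_nodes(self, tag: str) -> np.ndarray:
        """Sorted unique node indices on the boundary edges of ``tag``."""
        edges = self.boundary_edges.get(tag)
        if edges is None or len(edges) == 0:
            return np.empty(0, dtype=int)
        return np.unique(edges)

    def triangle_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def validate(self) -> None:
        """Raise if a structural invariant is violated."""
        if np.any(self.triangle_areas() <= 0):
            raise InvalidGeometryError("mesh contains non-positive triangle")
        referenced = np.unique(self.triangles)
        if len(referenced) != self.n_points:
            raise InvalidGeometryError("mesh contains unreferenced nodes")
        # each topological boundary edge carries exactly one tag
        topo = _boundary_edges(self.triangles)
        topo_set = {tuple(e) for e in np.sort(topo, axis=1)}
        tagged: list[tuple[int, int]] = []
        for edges in self.boundary_edges.values():
            tagged.extend(tuple(e) for e in np.sort(edges, axis=1))
        if len(tagged) != len(set(tagged)) or set(tagged) != topo_set:
            raise InvalidGeometryError("boundary tags do not partition the boundary")


# ---------------------------------------------------------------------------
# point placement


def _corners(geometry: ChamberGeometry2D) -> np.ndarray:
    g2 = geometry.electrode_gap / 2
    t = geometry.electrode_thickness
    w2 = geometry.electrode_width / 2
    return np.array(
        [[sx * x, sy * w2] for sx in (1.0, -1.0) for x in (g2, g2 + t)
         for sy in (1.0, -1.0)]
    )


def _local_size(points: np.ndarray, corners: np.ndarray, h: float) -> np.ndarray:
    d = np.sqrt(((points[:, None, :] - corners[None, :, :]) ** 2).sum(-1)).min(1)
    return np.minimum(h, h / CORNER_REFINEMENT + _GRADING_SLOPE * d)


def _walk_segment(p0, p1, corners, h) -> np.ndarray:
    """Points along a segment at the graded local spacing, excluding p1."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0))
    pts = [p0]
    t = 0.0
    while True:
        s = _local_size(pts[-1][None, :], corners, h)[0]
        if t + s >= length - 0.3 * s:
            break
        t += s
        pts.append(p0 + (p1 - p0) * t / length)
    # grade the closing gap against the local size at the far endpoint,
    # so edges arriving at a refined corner are as short as those leaving
    gap = length - t
    s_end = _local_size(p1[None, :], corners, h)[0]
    k = int(np.ceil(gap / s_end - 0.25))
    for j in range(1, k):
        pts.append(p0 + (p1 - p0) * (t + gap * j / k) / length)
    return np.array(pts)


def _circle_points(radius: float, corners: np.ndarray, h: float) -> np.ndarray:
    pts = []
    ang = 0.0
    while ang < 2 * np.pi:
        p = radius * np.array([np.cos(ang), np.sin(ang)])
        pts.append(p)
        ang += _local_size(p[None, :], corners, h)[0] / radius
    return np.array(pts)


def _rectangle_points(x0, x1, y0, y1, corners, h) -> np.ndarray:
    loop = [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]
    parts = [_walk_segment(loop[i], loop[i + 1], corners, h) for i in range(4)]
    return np.vstack(parts)


def _interior_points(geometry: ChamberGeometry2D, corners, h) -> np.ndarray:
    """Multi-level hexagonal lattices matched to the local size field."""
    radius = geometry.well_radius
    levels = [h / 2**k for k in range(_n_levels())]
    chunks = []
    for k, s in enumerate(levels):
        dy = s * np.sqrt(3) / 2
        ny = int(2 * radius / dy) + 2
        nx = int(2 * radius / s) + 2
        rows = []
        for j in range(ny):
            y = (j - ny / 2) * dy
            xs = (np.arange(nx) - nx / 2) * s + (j % 2) * s / 2
            rows.append(np.stack([xs, np.full_like(xs, y)], axis=1))
        lattice = np.vstack(rows)
        size = _local_size(lattice, corners, h)
        lo = s * 0.71
        hi = levels[k - 1] * 0.71 if k > 0 else np.inf
        chunks.append(lattice[(size > lo) & (size <= hi)])
    pts = np.vstack(chunks)
    size = _local_size(pts, corners, h)
    r = np.hypot(pts[:, 0], pts[:, 1])
    inside = r < radius - 0.5 * size
    g2 = geometry.electrode_gap / 2
    outer = g2 + geometry.electrode_thickness
    w2 = geometry.electrode_width / 2
    near_rect = (
        (np.abs(pts[:, 0]) > g2 - 0.5 * size)
        & (np.abs(pts[:, 0]) < outer + 0.5 * size)
        & (np.abs(pts[:, 1]) < w2 + 0.5 * size)
    )
    return pts[inside & ~near_rect]


def _n_levels() -> int:
    return int(np.log2(CORNER_REFINEMENT)) + 1


# ---------------------------------------------------------------------------
# triangulation


def _boundary_edges(triangles: np.ndarray) -> np.ndarray:
    edges = np.vstack(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    sorted_edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(sorted_edges, axis=0, return_counts=True)
    return uniq[counts == 1]


def _in_liquid(points: np.ndarray, geometry: ChamberGeometry2D) -> np.ndarray:
    r = np.hypot(points[:, 0], points[:, 1])
    g2 = geometry.electrode_gap / 2
    outer = g2 + geometry.electrode_thickness
    w2 = geometry.electrode_width / 2
    in_rect = (
        (np.abs(points[:, 0]) >= g2)
        & (np.abs(points[:, 0]) <= outer)
        & (np.abs(points[:, 1]) <= w2)
    )
    return (r < geometry.well_radius) & ~in_rect


def generate_mesh(
    geometry: ChamberGeometry2D, target_edge_length: float
) -> Mesh2D:
    """Triangulate the liquid cross-section of ``geometry``.

    The triangulation conforms to the well circle and both electrode
    rectangles, with edges a factor :data:`CORNER_REFINEMENT` shorter near
    the electrode corners.  Deterministic: identical inputs give the
    identical mesh.
    """
    if target_edge_length <= 0:
        raise InvalidGeometryError("target_edge_length must be positive")
    corners = _corners(geometry)
    if np.any(np.hypot(corners[:, 0], corners[:, 1]) >= geometry.well_radius):
        raise InvalidGeometryError("electrodes overlap the well boundary")

    h = float(target_edge_length)
    g2 = geometry.electrode_gap / 2
    outer = g2 + geometry.electrode_thickness
    w2 = geometry.electrode_width / 2

    boundary = [_circle_points(geometry.well_radius, corners, h)]
    boundary.append(_rectangle_points(g2, outer, -w2, w2, corners, h))
    boundary.append(_rectangle_points(-outer, -g2, -w2, w2, corners, h))
    bpts = np.vstack(boundary)

    ipts = _interior_points(geometry, corners, h)
    if len(ipts):
        dist, _ = cKDTree(bpts).query(ipts)
        ipts = ipts[dist > 0.55 * _local_size(ipts, corners, h)]
    points = np.vstack([bpts, ipts]) if len(ipts) else bpts

    tri = Delaunay(points)
    triangles = tri.simplices
    centroids = points[triangles].mean(axis=1)
    triangles = triangles[_in_liquid(centroids, geometry)]

    # enforce positive orientation
    p = points[triangles]
    signed = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0])
    )
    flip = signed < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]

    # drop nodes not referenced by any kept triangle
    used, inverse = np.unique(triangles, return_inverse=True)
    points = points[used]
    triangles = inverse.reshape(triangles.shape)

    edges = _boundary_edges(triangles)
    mids = points[edges].mean(axis=1)
    tol = 1e-9
    on_rect = (
        (np.abs(mids[:, 0]) >= g2 - tol)
        & (np.abs(mids[:, 0]) <= outer + tol)
        & (np.abs(mids[:, 1]) <= w2 + tol)
    )
    tags = {
        ELECTRODE_A: edges[on_rect & (mids[:, 0] > 0)],
        ELECTRODE_B: edges[on_rect & (mids[:, 0] < 0)],
        WALL: edges[~on_rect],
    }
    mesh = Mesh2D(points=points, triangles=triangles, boundary_edges=tags)
    mesh.validate()
    return mesh


def rectangle_mesh(
    width: float, height: float, nx: int, ny: int
) -> Mesh2D:
    """Structured mesh of a rectangle with full-height electrodes.

    The side at ``x = width`` is tagged ``electrode_a``, the side at
    ``x = 0`` is ``electrode_b``; top and bottom are insulating ``wall``.
    The exact parallel-plate solution (a linear potential ramp) lies in
    the P1 space on this mesh, making it the closed-form verification
    domain for the solver.
    """
    if width <= 0 or height <= 0 or nx < 1 or ny < 1:
        raise InvalidGeometryError("rectangle_mesh needs positive dimensions")
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel()], axis=1)

    def node(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = node(i, j), node(i + 1, j)
            c, d = node(i + 1, j + 1), node(i, j + 1)
            tris.append([a, b, c])
            tris.append([a, c, d])
    triangles = np.array(tris, dtype=int)

    left = [[node(0, j), node(0, j + 1)] for j in range(ny)]
    right = [[node(nx, j), node(nx, j + 1)] for j in range(ny)]
    bottom = [[node(i, 0), node(i + 1, 0)] for i in range(nx)]
    top = [[node(i, ny), node(i + 1, ny)] for i in range(nx)]
    tags = {
        ELECTRODE_A: np.array(right, dtype=int),
        ELECTRODE_B: np.array(left, dtype=int),
        WALL: np.array(bottom + top, dtype=int),
    }
    mesh = Mesh2D(points=points, triangles=triangles, boundary_edges=tags)
    mesh.validate()
    return mesh
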