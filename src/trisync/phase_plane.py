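"""Simplex phase-plane embedding and occupancy densities.

Because the three interior angles always sum to pi, an angle triple is a
point of a 2-simplex and can be drawn inside an equilateral triangle:
vertex i is the degenerate state ``theta_i = pi`` and the centre is the
symmetric state ``theta_i = pi/3`` for all i.  Pattern classes become
geometric attractors on this plane — a circle about the centre for
rotation, a line parallel to one edge for partial anti-phase, a median
line for partial in-phase — which is what makes the embedding useful:
occupancy density on the plane summarizes which attractor dominates a
trial or a group without any model fitting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ANGLE_SUM, AngleSeries
from .synthetic import PatternSpec, generate

#: Fixed vertex convention: V1 at the origin, V2 on the x-axis, unit side.
VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])
CENTROID = VERTICES.mean(axis=0)
#: Height of the triangle; distance from a vertex to the opposite edge.
HEIGHT = np.sqrt(3.0) / 2.0


@dataclass
class SimplexTrajectory:
    """2-D trajectory of embedded angle triples.

    ``points[k] = (theta1*V1 + theta2*V2 + theta3*V3) / pi`` — barycentric
    coordinates ``theta_i / pi`` against :data:`VERTICES`.
    """

    points: np.ndarray
    valid: np.ndarray
    rate: float | None = None
    t0: float = 0.0
    renormalized: bool = False

    @property
    def valid_points(self) -> np.ndarray:
        return self.points[self.valid]


@dataclass
class TemplateGeometry:
    """Ideal attractor geometry of a pattern class on the phase plane."""

    kind: str  # "circle" | "edge_parallel" | "median" | "point"
    anchor: np.ndarray  # circle centre / a point on the line / the point
    radius: float | None = None
    direction: np.ndarray | None = None  # unit vector along a line geometry


@dataclass
class DensityGrid:
    """Occupancy histogram on the phase plane, min–max normalized.

    ``normalized = (counts - min) / (max - min)`` over in-triangle bins;
    a flat field maps to all zeros by convention.
    """

    counts: np.ndarray
    normalized: np.ndarray
    in_triangle: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def bins(self) -> int:
        return self.counts.shape[0]


def embed(series: AngleSeries, sum_tol: float = 1e-6) -> SimplexTrajectory:
    """Map an angle series onto the equilateral-triangle phase plane.

    Triples whose sum drifts from pi by more than ``sum_tol`` (possible
    after filtering real data) are renormalized by their actual sum and
    the trajectory is flagged; negative angles are an error.
    """
    theta = series.theta.copy()
    valid = series.valid.copy()
    if np.any(theta[valid] < 0):
        raise ValueError("angles must be non-negative")
    sums = theta[valid].sum(axis=1)
    renorm = False
    if sums.size and np.max(np.abs(sums - ANGLE_SUM)) > sum_tol:
        renorm = True
        theta[valid] = ANGLE_SUM * theta[valid] / sums[:, None]
    points = theta @ VERTICES / ANGLE_SUM
    return SimplexTrajectory(
        points=points, valid=valid, rate=series.rate, t0=series.t0, renormalized=renorm
    )


def template_trajectory(
    spec: PatternSpec,
) -> tuple[SimplexTrajectory, TemplateGeometry | None]:
    """Ideal noise-free trajectory of a pattern class plus its geometry.

    Rotation maps to a circle about the centre of radius
    ``(sqrt(3)/2) * A / pi`` (the embedding is affine, so the common
    amplitude A sets the radius); partial anti-phase to a segment
    parallel to the edge opposite the dead vertex at height proportional
    to the dead value; partial in-phase to a segment of the median
    through the anti-phase vertex; the all-in-phase state to the centre
    point.  The fully asymmetric class has no attractor geometry.
    """
    traj = embed(generate(spec))
    label = spec.label
    if label == "R":
        geometry = TemplateGeometry(
            kind="circle",
            anchor=CENTROID.copy(),
            radius=(np.sqrt(3.0) / 2.0) * spec.amplitude / ANGLE_SUM,
        )
    elif label in ("PA1", "PA2"):
        dead = spec.special_channel - 1
        others = [i for i in range(3) if i != dead]
        edge = VERTICES[others[1]] - VERTICES[others[0]]
        direction = edge / np.linalg.norm(edge)
        # midpoint of the segment: dead channel at its value, pair at rest
        mid = np.full(3, (ANGLE_SUM - spec.base) / 2.0)
        mid[dead] = spec.base
        geometry = TemplateGeometry(
            kind="edge_parallel",
            anchor=mid @ VERTICES / ANGLE_SUM,
            direction=direction,
        )
    elif label in ("PI1", "PI2"):
        anti = spec.special_channel - 1
        direction = CENTROID - VERTICES[anti]
        direction = direction / np.linalg.norm(direction)
        geometry = TemplateGeometry(
            kind="median", anchor=VERTICES[anti].copy(), direction=direction
        )
    elif label == "ALL_IN":
        geometry = TemplateGeometry(kind="point", anchor=CENTROID.copy())
    else:  # ASYM: trajectory only
        geometry = None
    return traj, geometry


def point_in_triangle(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Vectorized membership test against the fixed triangle."""
    points = np.atleast_2d(points)
    # barycentric coordinates w.r.t. VERTICES
    t = np.linalg.solve(
        np.vstack([(VERTICES[1] - VERTICES[0]), (VERTICES[2] - VERTICES[0])]).T,
        (points - VERTICES[0]).T,
    ).T
    l1, l2 = t[:, 0], t[:, 1]
    l0 = 1.0 - l1 - l2
    return (l0 >= -tol) & (l1 >= -tol) & (l2 >= -tol)


def occupancy_density(
    trajectories: list[SimplexTrajectory] | SimplexTrajectory, bins: int = 60
) -> DensityGrid:
    """Pooled occupancy histogram over the phase plane.

    Valid samples of all trajectories are concatenated (pooling trials of
    one group), binned on a ``bins x bins`` grid covering the triangle's
    bounding box, and min–max normalized over in-triangle bins.
    """
    if isinstance(trajectories, SimplexTrajectory):
        trajectories = [trajectories]
    pts = [t.valid_points for t in trajectories]
    pts = np.concatenate(pts, axis=0) if pts else np.empty((0, 2))
    if len(pts) == 0:
        raise ValueError("no valid samples to bin")
    x = np.clip(pts[:, 0], 0.0, 1.0)
    y = np.clip(pts[:, 1], 0.0, HEIGHT)
    counts, x_edges, y_edges = np.histogram2d(
        x, y, bins=bins, range=[[0.0, 1.0], [0.0, HEIGHT]]
    )
    in_tri = _bin_in_triangle(x_edges, y_edges)
    h = counts[in_tri]
    normalized = np.zeros_like(counts)
    if h.max() > h.min():
        normalized[in_tri] = (counts[in_tri] - h.min()) / (h.max() - h.min())
    return DensityGrid(
        counts=counts,
        normalized=normalized,
        in_triangle=in_tri,
        x_edges=x_edges,
        y_edges=y_edges,
    )


def _bin_in_triangle(x_edges: np.ndarray, y_edges: np.ndarray) -> np.ndarray:
    """A bin counts as inside if its centre or any corner is inside."""
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    inside = np.zeros((nx, ny), dtype=bool)
    probes_x = [xc, x_edges[:-1], x_edges[1:]]
    probes_y = [yc, y_edges[:-1], y_edges[1:]]
    for px in probes_x:
        for py in probes_y:
            gx, gy = np.meshgrid(px, py, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            inside |= point_in_triangle(pts).reshape(nx, ny)
    return inside
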