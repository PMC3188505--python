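"""Track preprocessing: 2-D DLT reconstruction, filtering, angle extraction.

The measurement chain for a real recording is: digitize the three
attackers' head centres in image coordinates (pixels) at 30 Hz, map to
world coordinates (metres) with an eight-parameter 2-D direct linear
transformation fitted to surveyed control points, low-pass the tracks
with a second-order Butterworth filter (1.0 Hz on x, 0.5 Hz on y), and
compute the triangle's interior angles frame by frame.  Frames during
defender interception are excluded, and all downstream analysis operates
on the remaining contiguous valid segments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import AngleSeries, TrackSet


@dataclass
class ControlPointSet:
    """Paired image (pixels) and world (metres) calibration points."""

    image: np.ndarray  # (n, 2) u, v
    world: np.ndarray  # (n, 2) x, y

    def __post_init__(self) -> None:
        self.image = np.atleast_2d(np.asarray(self.image, dtype=float))
        self.world = np.atleast_2d(np.asarray(self.world, dtype=float))
        if self.image.shape != self.world.shape or self.image.shape[1] != 2:
            raise ValueError("image and world must both have shape (n, 2)")
        if len(self.image) < 4:
            raise ValueError("at least 4 control points are required")
        if len(np.unique(self.world.round(12), axis=0)) != len(self.world):
            raise ValueError("duplicate world control points")
        for pts, name in ((self.image, "image"), (self.world, "world")):
            centered = pts - pts.mean(axis=0)
            if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
                raise ValueError(f"{name} control points are collinear")


@dataclass
class Homography2D:
    """Eight-coefficient plane-to-plane projective map (2-D DLT).

    ``x = (L1*u + L2*v + L3) / (L7*u + L8*v + 1)`` and analogously for y
    with L4..L6.
    """

    coeffs: np.ndarray  # (8,) L1..L8

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float).reshape(8)


@dataclass
class FilterSpec:
    """Low-pass configuration for track smoothing.

    Cutoffs follow the convention of filtering the two world axes with
    different bandwidths; ``zero_phase`` selects forward–backward
    filtering (no phase lag, squared magnitude response).
    """

    order: int = 2
    cutoff_x: float = 1.0
    cutoff_y: float = 0.5
    zero_phase: bool = True


def fit_dlt(points: ControlPointSet) -> Homography2D:
    """Least-squares 2-D DLT calibration from control points.

    Solves the standard linearized system: each point contributes
    ``L1*u + L2*v + L3 - x*(L7*u + L8*v) = x`` and the matching row
    for y, stacked over all pairs and solved by linear least squares.
    """
    u, v = points.image[:, 0], points.image[:, 1]
    x, y = points.world[:, 0], points.world[:, 1]
    n = len(u)
    a = np.zeros((2 * n, 8))
    b = np.empty(2 * n)
    a[0::2, 0], a[0::2, 1], a[0::2, 2] = u, v, 1.0
    a[0::2, 6], a[0::2, 7] = -x * u, -x * v
    a[1::2, 3], a[1::2, 4], a[1::2, 5] = u, v, 1.0
    a[1::2, 6], a[1::2, 7] = -y * u, -y * v
    b[0::2], b[1::2] = x, y
    coeffs, *_ = np.linalg.lstsq(a, b, rcond=None)
    return Homography2D(coeffs)


def map_to_world(h: Homography2D, image_points: np.ndarray) -> np.ndarray:
    """Apply the calibrated rational map to image points (any leading shape)."""
    pts = np.asarray(image_points, dtype=float)
    flat = pts.reshape(-1, 2)
    l = h.coeffs
    den = l[6] * flat[:, 0] + l[7] * flat[:, 1] + 1.0
    if np.any(np.abs(den) < 1e-12):
        raise ValueError("degenerate point: projective denominator vanishes")
    out = np.empty_like(flat)
    out[:, 0] = (l[0] * flat[:, 0] + l[1] * flat[:, 1] + l[2]) / den
    out[:, 1] = (l[3] * flat[:, 0] + l[4] * flat[:, 1] + l[5]) / den
    return out.reshape(pts.shape)


def reconstruction_error(
    h: Homography2D, points: ControlPointSet
) -> tuple[float, float]:
    """Per-axis mean absolute error (m) reconstructing the control points."""
    pred = map_to_world(h, points.image)
    err = np.abs(pred - points.world).mean(axis=0)
    return float(err[0]), float(err[1])


def lowpass(tracks: TrackSet, spec: FilterSpec | None = None) -> TrackSet:
    """Low-pass filter player tracks per axis and per possession segment.

    Filtering restarts on each contiguous possession run so no transient
    leaks across excluded (interception) gaps; runs too short for the
    filter's edge padding are flagged invalid rather than filtered.  The
    possession mask itself is never modified.
    """
    spec = spec or FilterSpec()
    nyq = tracks.rate / 2.0
    if not (0 < spec.cutoff_x < nyq and 0 < spec.cutoff_y < nyq):
        raise ValueError("cutoffs must lie in (0, rate/2)")
    ba_x = signal.butter(spec.order, spec.cutoff_x, fs=tracks.rate)
    ba_y = signal.butter(spec.order, spec.cutoff_y, fs=tracks.rate)
    pad = 3 * max(len(ba_x[0]), len(ba_x[1]))  # filtfilt default padlen
    positions = tracks.positions.copy()
    valid = tracks.valid.copy()
    for i0, i1 in tracks.possession_runs():
        if spec.zero_phase and (i1 - i0) <= pad:
            valid[i0:i1] = False
            continue
        for player in range(3):
            for axis, (b, a) in enumerate((ba_x, ba_y)):
                seg = positions[i0:i1, player, axis]
                if spec.zero_phase:
                    positions[i0:i1, player, axis] = signal.filtfilt(b, a, seg)
                else:
                    positions[i0:i1, player, axis] = signal.lfilter(b, a, seg)
    return replace(tracks, positions=positions, valid=valid)


def extract_angles(tracks: TrackSet, collinear_tol: float = 1e-6) -> AngleSeries:
    """Interior angles of the attacker triangle, frame by frame.

    The angle at attacker i is the absolute angle between the two edge
    vectors to the other attackers, via the four-quadrant arctangent.
    Frames without possession, non-finite coordinates, or a near-collinear
    triple (smallest angle below ``collinear_tol`` rad) are marked invalid
    rather than raising.
    """
    pos = tracks.positions
    n = len(pos)
    theta = np.full((n, 3), np.nan)
    finite = np.isfinite(pos).all(axis=(1, 2))
    idx = np.flatnonzero(finite)
    for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        u = pos[idx, j] - pos[idx, i]
        w = pos[idx, k] - pos[idx, i]
        cross = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
        dot = (u * w).sum(axis=1)
        theta[idx, i] = np.abs(np.arctan2(cross, dot))
    valid = tracks.valid & finite
    with np.errstate(invalid="ignore"):
        degenerate = np.nanmin(theta, axis=1) < collinear_tol
    valid &= ~degenerate
    return AngleSeries(rate=tracks.rate, theta=theta, valid=valid, t0=tracks.t0)


def apply_exclusion(
    series: AngleSeries,
    min_duration: float | None = None,
    f_min: float = 0.2,
) -> list[AngleSeries]:
    """Split a masked series into analyzable contiguous valid segments.

    Segments shorter than ``min_duration`` (default two periods of the
    slowest expected oscillation, ``2 / f_min``) carry too few cycles for
    peak-based phase estimation and are dropped.
    """
    if min_duration is None:
        min_duration = 2.0 / f_min
    segments = [
        series.segment(i0, i1)
        for i0, i1 in series.valid_runs()
        if (i1 - i0) / series.rate >= min_duration
    ]
    if not segments:
        warnings.warn("no valid segments remain after exclusion", stacklevel=2)
    return segments
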