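"""Plain-text (CSV/JSON) readers and writers for the pipeline's artifacts."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import AngleSeries, TrackSet
from .phase_plane import DensityGrid
from .preprocess import ControlPointSet

ANGLE_COLUMNS = ["time_s", "theta1_rad", "theta2_rad", "theta3_rad", "valid"]
TRACK_COLUMNS = [
    "frame",
    "time_s",
    "a1_x",
    "a1_y",
    "a2_x",
    "a2_y",
    "a3_x",
    "a3_y",
    "possession",
]


def write_angles_csv(path: str | Path, series: AngleSeries) -> None:
    df = pd.DataFrame(
        {
            "time_s": series.times,
            "theta1_rad": series.theta[:, 0],
            "theta2_rad": series.theta[:, 1],
            "theta3_rad": series.theta[:, 2],
            "valid": series.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_angles_csv(path: str | Path) -> AngleSeries:
    df = pd.read_csv(path)
    missing = set(ANGLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"angle CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("angle CSV needs at least two samples")
    steps = np.diff(t)
    rate = 1.0 / np.median(steps)
    theta = df[["theta1_rad", "theta2_rad", "theta3_rad"]].to_numpy(dtype=float)
    valid = df["valid"].to_numpy().astype(bool)
    return AngleSeries(rate=rate, theta=theta, valid=valid, t0=float(t[0]))


def write_tracks_csv(path: str | Path, tracks: TrackSet) -> None:
    pos = tracks.positions
    df = pd.DataFrame(
        {
            "frame": np.arange(tracks.n_frames),
            "time_s": tracks.times,
            "a1_x": pos[:, 0, 0],
            "a1_y": pos[:, 0, 1],
            "a2_x": pos[:, 1, 0],
            "a2_y": pos[:, 1, 1],
            "a3_x": pos[:, 2, 0],
            "a3_y": pos[:, 2, 1],
            "possession": tracks.possession.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_tracks_csv(path: str | Path, rate: float | None = None) -> TrackSet:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if rate is None:
        if len(t) < 2:
            raise ValueError("track CSV needs at least two frames to infer the rate")
        rate = 1.0 / np.median(np.diff(t))
    positions = np.stack(
        [
            df[["a1_x", "a1_y"]].to_numpy(dtype=float),
            df[["a2_x", "a2_y"]].to_numpy(dtype=float),
            df[["a3_x", "a3_y"]].to_numpy(dtype=float),
        ],
        axis=1,
    )
    possession = df["possession"].to_numpy().astype(bool)
    return TrackSet(rate=rate, positions=positions, possession=possession, t0=float(t[0]))


def read_control_points_csv(path: str | Path) -> ControlPointSet:
    df = pd.read_csv(path)
    required = ["u_px", "v_px", "x_m", "y_m"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"control-point CSV missing columns: {sorted(missing)}")
    return ControlPointSet(
        image=df[["u_px", "v_px"]].to_numpy(dtype=float),
        world=df[["x_m", "y_m"]].to_numpy(dtype=float),
    )


def write_density_csv(path: str | Path, grid: DensityGrid) -> None:
    """Long-form density grid: one row per bin."""
    bx, by = np.meshgrid(np.arange(grid.bins), np.arange(grid.counts.shape[1]), indexing="ij")
    df = pd.DataFrame(
        {
            "bin_x": bx.ravel(),
            "bin_y": by.ravel(),
            "count": grid.counts.ravel().astype(int),
            "normalized": grid.normalized.ravel(),
            "in_triangle": grid.in_triangle.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_labels_csv(path: str | Path, segments) -> None:
    df = pd.DataFrame(
        [(t0, t1, label) for t0, t1, label in segments.segments],
        columns=["t_start", "t_end", "label"],
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_frequencies_csv(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
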