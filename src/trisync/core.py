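"""Shared containers for three-oscillator angle data and player tracks.

The package analyses the three interior angles of the triangle formed by
three interacting agents (e.g. three attackers in a small-sided ball
possession task).  Those angles always sum to pi, so a triple lives on a
2-simplex; :class:`AngleSeries` is the canonical in-memory form used by
every module.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

#: Angle triples must sum to this value (triangle angle-sum identity).
ANGLE_SUM = np.pi


@dataclass
class AngleSeries:
    """Uniformly sampled three-channel angle signal with a validity mask.

    Parameters
    ----------
    rate
        Sampling rate in Hz.
    theta
        Array of shape ``(n, 3)``; interior angle at each of the three
        agents, radians.  At every *valid* sample the row sums to pi.
    valid
        Boolean mask of length ``n``; invalid samples (e.g. defender
        interception, degenerate geometry) carry no information and may
        hold NaN.
    t0
        Time of the first sample in seconds (segments cut from a longer
        recording keep their original clock).
    """

    rate: float
    theta: np.ndarray
    valid: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[1] != 3:
            raise ValueError("theta must have shape (n, 3)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.valid is None:
            self.valid = np.ones(len(self.theta), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (len(self.theta),):
            raise ValueError("valid mask must match the number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.theta)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def check_invariants(self, sum_tol: float = 1e-9) -> None:
        """Raise if any valid sample violates the angle-sum or range bounds."""
        th = self.theta[self.valid]
        if th.size == 0:
            return
        if not np.all(np.isfinite(th)):
            raise ValueError("valid samples must be finite")
        dev = np.abs(th.sum(axis=1) - ANGLE_SUM)
        if dev.max() > sum_tol:
            raise ValueError(
                f"angle triples deviate from the sum-pi constraint by up to {dev.max():.3g}"
            )
        if th.min() < -sum_tol or th.max() > ANGLE_SUM + sum_tol:
            raise ValueError("angles must lie in [0, pi]")

    def segment(self, start: int, stop: int) -> "AngleSeries":
        """Contiguous sub-series ``[start, stop)`` keeping the original clock."""
        return AngleSeries(
            rate=self.rate,
            theta=self.theta[start:stop].copy(),
            valid=self.valid[start:stop].copy(),
            t0=self.t0 + start / self.rate,
        )

    def valid_runs(self) -> list[tuple[int, int]]:
        """Half-open index ranges of maximal contiguous valid stretches."""
        return _bool_runs(self.valid)


@dataclass
class TrackSet:
    """Per-frame 2-D positions (metres) of the three attackers.

    ``positions`` has shape ``(n, 3, 2)``.  ``possession`` marks frames in
    which the attackers hold the ball; ``valid`` additionally excludes
    frames rejected downstream (e.g. segments too short to filter) and
    defaults to a copy of ``possession``.
    """

    rate: float
    positions: np.ndarray
    possession: np.ndarray | None = None
    valid: np.ndarray | None = None
    arena: float = 6.0
    t0: float = 0.0
    defender: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (3, 2):
            raise ValueError("positions must have shape (n, 3, 2)")
        n = len(self.positions)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.possession is None:
            self.possession = np.ones(n, dtype=bool)
        self.possession = np.asarray(self.possession, dtype=bool)
        if self.valid is None:
            self.valid = self.possession.copy()
        self.valid = np.asarray(self.valid, dtype=bool)
        for mask in (self.possession, self.valid):
            if mask.shape != (n,):
                raise ValueError("masks must match the number of frames")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate

    def possession_runs(self) -> list[tuple[int, int]]:
        return _bool_runs(self.possession)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal True runs in a boolean vector."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def substream(seed: int | None, *names: str | int) -> np.random.Generator:
    """Named, reproducible random substream derived from one root seed.

    Every source of randomness in the package draws from a generator
    produced here, so a single root seed fixes an entire pipeline run
    while distinct stages stay statistically independent.
    """
    if seed is None:
        return np.random.default_rng()
    keys = [zlib.crc32(str(n).encode()) % (2**31) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))
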