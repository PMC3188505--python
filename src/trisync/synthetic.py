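"""Synthetic realizations of the synchronization patterns of a D3 ring.

A ring of three identically coupled oscillators admits five generic
pattern classes under equivariant (symmetric) Hopf bifurcation theory:

``ALL_IN``
    all three channels share one waveform in phase — under the sum-pi
    constraint this forces every channel constant at pi/3;
``R`` (rotation)
    one waveform repeated with cyclic 2*pi/3 phase shifts;
``PA`` (partial anti-phase)
    two channels anti-phase, the third *dead* (constant) in the
    operational reading, or oscillating at twice the common frequency in
    the full theory; ``PA1``/``PA2`` distinguish a dead value below/above
    pi/3;
``PI`` (partial in-phase)
    two channels identical and in phase, the third in anti-phase at
    twice their amplitude (forced by the sum-pi constraint);
    ``PI1``/``PI2`` distinguish an in-phase baseline below/above pi/3;
``ASYM``
    three unrelated waveforms (symmetry fully broken).

The generators here realize the *phase relations* of each class with
cosine carriers — the theory constrains phases, not waveform shape — and
are the ground truth against which the classifier is tested.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import ANGLE_SUM, AngleSeries, TrackSet, substream

PATTERN_LABELS = ("ALL_IN", "R", "PA1", "PA2", "PI1", "PI2", "ASYM")

_THIRD = ANGLE_SUM / 3.0  # pi/3, the symmetric fixed point of each channel


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of one synthetic trial of a single pattern class.

    Parameters
    ----------
    label
        One of :data:`PATTERN_LABELS`.
    amplitude
        Oscillation amplitude A in radians (half peak-to-valley).
    frequency
        Common oscillation frequency in Hz.
    base
        Constant channel value for PA (the dead channel's angle) or the
        in-phase pair's baseline for PI, radians.  Ignored by R/ALL_IN.
    special_channel
        1-based index of the distinguished channel: the dead channel for
        PA, the anti-phase channel for PI.
    duration, rate
        Trial length (s) and sampling rate (Hz); defaults match a 90 s
        trial digitized at 30 Hz.
    phase0
        Carrier phase offset at t = 0, radians.
    seed
        Seed for the randomized components (ASYM carrier phases).
    """

    label: str
    amplitude: float = 0.3
    frequency: float = 0.5
    base: float = 1.0
    special_channel: int = 3
    duration: float = 90.0
    rate: float = 30.0
    phase0: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.label not in PATTERN_LABELS:
            raise ValueError(f"unknown pattern label {self.label!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency <= 0 or self.duration <= 0 or self.rate <= 0:
            raise ValueError("frequency, duration and rate must be positive")
        if self.special_channel not in (1, 2, 3):
            raise ValueError("special_channel must be 1, 2 or 3")


@dataclass(frozen=True)
class PatternClass:
    """Catalog entry for one predicted pattern class of the ring."""

    label: str
    waveform_count: int
    pairwise_relation: str
    pairwise_shift: float | None = None
    frequency_note: str | None = None


def catalog_patterns(ring_size: int) -> list[PatternClass]:
    """The predicted pattern classes for a symmetric oscillator ring.

    Only ``ring_size == 3`` (dihedral D3 symmetry) is implemented; the
    argument exists as the extension point for larger rings.
    """
    if ring_size != 3:
        raise NotImplementedError(
            f"pattern catalog only implemented for a ring of 3 oscillators, got {ring_size}"
        )
    shift = 2.0 * math.pi / 3.0
    return [
        PatternClass("ALL_IN", 1, "all pairs in phase"),
        PatternClass("R", 1, "adjacent pairs shifted by 2*pi/3", pairwise_shift=shift),
        PatternClass(
            "PA",
            2,
            "one pair anti-phase; odd channel distinguished",
            frequency_note=(
                "theory: odd channel oscillates at twice the common frequency; "
                "operational: odd channel constant (oscillator death)"
            ),
        ),
        PatternClass(
            "PI",
            2,
            "one pair in phase; odd channel anti-phase at twice the amplitude",
        ),
        PatternClass("ASYM", 3, "no pairwise phase locking"),
    ]


# ---------------------------------------------------------------------------
# Closed-form waveforms.  Each returns an (n, 3) angle array for arbitrary
# sample times (negative t is legal: cross-fades evaluate one pattern a
# little before its own origin).
# ---------------------------------------------------------------------------


def _waveform(spec: PatternSpec, t: np.ndarray) -> np.ndarray:
    if spec.label == "ALL_IN":
        return np.full((len(t), 3), _THIRD)
    if spec.label == "R":
        return _rotation_waveform(spec, t)
    if spec.label in ("PA1", "PA2"):
        return _partial_antiphase_waveform(spec, t)
    if spec.label in ("PI1", "PI2"):
        return _partial_inphase_waveform(spec, t)
    if spec.label == "ASYM":
        return _asym_waveform(spec, t)
    raise ValueError(spec.label)  # pragma: no cover


def _rotation_waveform(spec: PatternSpec, t: np.ndarray) -> np.ndarray:
    if spec.amplitude >= _THIRD:
        raise ValueError(
            "rotation amplitude must be below pi/3 to keep all angles positive"
        )
    arg = 2.0 * math.pi * spec.frequency * t + spec.phase0
    shifts = 2.0 * math.pi * np.arange(3) / 3.0
    return _THIRD + spec.amplitude * np.cos(arg[:, None] - shifts[None, :])


def _partial_antiphase_waveform(spec: PatternSpec, t: np.ndarray) -> np.ndarray:
    c, a = spec.base, spec.amplitude
    if not 0.0 < c < ANGLE_SUM:
        raise ValueError("dead-channel value must lie strictly inside (0, pi)")
    if a > (ANGLE_SUM - c) / 2.0:
        raise ValueError("amplitude exceeds (pi - c)/2: oscillating angles leave [0, pi]")
    if spec.label == "PA1" and c >= _THIRD:
        raise ValueError("PA1 requires the dead-channel value below pi/3")
    if spec.label == "PA2" and c <= _THIRD:
        raise ValueError("PA2 requires the dead-channel value above pi/3")
    carrier = a * np.cos(2.0 * math.pi * spec.frequency * t + spec.phase0)
    dead = spec.special_channel - 1
    theta = np.empty((len(t), 3))
    theta[:, dead] = c
    others = [i for i in range(3) if i != dead]
    theta[:, others[0]] = (ANGLE_SUM - c) / 2.0 + carrier
    theta[:, others[1]] = (ANGLE_SUM - c) / 2.0 - carrier
    return theta


def _partial_inphase_waveform(spec: PatternSpec, t: np.ndarray) -> np.ndarray:
    c, a = spec.base, spec.amplitude
    # pair: c + A cos; anti channel: pi - 2c - 2A cos (sum-pi closure)
    if a >= c or c + a >= ANGLE_SUM / 2.0:
        raise ValueError(
            "partial in-phase requires amplitude < base and base + amplitude < pi/2"
        )
    if spec.label == "PI1" and c >= _THIRD:
        raise ValueError("PI1 requires the in-phase baseline below pi/3")
    if spec.label == "PI2" and c <= _THIRD:
        raise ValueError("PI2 requires the in-phase baseline above pi/3")
    carrier = a * np.cos(2.0 * math.pi * spec.frequency * t + spec.phase0)
    anti = spec.special_channel - 1
    theta = np.empty((len(t), 3))
    for i in range(3):
        theta[:, i] = c + carrier
    theta[:, anti] = ANGLE_SUM - 2.0 * c - 2.0 * carrier
    return theta


#: Incommensurate frequency ratios for the fully asymmetric pattern.
_ASYM_RATIOS = (1.0, math.sqrt(2.0), math.sqrt(3.0))


def _asym_waveform(spec: PatternSpec, t: np.ndarray) -> np.ndarray:
    if spec.amplitude >= _THIRD:
        raise ValueError("asym amplitude must stay below pi/3 for positivity")
    rng = substream(spec.seed, "asym-phases")
    phases = spec.phase0 + rng.uniform(0.0, 2.0 * math.pi, size=3)
    raw = np.empty((len(t), 3))
    for i in range(3):
        f = spec.frequency * _ASYM_RATIOS[i]
        raw[:, i] = _THIRD + spec.amplitude * np.cos(2.0 * math.pi * f * t + phases[i])
    # renormalize so the triple sums to pi exactly
    return ANGLE_SUM * raw / raw.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def _grid(spec: PatternSpec) -> np.ndarray:
    n = int(round(spec.duration * spec.rate))
    return np.arange(n) / spec.rate


def generate(spec: PatternSpec) -> AngleSeries:
    """Generate one noise-free trial of the pattern class in ``spec``."""
    series = AngleSeries(rate=spec.rate, theta=_waveform(spec, _grid(spec)))
    series.check_invariants()
    return series


def generate_rotation(spec: PatternSpec) -> AngleSeries:
    """Rotation pattern: one waveform with cyclic 2*pi/3 shifts."""
    return generate(replace(spec, label="R"))


def generate_partial_antiphase(spec: PatternSpec) -> AngleSeries:
    """Partial anti-phase: one dead (constant) channel, two anti-phase."""
    if spec.label not in ("PA1", "PA2"):
        label = "PA1" if spec.base < _THIRD else "PA2"
        spec = replace(spec, label=label)
    return generate(spec)


def generate_partial_inphase(spec: PatternSpec) -> AngleSeries:
    """Partial in-phase: identical pair, odd channel anti-phase at 2x amplitude."""
    if spec.label not in ("PI1", "PI2"):
        label = "PI1" if spec.base < _THIRD else "PI2"
        spec = replace(spec, label=label)
    return generate(spec)


def generate_switching(
    specs: list[PatternSpec], blend_time: float = 0.0
) -> tuple[AngleSeries, list[tuple[float, float, str]]]:
    """Concatenate pattern segments with a linear cross-fade at boundaries.

    Returns the blended series together with ground-truth label segments
    ``(t_start, t_end, label)``.  Because every segment's triple sums to
    pi, any convex combination does too, so the cross-fade preserves the
    simplex constraint exactly.
    """
    if not specs:
        raise ValueError("at least one pattern segment is required")
    if blend_time < 0:
        raise ValueError("blend_time must be non-negative")
    rate = specs[0].rate
    if any(s.rate != rate for s in specs):
        raise ValueError("all segments must share one sampling rate")
    durations = [s.duration for s in specs]
    starts = np.concatenate(([0.0], np.cumsum(durations)))
    total = starts[-1]
    t = np.arange(int(round(total * rate))) / rate
    theta = np.empty((len(t), 3))
    for k, spec in enumerate(specs):
        mask = (t >= starts[k]) & (t < starts[k + 1])
        theta[mask] = _waveform(spec, t[mask] - starts[k])
    for k in range(len(specs) - 1):  # cross-fade around each interior boundary
        if blend_time == 0:
            break
        tb = starts[k + 1]
        mask = (t >= tb - blend_time / 2.0) & (t < tb + blend_time / 2.0)
        if not mask.any():
            continue
        w = (t[mask] - (tb - blend_time / 2.0)) / blend_time
        prev = _waveform(specs[k], t[mask] - starts[k])
        nxt = _waveform(specs[k + 1], t[mask] - starts[k + 1])
        theta[mask] = (1.0 - w)[:, None] * prev + w[:, None] * nxt
    series = AngleSeries(rate=rate, theta=theta)
    series.check_invariants()
    labels = [
        (float(starts[k]), float(starts[k + 1]), specs[k].label)
        for k in range(len(specs))
    ]
    return series, labels


def angles_to_tracks(
    series: AngleSeries,
    circumradius: float = 2.0,
    center: tuple[float, float] = (3.0, 3.0),
    rotation_rate: float = 0.0,
    drift_velocity: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
    arena: float = 6.0,
) -> TrackSet:
    """Realize an angle series as player positions on a circumscribed circle.

    Uses the inscribed-angle theorem: placing the three vertices on a
    circle of radius ``circumradius`` at cumulative central angles
    ``2*theta3, 2*theta1`` (the arc opposite vertex i subtends ``2*theta_i``)
    reproduces the requested interior angles exactly, so
    ``preprocess.extract_angles`` inverts this construction at noise 0.
    A slow rigid rotation/translation and seeded Gaussian position noise
    can be layered on top; noise lives in position space so the recovered
    angles always obey the sum-pi identity.
    """
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    series.check_invariants(sum_tol=1e-6)
    t = series.times
    th = series.theta
    base = rotation_rate * t
    a1 = base
    a2 = base + 2.0 * th[:, 2]
    a3 = a2 + 2.0 * th[:, 0]
    angles = np.stack([a1, a2, a3], axis=1)
    cx = center[0] + drift_velocity[0] * t
    cy = center[1] + drift_velocity[1] * t
    positions = np.empty((series.n_samples, 3, 2))
    positions[:, :, 0] = cx[:, None] + circumradius * np.cos(angles)
    positions[:, :, 1] = cy[:, None] + circumradius * np.sin(angles)
    if noise_sd > 0:
        rng = substream(seed, "track-noise")
        positions = positions + rng.normal(0.0, noise_sd, size=positions.shape)
    return TrackSet(
        rate=series.rate,
        positions=positions,
        possession=series.valid.copy(),
        arena=arena,
        t0=series.t0,
    )
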