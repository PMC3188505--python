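"""Peak-based pattern classification of three-oscillator angle series.

The pipeline is deliberately peak-based (no Hilbert/wavelet phase):

1. detect alternating peaks and valleys per channel;
2. for each ordered channel pair, estimate a relative phase at every
   reference peak from the lag to the nearest peak of the other channel,
   expressed as a fraction of the local period;
3. label each pair relation as in-phase, anti-phase, a +/-2*pi/3 shift,
   dead (one channel's local amplitude below an oscillator-death
   threshold), or other;
4. combine the three cyclic pair labels on the reference channel's
   half-cycle intervals into a triple pattern: rotation (R), partial
   anti-phase (PA1/PA2), partial in-phase (PI1/PI2), all-in-phase, or
   other;
5. summarize a trial as the percentage of valid time occupied by each
   pattern (its occurrence frequency).

Tolerance bands default to pi/6 around each nominal phase (0, +/-2*pi/3,
pi) — equal, non-overlapping bands covering the circle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import ANGLE_SUM, AngleSeries

TOL_DEFAULT = np.pi / 6.0
#: A channel is "dead" when its local amplitude falls below this fraction
#: of the median channel amplitude.  The fraction must clear the residual
#: amplitude that measurement noise leaves on a truly constant channel
#: after low-pass filtering (roughly a quarter of the signal amplitude at
#: realistic tracking-noise levels), while staying well below 1.
DEATH_FRAC_DEFAULT = 0.3
TWO_THIRDS_PI = 2.0 * np.pi / 3.0

# pair relation labels
IN, ANTI, SHIFT_PLUS, SHIFT_MINUS, DEAD, OTHER = (
    "IN",
    "ANTI",
    "SHIFT_PLUS",
    "SHIFT_MINUS",
    "DEAD",
    "OTHER",
)

TRIPLE_LABELS = ("R", "PA1", "PA2", "PI1", "PI2", "ALL_IN", "OTHER")

#: Cyclic channel pairs (0-based) used for the triple decision.
CYCLIC_PAIRS = ((0, 1), (1, 2), (2, 0))


@dataclass
class ExtremaList:
    """Alternating peaks (+1) and valleys (-1) of one channel."""

    times: np.ndarray
    values: np.ndarray
    kinds: np.ndarray  # +1 peak, -1 valley

    @property
    def peak_times(self) -> np.ndarray:
        return self.times[self.kinds == 1]

    @property
    def peak_values(self) -> np.ndarray:
        return self.values[self.kinds == 1]


@dataclass
class PairPhaseSeries:
    """Per-reference-peak phase estimates for one ordered channel pair.

    For the reference peak at time t with next reference peak at t + T:
    ``dphi = wrap(2*pi*(t* - t)/T)`` where t* is the nearest peak of the
    other channel (NaN when none lies within +/-T).  Local amplitudes are
    half the extremum span of each channel inside the window [t-T, t+T].
    """

    t_ref: np.ndarray
    period: np.ndarray
    dphi: np.ndarray
    amp_ref: np.ndarray
    amp_other: np.ndarray

    def __len__(self) -> int:
        return len(self.t_ref)


@dataclass
class PatternLabelSegments:
    """Interval labels over a segment, merged into runs of equal label.

    ``intervals`` are the reference channel's consecutive extremum spans
    with one triple label and the supporting cyclic pair labels each;
    ``segments`` merges adjacent intervals sharing a label.
    """

    intervals: list[tuple[float, float, str, tuple[str, str, str]]]
    segments: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = _merge(self.intervals)

    def label_durations(self) -> dict[str, float]:
        out = {label: 0.0 for label in TRIPLE_LABELS}
        for t0, t1, label, _ in self.intervals:
            out[label] += t1 - t0
        return out


def _merge(intervals) -> list[tuple[float, float, str]]:
    merged: list[tuple[float, float, str]] = []
    for t0, t1, label, _ in intervals:
        if merged and merged[-1][2] == label and np.isclose(merged[-1][1], t0):
            merged[-1] = (merged[-1][0], t1, label)
        else:
            merged.append((t0, t1, label))
    return merged


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-pi, pi]; the boundary maps to +pi by convention."""
    out = np.asarray(phi, dtype=float)
    out = out - 2.0 * np.pi * np.floor((out + np.pi) / (2.0 * np.pi))
    out = np.where(out <= -np.pi, out + 2.0 * np.pi, out)
    return float(out) if np.isscalar(phi) else out


def detect_extrema(
    values: np.ndarray,
    rate: float,
    t0: float = 0.0,
    prominence: float = 0.05,
    min_separation: float = 1.0,
) -> ExtremaList:
    """Alternating local extrema of a uniformly sampled channel.

    Peaks and valleys are found independently with the given prominence
    (radians) and minimum separation (seconds), merged in time order,
    and forced to alternate: of two same-kind neighbours the more extreme
    one is kept.  Sample endpoints never count as extrema.  A constant
    channel yields an empty list.
    """
    x = np.asarray(values, dtype=float)
    distance = max(1, int(round(min_separation * rate)))
    peaks, _ = find_peaks(x, prominence=prominence, distance=distance)
    valleys, _ = find_peaks(-x, prominence=prominence, distance=distance)
    idx = np.concatenate([peaks, valleys])
    kinds = np.concatenate([np.ones(len(peaks), int), -np.ones(len(valleys), int)])
    order = np.argsort(idx, kind="stable")
    idx, kinds = idx[order], kinds[order]
    keep_idx: list[int] = []
    keep_kind: list[int] = []
    for i, k in zip(idx, kinds):
        if keep_kind and keep_kind[-1] == k:
            # same kind twice: keep the more extreme of the two
            better = x[i] > x[keep_idx[-1]] if k == 1 else x[i] < x[keep_idx[-1]]
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(int(i))
            keep_kind.append(int(k))
    idx = np.array(keep_idx, dtype=int)
    return ExtremaList(
        times=t0 + idx / rate,
        values=x[idx] if len(idx) else np.empty(0),
        kinds=np.array(keep_kind, dtype=int),
    )


def _half_span(ex: ExtremaList, lo: float, hi: float) -> float:
    """Half peak-to-valley span of a channel's extrema inside [lo, hi]."""
    mask = (ex.times >= lo) & (ex.times <= hi)
    vals = ex.values[mask]
    if len(vals) < 2:
        return 0.0
    return float(vals.max() - vals.min()) / 2.0


def pairwise_phase(ref: ExtremaList, other: ExtremaList) -> PairPhaseSeries:
    """Relative phase of ``other`` against ``ref`` at each reference peak.

    When the reference channel itself has fewer than two peaks (e.g. it
    is dead) but the other one oscillates, the roles of the time base are
    swapped so the pair still gets amplitude evidence; the phase is then
    undefined (NaN) on every entry.
    """
    rp = ref.peak_times
    if len(rp) < 2:
        op = other.peak_times
        if len(op) < 2:
            empty = np.empty(0)
            return PairPhaseSeries(empty, empty, empty, empty, empty)
        # fall back to the other channel's peak grid, phase undefined
        periods = np.diff(op)
        t = op[:-1]
        amp_ref = np.array(
            [_half_span(ref, ti - Ti, ti + Ti) for ti, Ti in zip(t, periods)]
        )
        amp_other = np.array(
            [_half_span(other, ti - Ti, ti + Ti) for ti, Ti in zip(t, periods)]
        )
        return PairPhaseSeries(t, periods, np.full(len(t), np.nan), amp_ref, amp_other)
    # every ref peak contributes; the last one uses the backward period
    periods = np.append(np.diff(rp), rp[-1] - rp[-2])
    t = rp
    op = other.peak_times
    dphi = np.full(len(t), np.nan)
    amp_ref = np.empty(len(t))
    amp_other = np.empty(len(t))
    for i, (ti, Ti) in enumerate(zip(t, periods)):
        amp_ref[i] = _half_span(ref, ti - Ti, ti + Ti)
        amp_other[i] = _half_span(other, ti - Ti, ti + Ti)
        if len(op):
            lags = op - ti
            j = int(np.argmin(np.abs(lags)))  # ties resolve to the earlier peak
            if abs(lags[j]) <= Ti:
                dphi[i] = wrap_phase(2.0 * np.pi * lags[j] / Ti)
    return PairPhaseSeries(t, periods, dphi, amp_ref, amp_other)


def classify_pair(
    pp: PairPhaseSeries,
    tol: float = TOL_DEFAULT,
    death_threshold: float | None = None,
    death_frac: float = DEATH_FRAC_DEFAULT,
) -> np.ndarray:
    """Label each pair-phase entry as IN/ANTI/SHIFT_PLUS/SHIFT_MINUS/DEAD/OTHER.

    Oscillator death takes precedence: if either channel's local
    amplitude falls below ``death_threshold`` (default ``death_frac``
    times the median of the pair's own local amplitudes) the entry is
    DEAD regardless of phase.  Undefined phases label OTHER.
    """
    if not 0 < tol < np.pi / 3.0 + 1e-12:
        raise ValueError("tol must lie in (0, pi/3] for non-overlapping bands")
    if death_threshold is None:
        amps = np.concatenate([pp.amp_ref, pp.amp_other])
        amps = amps[amps > 0]
        death_threshold = death_frac * (np.median(amps) if len(amps) else 0.0)
    labels = np.full(len(pp), OTHER, dtype=object)
    for i in range(len(pp)):
        if min(pp.amp_ref[i], pp.amp_other[i]) < death_threshold:
            labels[i] = DEAD
        elif np.isnan(pp.dphi[i]):
            labels[i] = OTHER
        elif abs(pp.dphi[i]) <= tol:
            labels[i] = IN
        elif abs(abs(pp.dphi[i]) - np.pi) <= tol:
            labels[i] = ANTI
        elif abs(pp.dphi[i] - TWO_THIRDS_PI) <= tol:
            labels[i] = SHIFT_PLUS
        elif abs(pp.dphi[i] + TWO_THIRDS_PI) <= tol:
            labels[i] = SHIFT_MINUS
    return labels


def _label_near(
    pp: PairPhaseSeries,
    labels: np.ndarray,
    t: float,
    pair: tuple[int, int],
    extrema: list[ExtremaList],
    threshold: float,
    scale: float,
) -> str:
    """Pair label in force at time t, from temporally local evidence only.

    The nearest phase entry is used when it lies within 1.5 local periods
    of t; otherwise the pair has no phase evidence there (a channel may
    have stopped oscillating mid-segment), so the decision falls back to
    local amplitudes: DEAD if either channel's extremum span around t is
    below the death threshold, else OTHER.
    """
    if len(pp):
        j = int(np.argmin(np.abs(pp.t_ref - t)))
        if abs(pp.t_ref[j] - t) <= 1.5 * pp.period[j]:
            return str(labels[j])
    window = 2.0 * scale
    amps = [_half_span(extrema[c], t - window, t + window) for c in pair]
    return DEAD if min(amps) < threshold else OTHER


def _triple_rule(
    pair_labels: tuple[str, str, str], interval_means: np.ndarray
) -> str:
    """Combine the three cyclic pair labels into one triple pattern label.

    ``pair_labels`` follows :data:`CYCLIC_PAIRS`; ``interval_means`` are
    the three channel means over the interval, used for the PA1/PA2 and
    PI1/PI2 sub-labels (dead value / in-phase baseline vs pi/3).
    """
    third = ANGLE_SUM / 3.0
    labs = list(pair_labels)
    if all(l in (SHIFT_PLUS, SHIFT_MINUS) for l in labs) and len(set(labs)) == 1:
        return "R"
    if labs.count(ANTI) == 1 and labs.count(DEAD) == 2:
        anti_pair = CYCLIC_PAIRS[labs.index(ANTI)]
        dead_channel = ({0, 1, 2} - set(anti_pair)).pop()
        # the two DEAD pairs must both involve the remaining channel
        if all(
            dead_channel in CYCLIC_PAIRS[i]
            for i in range(3)
            if labs[i] == DEAD
        ):
            return "PA1" if interval_means[dead_channel] < third else "PA2"
    if labs.count(IN) == 1 and labs.count(ANTI) == 2:
        in_pair = CYCLIC_PAIRS[labs.index(IN)]
        pair_mean = interval_means[list(in_pair)].mean()
        return "PI1" if pair_mean < third else "PI2"
    if all(l == IN for l in labs):
        return "ALL_IN"
    return OTHER


def classify_triple(
    series: AngleSeries,
    tol: float = TOL_DEFAULT,
    death_frac: float = DEATH_FRAC_DEFAULT,
    prominence: float = 0.05,
    min_separation: float = 1.0,
) -> PatternLabelSegments:
    """Label a fully valid segment with triple synchronization patterns.

    The reference channel is the one with the most extrema among the
    channels that actually oscillate; its consecutive extremum
    (peak–valley) spans are the labelling intervals.  Each interval takes
    the pair labels in force at its midpoint and the channel means over
    the interval, combined by :func:`_triple_rule`.  The oscillator-death
    threshold is ``death_frac`` times the median channel amplitude, and
    ``prominence`` acts as a floor: the working prominence adapts to the
    segment's own amplitude scale so measurement ripple on a large
    signal does not masquerade as extra cycles.
    """
    th = series.theta
    # robust per-channel amplitude from the signal itself (half the
    # 5–95% quantile span ~ the amplitude of a sinusoid)
    robust_amp = np.array(
        [(np.quantile(th[:, c], 0.95) - np.quantile(th[:, c], 0.05)) / 2.0 for c in range(3)]
    )
    prominence = max(prominence, 0.4 * float(np.median(robust_amp)))
    extrema = [
        detect_extrema(th[:, c], series.rate, series.t0, prominence, min_separation)
        for c in range(3)
    ]
    phases = {pair: pairwise_phase(extrema[pair[0]], extrema[pair[1]]) for pair in CYCLIC_PAIRS}
    # per-channel amplitude scale: median half-span between consecutive
    # extrema; the death threshold is a fraction of the channel median
    chan_amp = np.array(
        [
            float(np.median(np.abs(np.diff(ex.values)))) / 2.0 if len(ex.values) >= 2 else 0.0
            for ex in extrema
        ]
    )
    threshold = death_frac * float(np.median(chan_amp))
    pair_labels = {
        pair: classify_pair(phases[pair], tol=tol, death_threshold=threshold)
        for pair in CYCLIC_PAIRS
    }
    # reference channel: most extrema among channels that actually oscillate
    alive = [c for c in range(3) if chan_amp[c] >= threshold]
    ref = max(alive or range(3), key=lambda c: len(extrema[c].times))
    ref_times = extrema[ref].times
    # local timescale: the median inter-peak interval across channels
    peak_gaps = np.concatenate(
        [np.diff(ex.peak_times) for ex in extrema if len(ex.peak_times) >= 2]
        or [np.empty(0)]
    )
    scale = float(np.median(peak_gaps)) if len(peak_gaps) else 2.0
    intervals = []
    times = series.times
    for k in range(len(ref_times) - 1):
        t0, t1 = float(ref_times[k]), float(ref_times[k + 1])
        tm = 0.5 * (t0 + t1)
        labs = tuple(
            _label_near(
                phases[pair], pair_labels[pair], tm, pair, extrema, threshold, scale
            )
            for pair in CYCLIC_PAIRS
        )
        window = (times >= t0) & (times <= t1)
        means = th[window].mean(axis=0) if window.any() else th.mean(axis=0)
        intervals.append((t0, t1, _triple_rule(labs, means), labs))
    return PatternLabelSegments(intervals=intervals)


def occurrence_frequencies(
    segments: PatternLabelSegments, valid_duration: float
) -> dict[str, float]:
    """Percentage of valid time occupied by each triple pattern label."""
    if valid_duration <= 0:
        raise ValueError("valid_duration must be positive")
    durations = segments.label_durations()
    return {label: 100.0 * d / valid_duration for label, d in durations.items()}
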