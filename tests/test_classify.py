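"""Extremum detection, phase estimation and triple-pattern labelling."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisync.classify import (
    ANTI,
    DEAD,
    IN,
    OTHER,
    SHIFT_PLUS,
    PairPhaseSeries,
    classify_pair,
    classify_triple,
    detect_extrema,
    occurrence_frequencies,
    pairwise_phase,
    wrap_phase,
)
from trisync.core import AngleSeries
from trisync.preprocess import FilterSpec, extract_angles, lowpass
from trisync.synthetic import PatternSpec, angles_to_tracks, generate, generate_switching

from conftest import PATTERN_SPECS

RATE = 30.0


def _cosine(freq=0.5, duration=10.0, amp=1.0, phase=0.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.cos(2 * np.pi * freq * t + phase), t


class TestDetectExtrema:
    def test_constant_channel_has_no_extrema(self):
        ex = detect_extrema(np.full(300, 1.0), RATE)
        assert len(ex.times) == 0

    def test_cosine_interior_peaks_at_whole_periods(self):
        x, _ = _cosine(freq=0.5, duration=10.0)
        ex = detect_extrema(x, RATE)
        assert np.allclose(ex.peak_times, [2.0, 4.0, 6.0, 8.0], atol=1 / RATE)
        assert len(ex.peak_times) == 4

    def test_alternation_enforced(self):
        x, _ = _cosine(freq=0.5, duration=20.0)
        ex = detect_extrema(x, RATE)
        assert np.all(np.diff(ex.times) > 0)
        assert np.all(ex.kinds[1:] != ex.kinds[:-1])

    def test_small_ripple_suppressed_by_prominence(self):
        x, t = _cosine(freq=0.4, duration=20.0, amp=1.0)
        ripple = 0.02 * np.cos(2 * np.pi * 5.0 * t)
        clean = detect_extrema(x, RATE, prominence=0.1)
        noisy = detect_extrema(x + ripple, RATE, prominence=0.1)
        assert len(noisy.times) == len(clean.times)


class TestPairwisePhase:
    def test_identical_channels_zero_phase(self):
        x, _ = _cosine()
        ex = detect_extrema(x, RATE)
        pp = pairwise_phase(ex, ex)
        assert np.allclose(pp.dphi, 0.0)

    def test_half_period_delay_gives_pi(self):
        freq, rate = 0.5, 100.0
        x, _ = _cosine(freq, 20.0, rate=rate)
        y, _ = _cosine(freq, 20.0, phase=np.pi, rate=rate)
        pp = pairwise_phase(detect_extrema(x, rate), detect_extrema(y, rate))
        assert np.allclose(np.abs(pp.dphi), np.pi, atol=0.05)

    def test_third_period_delay_gives_two_thirds_pi(self):
        freq = 0.5
        x, _ = _cosine(freq, 30.0)
        y, _ = _cosine(freq, 30.0, phase=-2 * np.pi / 3)  # lags by T/3
        pp = pairwise_phase(detect_extrema(x, RATE), detect_extrema(y, RATE))
        assert np.allclose(pp.dphi, 2 * np.pi / 3, atol=0.1)

    @pytest.mark.parametrize("delay_frac", [0.1, 0.25, 0.4])
    def test_estimator_error_bounded_by_one_sample(self, delay_frac):
        freq = 0.5
        period = 1.0 / freq
        x, _ = _cosine(freq, 60.0)
        y, _ = _cosine(freq, 60.0, phase=-2 * np.pi * delay_frac)
        pp = pairwise_phase(detect_extrema(x, RATE), detect_extrema(y, RATE))
        bound = 2 * np.pi * (1 / RATE) / period + 1e-9
        assert np.abs(pp.dphi - 2 * np.pi * delay_frac).max() < bound

    def test_no_nearby_peak_is_undefined(self):
        x, _ = _cosine(0.5, 20.0)
        far = detect_extrema(np.zeros(len(x)), RATE)  # no peaks at all
        pp = pairwise_phase(detect_extrema(x, RATE), far)
        assert np.isnan(pp.dphi).all()

    def test_local_amplitudes_estimate_half_span(self):
        x, _ = _cosine(0.5, 30.0, amp=0.4)
        y, _ = _cosine(0.5, 30.0, amp=0.1)
        pp = pairwise_phase(detect_extrema(x, RATE), detect_extrema(y, RATE))
        assert np.allclose(pp.amp_ref, 0.4, atol=0.01)
        assert np.allclose(pp.amp_other, 0.1, atol=0.01)


class TestClassifyPair:
    def _pp(self, dphi, amp_ref=0.4, amp_other=0.4):
        n = len(dphi)
        return PairPhaseSeries(
            t_ref=np.arange(n, dtype=float),
            period=np.ones(n),
            dphi=np.asarray(dphi, dtype=float),
            amp_ref=np.full(n, amp_ref),
            amp_other=np.full(n, amp_other),
        )

    @pytest.mark.parametrize(
        "dphi,expected",
        [
            (0.05, IN),
            (3.10, ANTI),
            (-3.10, ANTI),
            (2 * np.pi / 3 + 0.1, SHIFT_PLUS),
            (-2 * np.pi / 3 + 0.1, "SHIFT_MINUS"),
            (1.3, OTHER),
        ],
    )
    def test_band_assignment(self, dphi, expected):
        labels = classify_pair(self._pp([dphi]), tol=np.pi / 6, death_threshold=0.05)
        assert labels[0] == expected

    def test_death_takes_precedence_over_phase(self):
        pp = self._pp([0.0], amp_other=0.02)
        labels = classify_pair(pp, death_threshold=0.05)
        assert labels[0] == DEAD

    def test_undefined_phase_labels_other(self):
        labels = classify_pair(self._pp([np.nan]), death_threshold=0.05)
        assert labels[0] == OTHER

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(self._pp([0.0]), tol=2.0)


class TestClassifyTriple:
    @pytest.mark.parametrize("label", sorted(PATTERN_SPECS))
    def test_recovers_the_generating_pattern(self, label):
        lab = classify_triple(generate(PATTERN_SPECS[label]))
        hits = sum(1 for *_, l, _p in lab.intervals if l == label)
        assert len(lab.intervals) > 50
        assert hits / len(lab.intervals) >= 0.99

    def test_contradictory_pair_labels_fall_to_other(self):
        from trisync.classify import _triple_rule

        means = np.full(3, np.pi / 3)
        assert _triple_rule((IN, IN, ANTI), means) == OTHER

    def test_relabelling_equivariance_under_cyclic_permutation(self):
        spec = PATTERN_SPECS["PA1"]
        series = generate(spec)
        rolled = AngleSeries(rate=series.rate, theta=np.roll(series.theta, 1, axis=1))
        a = classify_triple(series)
        b = classify_triple(rolled)
        maj = lambda lab: max(
            set(l for *_, l, _p in lab.intervals),
            key=lambda x: sum(1 for *_, l, _p in lab.intervals if l == x),
        )
        assert maj(a) == maj(b) == "PA1"

    def test_switching_trial_segments_recovered(self):
        specs = [
            PatternSpec("R", amplitude=0.3, frequency=0.5, duration=30),
            PatternSpec("PA1", amplitude=0.3, frequency=0.5, base=1.0, duration=30),
        ]
        series, truth = generate_switching(specs, blend_time=1.0)
        lab = classify_triple(series)
        for t0, t1, expected in truth:
            core = [
                l for a, b, l, _ in lab.intervals if a >= t0 + 3 and b <= t1 - 3
            ]
            hits = sum(1 for l in core if l == expected)
            assert hits / len(core) >= 0.9

    # smoothing for the noisy-track chain must pass the oscillation band
    # (up to ~0.8 Hz) on both axes while rejecting frame-to-frame noise
    _SMOOTH = FilterSpec(cutoff_x=2.0, cutoff_y=2.0)

    @pytest.mark.parametrize("label", ["R", "PA1", "PI2"])
    def test_majority_recovery_survives_position_noise(self, label):
        # the full measurement chain: noisy tracks -> low-pass -> angles
        spec = PATTERN_SPECS[label]
        series = generate(spec)
        tracks = lowpass(angles_to_tracks(series, noise_sd=0.05, seed=1), self._SMOOTH)
        noisy = extract_angles(tracks)
        lab = classify_triple(noisy)
        hits = sum(1 for *_, l, _p in lab.intervals if l == label)
        assert hits / len(lab.intervals) > 0.5

    def test_noise_degrades_recovery_monotonically_on_average(self):
        spec = PATTERN_SPECS["R"]
        series = generate(spec)

        def recovery(sd, seed):
            tracks = lowpass(
                angles_to_tracks(series, noise_sd=sd, seed=seed), self._SMOOTH
            )
            noisy = extract_angles(tracks)
            lab = classify_triple(noisy)
            return sum(1 for *_, l, _p in lab.intervals if l == "R") / len(lab.intervals)

        lo = np.mean([recovery(0.01, s) for s in range(3)])
        hi = np.mean([recovery(0.2, s) for s in range(3)])
        assert lo > hi


class TestFrequencies:
    def test_single_label_trial_is_one_hundred_percent(self):
        lab = classify_triple(generate(PATTERN_SPECS["R"]))
        total = sum(t1 - t0 for t0, t1, *_ in lab.intervals)
        freq = occurrence_frequencies(lab, valid_duration=total)
        assert freq["R"] == pytest.approx(100.0)

    def test_partition_sums_to_total_labelled_time(self):
        specs = [
            PatternSpec("R", duration=30),
            PatternSpec("PA1", base=1.0, duration=30),
        ]
        series, _ = generate_switching(specs)
        lab = classify_triple(series)
        total = sum(t1 - t0 for t0, t1, *_ in lab.intervals)
        freq = occurrence_frequencies(lab, valid_duration=total)
        assert sum(freq.values()) == pytest.approx(100.0)
        assert freq["R"] > 30 and freq["PA1"] > 30

    def test_zero_duration_rejected(self):
        lab = classify_triple(generate(PatternSpec("R", duration=10)))
        with pytest.raises(ValueError):
            occurrence_frequencies(lab, valid_duration=0.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.floats(-50.0, 50.0))
def test_wrap_phase_lands_in_the_half_open_interval(phi):
    w = wrap_phase(phi)
    assert -np.pi < w <= np.pi
    assert np.cos(w) == pytest.approx(np.cos(phi), abs=1e-9)
    assert np.sin(w) == pytest.approx(np.sin(phi), abs=1e-9)
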