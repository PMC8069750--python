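"""Cycle detection against analytic and brute-force oracles, and the
telescoping behaviour of N-cycle averages."""

import numpy as np
import pytest

from skategears import (CycleRecord, TrajectorySeries, average_over_n,
                        build_lcs, detect_cycles, lowpass_trajectory,
                        measure_cycles, smooth_spline)
from skategears.cycles import block_duration_deviations

FS = 50.0


# -- brute-force oracle ------------------------------------------------------

def brute_force_boundaries(time, v, prominence=0.7, min_sep=0.8):
    """Independent re-derivation: explicit topographic prominence per local
    maximum (endpoints as infinite-depth valleys), then greedy thinning by
    height (ties to the earlier peak)."""
    n = len(v)
    peaks = [i for i in range(1, n - 1) if v[i - 1] < v[i] >= v[i + 1]]
    keep = []
    for i in peaks:
        j = i
        left_min = v[i]
        while j > 0 and v[j] <= v[i]:
            j -= 1
            left_min = min(left_min, v[j])
        if v[j] <= v[i]:          # ran into the edge: whole side is valley
            left_base = left_min
        else:
            left_base = left_min
        j = i
        right_min = v[i]
        while j < n - 1 and v[j] <= v[i]:
            j += 1
            right_min = min(right_min, v[j])
        right_base = right_min
        prom = v[i] - max(left_base, right_base)
        if prom >= prominence:
            keep.append(i)
    accepted = []
    for i in sorted(keep, key=lambda i: (-v[i], i)):
        if all(abs(time[i] - time[j]) >= min_sep for j in accepted):
            accepted.append(i)
    return time[np.sort(accepted)]


class TestDetectCycles:
    def test_flat_signal_has_no_boundaries(self):
        t = np.arange(500) / FS
        assert detect_cycles(t, np.zeros_like(t)).size == 0

    def test_sine_boundaries_at_analytic_maxima(self):
        t = np.arange(500) / FS
        v = 1.0 * np.sin(2 * np.pi * 0.7 * t)
        b = detect_cycles(t, v)
        # maxima of sin at t = 1/(4*0.7) + k/0.7
        expected = 1 / 2.8 + np.arange(7) / 0.7
        expected = expected[expected < t[-1] - 0.1]
        assert b.size == expected.size
        assert np.allclose(b, expected, atol=1.0 / FS)
        assert np.allclose(np.diff(b), 1 / 0.7, atol=2.0 / FS)

    def test_prominence_of_pure_sine_is_twice_amplitude(self):
        t = np.arange(500) / FS
        # prominence 0.6 < 0.7: rejected
        assert detect_cycles(t, 0.3 * np.sin(2 * np.pi * 0.7 * t)).size == 0
        # prominence 0.8 >= 0.7: accepted
        assert detect_cycles(t, 0.4 * np.sin(2 * np.pi * 0.7 * t)).size > 0

    def test_close_peaks_keep_the_higher_one(self):
        t = np.arange(200) / FS
        v = np.zeros_like(t)
        v[50] = 1.0   # t = 1.0 s
        v[70] = 1.5   # t = 1.4 s, within 0.8 s of the first
        b = detect_cycles(t, v)
        assert np.allclose(b, [t[70]])

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(100) / FS
        v = rng.normal(0, 1.0, t.size)
        assert np.array_equal(detect_cycles(t, v),
                              brute_force_boundaries(t, v))


class TestMeasureCycles:
    def _uniform(self, speed=3.0, duration=40.0):
        t = np.arange(int(duration * FS)) / FS
        pos = np.column_stack([np.zeros_like(t), speed * t,
                               np.zeros_like(t)])
        smooth = smooth_spline(TrajectorySeries(t, pos), 0.0)
        lcs = build_lcs(smooth, lowpass_trajectory(smooth))
        return smooth, lcs

    def test_straight_line_durations_and_lengths(self):
        smooth, lcs = self._uniform(speed=3.0)
        boundaries = 5.0 + 1.5 * np.arange(10)
        recs = measure_cycles(boundaries, smooth, lcs)
        assert len(recs) == 9
        for r in recs:
            assert r.duration == pytest.approx(1.5, abs=1e-9)
            assert r.length == pytest.approx(4.5, abs=1e-6)
            assert abs(r.heading_change) < 1e-6

    def test_heading_rate_on_circular_arc(self):
        # speed 6 m/s on radius 17.19 m: omega = v/R = 0.349 rad/s = 20 deg/s
        omega = 6.0 / 17.19
        t = np.arange(int(40 * FS)) / FS
        psi = omega * t
        pos = np.column_stack([17.19 * (1 - np.cos(psi)),
                               17.19 * np.sin(psi), np.zeros_like(t)])
        smooth = smooth_spline(TrajectorySeries(t, pos), 0.0)
        lcs = build_lcs(smooth, lowpass_trajectory(smooth))
        recs = measure_cycles(np.array([15.0, 16.0]), smooth, lcs)
        assert len(recs) == 1
        assert recs[0].heading_rate == pytest.approx(np.degrees(omega),
                                                     rel=0.02)

    def test_chord_length_below_path_length(self):
        # zig-zag: strong sideways oscillation superposed on progression
        t = np.arange(int(40 * FS)) / FS
        pos = np.column_stack([0.5 * np.sin(2 * np.pi * 0.7 * t), 3.0 * t,
                               np.zeros_like(t)])
        smooth = smooth_spline(TrajectorySeries(t, pos), 0.0)
        lcs = build_lcs(smooth, lowpass_trajectory(smooth))
        recs = measure_cycles(np.array([10.0, 11.5]), smooth, lcs)
        sel = (smooth.time >= 10.0) & (smooth.time <= 11.5)
        path = np.sum(np.linalg.norm(np.diff(smooth.pos[sel], axis=0),
                                     axis=1))
        assert recs[0].length < path


def _records(durations, t0=0.0, length=4.0):
    recs, t = [], t0
    for d in durations:
        recs.append(CycleRecord(t_start=t, t_end=t + d, duration=d,
                                length=length, heading_change=0.0,
                                heading_rate=0.0))
        t += d
    return recs


class TestAverageOverN:
    def test_n1_is_identity(self):
        recs = _records([1.4, 1.5, 1.6])
        out = average_over_n(recs, 1)
        assert [d for d, _ in out] == pytest.approx([1.4, 1.5, 1.6])

    def test_constant_durations(self):
        out = average_over_n(_records([1.5] * 10), 5)
        assert len(out) == 2
        assert all(d == pytest.approx(1.5) for d, _ in out)

    def test_telescoping_sum_is_exact(self):
        rng = np.random.default_rng(0)
        durs = 1.4 + rng.uniform(-0.2, 0.2, 15)
        recs = _records(durs)
        total = sum(r.duration for r in recs)
        assert total == pytest.approx(recs[-1].t_end - recs[0].t_start,
                                      abs=1e-12)

    def test_block_mean_depends_only_on_outer_boundaries(self):
        # perturb interior boundaries only: block means must not change
        rng = np.random.default_rng(1)
        durs = np.full(10, 1.5)
        recs_a = _records(durs)
        bounds = np.concatenate([[0.0], np.cumsum(durs)])
        noisy = bounds.copy()
        for k in range(1, 10):
            if k % 5 != 0:  # interior to its 5-cycle block
                noisy[k] += rng.normal(0, 0.05)
        recs_b = []
        for a, b in zip(noisy[:-1], noisy[1:]):
            recs_b.append(CycleRecord(t_start=a, t_end=b, duration=b - a,
                                      length=4.0, heading_change=0.0,
                                      heading_rate=0.0))
        out_a = average_over_n(recs_a, 5)
        out_b = average_over_n(recs_b, 5)
        assert [d for d, _ in out_a] == pytest.approx(
            [d for d, _ in out_b], abs=1e-12)

    def test_fewer_than_n_cycles_gives_empty(self):
        assert average_over_n(_records([1.5] * 3), 5) == []


class TestBlockDeviations:
    def test_exact_boundaries_give_zero_deviation(self):
        ev = 0.25 + np.arange(20) * 1.4
        dev = block_duration_deviations(ev, ev, n=5)
        assert dev.size == 3
        assert np.allclose(dev, 0.0, atol=1e-12)

    def test_interior_jitter_cancels_in_blocks(self):
        rng = np.random.default_rng(5)
        truth = np.arange(21) * 1.4
        det = truth.copy()
        jitter = rng.normal(0, 0.03, det.size)
        det += jitter
        dev5 = block_duration_deviations(det, truth, n=5)
        # only the outer boundary errors survive: |dev| <= (|e0|+|e5|)/(5T)
        for k, d in enumerate(dev5):
            bound = (abs(jitter[5 * k]) + abs(jitter[5 * k + 5])) / (5 * 1.4)
            assert abs(d) <= bound + 1e-12
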