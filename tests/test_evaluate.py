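"""Event matching, sensitivity, laterality accuracy and error statistics."""

import numpy as np
import pytest

from tpear.evaluate import (align_start, laterality_accuracy, match_events,
                            sensitivity, temporal_error_stats)
from tpear.events import GaitEvent
from tpear.exceptions import DataError
from tpear.temporal import build_cycles


def _ic(sample, side="U"):
    return GaitEvent(sample, "IC", side)


def brute_force_assignment(truth_s, det_s, tol):
    """Exhaustive one-to-one assignment: max pairs, then min total offset."""
    best = (0, float("inf"))

    def rec(i, used, cost, npairs):
        nonlocal best
        if i == len(truth_s):
            cand = (npairs, cost)
            if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
            return
        rec(i + 1, used, cost, npairs)
        for j in range(len(det_s)):
            if j not in used and abs(truth_s[i] - det_s[j]) <= tol:
                used.add(j)
                rec(i + 1, used, cost + abs(truth_s[i] - det_s[j]), npairs + 1)
                used.remove(j)

    rec(0, set(), 0.0, 0)
    return best


class TestAlignStart:
    def test_delayed_copy_recovers_lag(self, rng):
        x = rng.normal(size=500)
        delayed = np.concatenate([np.zeros(17), x])[:500]
        assert align_start(delayed, x) == 17

    def test_identical_series_lag_zero(self, rng):
        x = rng.normal(size=300)
        assert align_start(x, x) == 0

    def test_noisy_shifted_sine_within_one_sample(self):
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        ref = np.sin(2 * np.pi * 1.3 * t) * np.exp(-0.1 * t)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            true_lag = int(rng.integers(-30, 30))
            shifted = np.roll(ref, true_lag) + rng.normal(0, 0.1, ref.shape)
            assert abs(align_start(shifted, ref) - true_lag) <= 1

    def test_flat_series_raises(self):
        with pytest.raises(DataError):
            align_start(np.zeros(100), np.ones(100))


class TestMatchEvents:
    def test_pair_within_300ms(self):
        m = match_events([_ic(500)], [_ic(525)], fs=100.0)
        assert len(m.pairs) == 1
        assert m.pairs[0][2] == pytest.approx(0.25)

    def test_beyond_300ms_is_fn_plus_fp(self):
        m = match_events([_ic(500)], [_ic(535)], fs=100.0)
        assert len(m.pairs) == 0
        assert len(m.false_negatives) == 1
        assert len(m.false_positives) == 1

    def test_kinds_never_cross_match(self):
        m = match_events([_ic(500)], [GaitEvent(505, "TC")], fs=100.0)
        assert len(m.pairs) == 0

    def test_equals_exhaustive_enumeration(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            nt, nd = rng.integers(1, 13), rng.integers(1, 13)
            ts = np.sort(rng.integers(0, 1000, nt))
            ds = np.sort(rng.integers(0, 1000, nd))
            truth = [_ic(int(s)) for s in ts]
            det = [_ic(int(s)) for s in ds]
            m = match_events(truth, det, tolerance_s=0.3, fs=100.0)
            n_best, cost_best = brute_force_assignment(ts / 100, ds / 100, 0.3)
            assert len(m.pairs) == n_best
            assert sum(abs(o) for *_, o in m.pairs) == pytest.approx(cost_best)

    def test_symmetry_up_to_fn_fp_relabelling(self, rng):
        ts = np.sort(rng.integers(0, 2000, 15))
        ds = np.sort(rng.integers(0, 2000, 12))
        a = match_events([_ic(int(s)) for s in ts], [_ic(int(s)) for s in ds],
                         fs=100.0)
        b = match_events([_ic(int(s)) for s in ds], [_ic(int(s)) for s in ts],
                         fs=100.0)
        assert len(a.pairs) == len(b.pairs)
        assert len(a.false_negatives) == len(b.false_positives)
        assert len(a.false_positives) == len(b.false_negatives)


class TestSensitivity:
    def test_basic_arithmetic(self):
        truth = [_ic(i * 100) for i in range(100)]
        det = [_ic(i * 100) for i in range(99)]
        m = match_events(truth, det, fs=100.0)
        assert sensitivity(m, "IC") == pytest.approx(99.0)

    def test_nothing_detected_is_zero(self):
        m = match_events([_ic(i * 100) for i in range(5)], [], fs=100.0)
        assert sensitivity(m, "IC") == 0.0

    def test_all_matched_is_100(self):
        truth = [_ic(i * 100) for i in range(10)]
        m = match_events(truth, truth, fs=100.0)
        assert sensitivity(m, "IC") == 100.0

    def test_no_truth_is_not_applicable(self):
        m = match_events([], [_ic(100)], fs=100.0)
        assert sensitivity(m, "IC") is None

    def test_bounded_in_0_100(self, rng):
        ts = np.sort(rng.integers(0, 3000, 20))
        ds = np.sort(rng.integers(0, 3000, 25))
        m = match_events([_ic(int(s)) for s in ts],
                         [_ic(int(s)) for s in ds], fs=100.0)
        s = sensitivity(m, "IC")
        assert 0.0 <= s <= 100.0


class TestLateralityAccuracy:
    def test_nine_of_ten(self):
        truth = [_ic(i * 100, "L") for i in range(10)]
        det = [_ic(i * 100, "L" if i else "R") for i in range(10)]
        m = match_events(truth, det, fs=100.0)
        assert laterality_accuracy(m) == pytest.approx(90.0)

    def test_all_agree(self):
        truth = [_ic(i * 100, "L" if i % 2 else "R") for i in range(10)]
        m = match_events(truth, truth, fs=100.0)
        assert laterality_accuracy(m) == 100.0

    def test_no_pairs_is_not_applicable(self):
        m = match_events([], [], fs=100.0)
        assert laterality_accuracy(m) is None

    def test_random_sides_near_fifty_percent(self):
        rng = np.random.default_rng(99)
        n = 1000
        truth = [_ic(i * 100, rng.choice(["L", "R"])) for i in range(n)]
        det = [_ic(i * 100, rng.choice(["L", "R"])) for i in range(n)]
        m = match_events(truth, det, fs=100.0)
        assert laterality_accuracy(m) == pytest.approx(50.0, abs=5.0)


def _stream(n_strides, fs=100.0, ic_shift=0, tc_shift=0):
    """Alternating L/R walking stream with both feet's TCs."""
    events = []
    stride, half, ds = 110, 55, 11
    for k in range(n_strides):
        events.append(GaitEvent(k * stride + ic_shift, "IC", "L"))
        events.append(GaitEvent(k * stride + ds + tc_shift, "TC", "U"))
        events.append(GaitEvent(k * stride + half + ic_shift, "IC", "R"))
        events.append(GaitEvent(k * stride + half + ds + tc_shift, "TC", "U"))
    return sorted(events, key=lambda e: e.sample)


class TestTemporalErrorStats:
    def test_self_evaluation_is_exactly_zero(self):
        truth = _stream(10)
        cycles = build_cycles(truth, 100.0)
        m = match_events(truth, truth, fs=100.0)
        stats = temporal_error_stats(cycles, cycles, m)
        for param in ("stride", "stance", "swing"):
            assert stats[param].mae_ms == 0.0
            assert stats[param].mse_ms == 0.0

    def test_late_ics_shift_stance_and_swing_not_stride(self):
        fs = 100.0
        truth = _stream(10)
        detected = _stream(10, ic_shift=2)  # every IC 20 ms late, TCs exact
        m = match_events(truth, detected, fs=fs)
        stats = temporal_error_stats(build_cycles(truth, fs),
                                     build_cycles(detected, fs), m)
        assert stats["stride"].mse_ms == pytest.approx(0.0)
        assert stats["stance"].mse_ms == pytest.approx(-20.0)
        assert stats["swing"].mse_ms == pytest.approx(20.0)

    def test_uniform_jitter_matches_analytic_variance(self):
        # strides bounded by two ICs with independent uniform(-30, 30) ms
        # jitter: SE = d2 - d1, mean 0, SD = sqrt(2) * 60/sqrt(12) ms
        rng = np.random.default_rng(5)
        fs = 1000.0
        n = 501
        stride = 1100
        truth, detected = [], []
        jitter = rng.integers(-30, 31, size=n)
        for k in range(n):
            truth.append(GaitEvent(k * stride, "IC", "L"))
            truth.append(GaitEvent(k * stride + 660, "TC", "U"))
            detected.append(GaitEvent(k * stride + int(jitter[k]), "IC", "L"))
            detected.append(GaitEvent(k * stride + 660, "TC", "U"))
        m = match_events(truth, detected, fs=fs)
        stats = temporal_error_stats(build_cycles(truth, fs),
                                     build_cycles(detected, fs), m)
        sd_analytic = np.sqrt(2.0) * 60.0 / np.sqrt(12.0)
        assert stats["stride"].mse_ms == pytest.approx(0.0, abs=3.0)
        assert stats["stride"].sd_se_ms == pytest.approx(sd_analytic, rel=0.15)

    def test_mae_bounds_signed_error(self, rng):
        truth = _stream(20)
        detected = _stream(20, ic_shift=1, tc_shift=-2)
        m = match_events(truth, detected, fs=100.0)
        stats = temporal_error_stats(build_cycles(truth, 100.0),
                                     build_cycles(detected, 100.0), m)
        for s in stats.values():
            assert s.mae_ms >= abs(s.mse_ms)
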