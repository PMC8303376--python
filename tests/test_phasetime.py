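"""Phase signals, smoothing, batch detection, sequential matching, coverage."""

import math

import numpy as np
import pytest

from cranioflow.detector import DetectionLog, DetectionRecord
from cranioflow.labelspace import PHASES, TOOL_NAMES, phase_tools
from cranioflow.phasetime import (
    PhaseEstimationConfig,
    build_phase_signal,
    estimate_phases,
    find_batches,
    phase_coverage,
    smooth_and_binarize,
)
from cranioflow.synthdata import NoiseModel, default_timeline, simulate_detection_log


def _log_from_sets(sets, frame_rate=15.0):
    recs = []
    for i, det in enumerate(sets):
        p = tuple(0.9 if n in det else 0.1 for n in TOOL_NAMES)
        recs.append(DetectionRecord(i, i / frame_rate, p, frozenset(det)))
    return DetectionLog(recs, frame_rate=frame_rate)


class TestPhaseSignal:
    def test_environment_is_ignored(self):
        log = _log_from_sets([{"Scalpel", "Environment"}])
        assert build_phase_signal(log, "P1").tolist() == [1]

    def test_wrong_phase_tool_gives_zero(self):
        log = _log_from_sets([{"Scalpel", "Motor"}])
        assert build_phase_signal(log, "P1").tolist() == [0]

    def test_missing_right_tool_gives_zero(self):
        log = _log_from_sets([{"SOGuide"}])  # P3 needs SOGuide AND FTGuide
        assert build_phase_signal(log, "P3").tolist() == [0]

    def test_empty_detection_never_matches(self):
        log = _log_from_sets([set()])
        for phase in PHASES:
            assert build_phase_signal(log, phase).tolist() == [0]

    def test_relaxed_rule_tolerates_extra_tools(self):
        log = _log_from_sets([{"Scalpel", "Motor"}])
        assert build_phase_signal(log, "P1", relaxed=True).tolist() == [1]


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        cfg = PhaseEstimationConfig(window=5)
        assert smooth_and_binarize(np.ones(20), cfg).tolist() == [1] * 20
        assert smooth_and_binarize(np.zeros(20), cfg).tolist() == [0] * 20

    def test_hand_computed_window3(self):
        # averages with edge shrink: [1/2, 2/3, 1, 2/3, 1/2] -> [0,1,1,1,0]
        cfg = PhaseEstimationConfig(window=3)
        out = smooth_and_binarize(np.array([0, 1, 1, 1, 0]), cfg)
        assert out.tolist() == [0, 1, 1, 1, 0]

    def test_isolated_one_removed(self):
        cfg = PhaseEstimationConfig(window=3)
        sig = np.zeros(11)
        sig[5] = 1
        assert smooth_and_binarize(sig, cfg).sum() == 0

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            smooth_and_binarize(np.ones(5), PhaseEstimationConfig(window=7))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            PhaseEstimationConfig(window=4)


class TestFindBatches:
    def test_enumerated_example(self):
        assert find_batches([0, 1, 1, 0, 1]) == [(1, 2), (4, 4)]

    def test_all_zeros(self):
        assert find_batches([0, 0, 0]) == []

    def test_runs_touching_ends_included(self):
        assert find_batches([1, 1, 0, 1]) == [(0, 1), (3, 3)]
        assert find_batches([1]) == [(0, 0)]

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            find_batches([0, 2, 1])

    def test_against_brute_force_scan(self, rng):
        def brute(v):
            runs, start = [], None
            for i, b in enumerate(v):
                if b and start is None:
                    start = i
                if not b and start is not None:
                    runs.append((start, i - 1))
                    start = None
            if start is not None:
                runs.append((start, len(v) - 1))
            return runs

        for _ in range(1000):
            v = rng.integers(0, 2, size=rng.integers(1, 40)).tolist()
            assert find_batches(v) == brute(v)


class TestEstimatePhases:
    def test_hits_before_cursor_discarded(self):
        # spurious P2 detections at 0..8 precede P1 (frames 9..25); the
        # real P2 occurrence is 40..50.  P1 sets the cursor to 25, so the
        # early P2 batch must be discarded.
        sets = []
        for t in range(60):
            if t <= 8:
                sets.append(phase_tools("P2"))
            elif t <= 25:
                sets.append(phase_tools("P1"))
            elif 40 <= t <= 50:
                sets.append(phase_tools("P2"))
            else:
                sets.append(set())
        log = _log_from_sets(sets)
        cfg = PhaseEstimationConfig(window=1)
        ests = estimate_phases(log, PHASES[:2], cfg)
        assert ests[0].raw_batch == (9, 25)
        assert ests[1].raw_batch == (40, 50)

    def test_boundary_is_rounded_midpoint(self):
        sets = [phase_tools("P1")] * 101 + [set()] * 9 + [phase_tools("P2")] * 40
        log = _log_from_sets(sets)
        ests = estimate_phases(log, PHASES[:2], PhaseEstimationConfig(window=1))
        assert ests[0].raw_batch == (0, 100)
        assert ests[1].raw_batch == (110, 149)
        # midpoint of end 100 and start 110 is 105
        assert ests[0].final_interval == (0, 105)
        assert ests[1].final_interval == (106, 149)

    def test_undetected_phase_flagged_and_cursor_kept(self):
        sets = [phase_tools("P1")] * 30 + [phase_tools("P3")] * 30
        log = _log_from_sets(sets)
        ests = estimate_phases(log, PHASES[:3], PhaseEstimationConfig(window=5))
        assert [e.detected for e in ests] == [True, False, True]
        assert ests[1].final_interval is None

    def test_zero_noise_recovery_within_half_window(self, short_timeline, clean_log):
        cfg = PhaseEstimationConfig(window=15)
        ests = estimate_phases(clean_log, PHASES, cfg)
        tol = math.ceil(cfg.window / 2)
        assert all(e.detected for e in ests)
        for e in ests:
            gs, ge = short_timeline.interval(e.phase)
            ps, pe = e.final_interval
            assert abs(ps - gs) <= tol
            assert abs(pe - ge) <= tol

    def test_final_intervals_ordered_and_disjoint_under_noise(self):
        tl = default_timeline(1100)
        for seed in range(5):
            log = simulate_detection_log(
                tl, NoiseModel(flip_rate=0.05, jitter=10), seed=seed
            )
            ests = estimate_phases(log, PHASES, PhaseEstimationConfig(window=45, threshold=0.4))
            prev_end = -1
            for e in ests:
                if e.detected:
                    s, t = e.final_interval
                    assert prev_end < s <= t
                    prev_end = t


class TestCoverage:
    def test_prediction_enclosing_truth_is_100(self):
        assert phase_coverage((10, 20), (8, 22)) == 100.0

    def test_half_covered(self):
        assert phase_coverage((10, 19), (15, 19)) == 50.0

    def test_disjoint_is_zero(self):
        assert phase_coverage((10, 20), (30, 40)) == 0.0

    def test_undetected_is_zero(self):
        assert phase_coverage((10, 20), None) == 0.0

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            phase_coverage((20, 10), (10, 20))
        with pytest.raises(ValueError):
            phase_coverage((10, 20), (20, 10))

    def test_enlarging_prediction_never_decreases_coverage(self, rng):
        for _ in range(200):
            gs = int(rng.integers(0, 50))
            ge = gs + int(rng.integers(0, 50))
            ps = int(rng.integers(0, 80))
            pe = ps + int(rng.integers(0, 50))
            base = phase_coverage((gs, ge), (ps, pe))
            assert phase_coverage((gs, ge), (ps - 1, pe)) >= base
            assert phase_coverage((gs, ge), (ps, pe + 1)) >= base
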