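import dataclasses

import numpy as np
import pytest

from thighgait import (
    DetectionConfig,
    GroundTruth,
    ImuRecording,
    SimulationSpec,
    compute_features,
    detect_events,
    match_events,
    simulate,
)
from thighgait.event_detection import (
    calibrate_thresholds,
    cycles_to_event_times,
    detect_ic,
    detect_oic,
    detect_oto,
    detect_to,
    find_local_extrema,
    ic_windows,
)

FS = 100.0


def _events_within(cycles, truth, kind, tol_s):
    """Max |detected - truth| over interior strides, asserting full recovery."""
    det = cycles_to_event_times(cycles)[kind]
    ref = truth.events[kind][1:-1]  # interior strides only
    worst = 0.0
    for r in ref:
        d = det[np.argmin(np.abs(det - r))]
        worst = max(worst, abs(d - r))
    assert worst <= tol_s
    return worst


class TestFindLocalExtrema:
    def test_sine_maxima_analytic(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * t)  # maxima at t = 0.25 + k
        idx = find_local_extrema(x, "max", min_separation=50)
        assert list(idx) == [25 + 100 * k for k in range(10)]

    def test_constant_series_empty(self):
        assert find_local_extrema(np.ones(100), "max").size == 0
        assert find_local_extrema(np.ones(100), "min").size == 0

    def test_close_maxima_larger_survives(self):
        x = np.zeros(100)
        x[40] = 1.0
        x[50] = 2.0  # 10 samples apart
        idx = find_local_extrema(x, "max", min_separation=30)
        # brute-force oracle over all candidate pairs: among extrema closer
        # than min_separation the more extreme must survive
        raw = [i for i in range(1, 99) if x[i] > x[i - 1] and x[i] > x[i + 1]]
        expected = [i for i in raw
                    if all(x[j] <= x[i] for j in raw if j != i and abs(j - i) < 30)]
        assert list(idx) == expected == [50]

    def test_plateau_first_sample(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        assert list(find_local_extrema(x, "max")) == [1]

    def test_minima_mode(self):
        t = np.arange(500) / FS
        x = np.cos(2 * np.pi * t)  # minima at t = 0.5 + k
        idx = find_local_extrema(x, "min", min_separation=50)
        assert list(idx) == [50, 150, 250, 350, 450]

    def test_invalid_args(self):
        with pytest.raises(ValueError, match="mode"):
            find_local_extrema(np.zeros(10), "peak")
        with pytest.raises(ValueError, match="min_separation"):
            find_local_extrema(np.zeros(10), "max", 0)

    def test_short_series_empty(self):
        assert find_local_extrema(np.array([1.0]), "max").size == 0


class TestDetectTo:
    def test_simulated_noiseless_within_20ms(self, noiseless_sim):
        rec, truth = noiseless_sim
        idx = detect_to(rec.gyro_pitch, -0.5, min_separation=30)
        det = idx / FS
        for r in truth.events["TO"]:
            assert np.min(np.abs(det - r)) <= 0.020

    def test_zero_signal_empty(self):
        assert detect_to(np.zeros(100), -0.5).size == 0

    def test_threshold_below_global_min_empty(self, noiseless_sim):
        rec, _ = noiseless_sim
        floor = rec.gyro_pitch.min() - 1.0
        assert detect_to(rec.gyro_pitch, floor, 30).size == 0

    def test_requires_negative_threshold(self):
        with pytest.raises(ValueError):
            detect_to(np.zeros(10), 0.5)


class TestIcWindows:
    def test_cosine_windows_contain_ic(self):
        # az_bp = cos(4*pi*phase) over 3 strides of 1 s: minima at phases
        # 0.25 and 0.75 of each stride; IC (phase 1.0) inside [0.75, 1.25)
        t = np.arange(300) / FS
        x = np.cos(4 * np.pi * t)
        wins = ic_windows(x, min_separation=30)
        ics = [100, 200]  # phase-1.0 samples with an earlier+later minimum
        for ic in ics:
            containing = [w for w in wins if w[0] < ic < w[1]]
            assert len(containing) == 1

    def test_monotone_series_empty(self):
        assert ic_windows(np.arange(100.0)) == []

    def test_simulated_each_window_one_ic(self, noiseless_sim, config):
        rec, truth = noiseless_sim
        feats = compute_features(rec, config)
        wins = ic_windows(feats.az_bp, min_separation=30)
        assert len(wins) >= 19
        hits = 0
        for w in wins:
            inside = [
                ic for ic in truth.events["IC"]
                if w[0] < ic * FS < w[1]
            ]
            assert len(inside) <= 1
            hits += len(inside)
        assert hits >= 19


class TestDetectIc:
    def test_branch_a_earliest_after_gate(self):
        acc_x = np.zeros(100)
        acc_x[40] = 2.0  # gate opens at sample 40
        acc_z = np.zeros(100)
        acc_z[35] = 3.0
        acc_z[45] = 3.0
        got = detect_ic(acc_x, acc_z, (20, 80), th_acc_x=1.5, th_acc_z=1.5)
        # oracle: brute force over supra-threshold peaks at/after the gate
        peaks = [i for i in range(21, 79)
                 if acc_z[i] > acc_z[i - 1] and acc_z[i] > acc_z[i + 1]
                 and acc_z[i] > 1.5]
        expected = min(p for p in peaks if p >= 40)
        assert got == expected == 45

    def test_branch_b_largest_peak(self):
        acc_x = np.zeros(100)  # never crosses threshold
        acc_z = np.zeros(100)
        acc_z[30] = 2.0
        acc_z[60] = 3.5
        assert detect_ic(acc_x, acc_z, (10, 90), 1.5, 1.5) == 60

    def test_flat_zero_absent(self):
        assert detect_ic(np.zeros(50), np.zeros(50), (5, 45), 1.5, 1.5) is None

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            detect_ic(np.zeros(50), np.zeros(50), (20, 20), 1.5, 1.5)


class TestDetectOto:
    def test_simulated_within_20ms(self, noiseless_sim, config):
        rec, truth = noiseless_sim
        cycles = detect_events(rec, config)
        _events_within(cycles, truth, "OTO", 0.020)

    def test_monotone_decreasing_absent(self):
        x = -np.arange(100.0)
        assert detect_oto(x, 10, 5, 90) is None

    def test_two_peaks_earlier_wins(self):
        x = np.zeros(100)
        x[40] = 1.0
        x[80] = 2.0
        got = detect_oto(x, 10, 5, 95)
        # brute-force first-peak oracle
        peaks = [i for i in range(16, 94) if x[i] > x[i - 1] and x[i] > x[i + 1]]
        assert got == peaks[0] == 40

    def test_bad_range_absent(self):
        assert detect_oto(np.zeros(100), 50, 60, 80) is None


class TestDetectOic:
    def test_sine_crossing_at_half_period(self):
        t = np.arange(100) / FS
        x = np.sin(2 * np.pi * t)
        x[np.abs(x) < 1e-12] = 0.0  # snap representation noise to exact zero
        assert detect_oic(x, 10, 100) == 50

    def test_all_positive_absent(self):
        assert detect_oic(np.ones(100), 10, 100) is None

    def test_simulated_within_20ms(self, noiseless_sim, config):
        rec, truth = noiseless_sim
        cycles = detect_events(rec, config)
        _events_within(cycles, truth, "OIC", 0.020)


class TestDetectEvents:
    def test_noiseless_recovery(self, noiseless_sim, config):
        rec, truth = noiseless_sim
        cycles = detect_events(rec, config)
        interior = [c for c in cycles if not c.edge]
        assert 18 <= len(interior) <= 19
        assert all(c.valid for c in interior)
        for kind in ("IC", "OTO", "OIC", "TO"):
            _events_within(cycles, truth, kind, 0.020)

    def test_event_ordering_in_valid_cycles(self, noiseless_sim, config):
        rec, _ = noiseless_sim
        for c in detect_events(rec, config):
            if c.valid:
                assert (c.ic.time < c.oto.time < c.oic.time < c.to.time
                        < c.next_ic.time)

    def test_white_noise_no_valid_cycles(self, config):
        rng = np.random.default_rng(99)
        n = 3000
        rec = ImuRecording(FS, *(rng.normal(0, 0.2, n) for _ in range(6)))
        try:
            cycles = detect_events(rec, config)
        except ValueError:
            cycles = []  # degenerate spectrum is an acceptable outcome
        assert sum(c.valid for c in cycles) == 0

    def test_determinism(self, noiseless_sim, config):
        rec, _ = noiseless_sim
        c1 = detect_events(rec, config)
        c2 = detect_events(rec, config)
        assert [(c.ic.time, c.valid) for c in c1] == [(c.ic.time, c.valid) for c in c2]

    def test_too_short_errors(self, config):
        rec, _ = simulate(SimulationSpec(n_strides=1, seed=0))
        # 1 stride + padding is under the 3-stride precondition
        with pytest.raises(ValueError, match="too short"):
            detect_events(rec, config)

    def test_translation_equivariance(self, config):
        # prepending whole strides of the same periodic signal shifts all
        # event times by the same whole number of strides
        short, _ = simulate(SimulationSpec(n_strides=10, seed=5))
        longer, _ = simulate(SimulationSpec(n_strides=13, seed=5))
        t_short = cycles_to_event_times(detect_events(short, config))
        t_long = cycles_to_event_times(detect_events(longer, config))
        shift = 0.0  # same pad, same first IC: shift is zero strides here
        for kind in ("IC", "OTO", "OIC", "TO"):
            a = t_short[kind]
            b = t_long[kind][: a.size]
            assert np.all(np.abs(b - a - shift) <= 1.0 / FS + 1e-9)


@pytest.fixture(scope="module")
def calib_data():
    rec, truth = simulate(SimulationSpec(n_strides=12, seed=11))
    return [rec], [truth]


class TestCalibrateThresholds:
    def test_grid_with_oracle_point_reaches_f1_one(self, calib_data):
        recs, refs = calib_data
        grid = {
            "th_to_gyro": [-1.5, -0.5],
            "th_acc_x": [1.5, 3.0],
            "th_acc_z": [1.5, 3.0],
            "oto_delay": [0.05, 0.10],
        }
        res = calibrate_thresholds(recs, refs, grid)
        assert res.f1 == 1.0

    def test_single_point_grid_returned(self, calib_data):
        recs, refs = calib_data
        grid = {"th_to_gyro": [-9.0]}  # hopeless threshold, still returned
        res = calibrate_thresholds(recs, refs, grid)
        assert res.config.th_to_gyro == -9.0

    def test_tie_break_prefers_grid_centre(self, calib_data):
        recs, refs = calib_data
        # all three thresholds sit between 0 and the trough depth, so the
        # detections (and scores) are identical -> centre point wins
        grid = {"th_to_gyro": [-0.7, -0.5, -0.3]}
        res = calibrate_thresholds(recs, refs, grid)
        scores = [(r["f1"], r["mean_abs_error_ms"]) for r in res.table]
        assert len(set(scores)) == 1
        assert res.config.th_to_gyro == -0.5

    def test_recording_order_invariance(self):
        pair = [simulate(SimulationSpec(n_strides=8, seed=s)) for s in (1, 2)]
        recs = [p[0] for p in pair]
        refs = [p[1] for p in pair]
        grid = {"th_to_gyro": [-1.0, -0.5], "th_acc_z": [1.5, 2.0]}
        a = calibrate_thresholds(recs, refs, grid)
        b = calibrate_thresholds(recs[::-1], refs[::-1], grid)
        assert dataclasses.asdict(a.config) == dataclasses.asdict(b.config)

    def test_empty_grid_errors(self, calib_data):
        recs, refs = calib_data
        with pytest.raises(ValueError, match="grid"):
            calibrate_thresholds(recs, refs, {})

    def test_no_references_errors(self):
        with pytest.raises(ValueError, match="recording"):
            calibrate_thresholds([], [], {"th_to_gyro": [-0.5]})
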