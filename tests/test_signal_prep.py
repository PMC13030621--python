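import numpy as np
import pytest

from gaitval.signal_prep import (
    EventSet,
    InsufficientStridesError,
    NoCompleteCycleError,
    NoDropError,
    NoImpactError,
    NoProgressionError,
    PairingError,
    detect_drop_event,
    detect_events_imu,
    detect_events_zeni,
    detect_impact_time,
    fill_gaps,
    segment_cycles,
    synchronize,
)
from gaitval.synthetic_gait import simulate_sync_trial, simulate_walk


class TestImpactDetection:
    def test_synthetic_trial(self):
        trial = simulate_sync_trial(2.5, seed=0)
        assert detect_impact_time(trial.accel) == pytest.approx(2.5, abs=0.005)

    def test_constant_gravity_no_impact(self):
        accel = np.tile([0.0, 0.0, 1.0], (512, 1))
        with pytest.raises(NoImpactError):
            detect_impact_time(accel)

    def test_largest_of_two_impacts_wins(self):
        t = np.arange(0, 4.0, 1 / 256)
        accel = np.zeros((t.size, 3))
        accel[:, 2] = 1.0
        accel[:, 2] += 4.1 * np.exp(-0.5 * ((t - 1.0) / 0.01) ** 2)
        accel[:, 2] += 9.0 * np.exp(-0.5 * ((t - 3.0) / 0.01) ** 2)
        assert detect_impact_time(accel) == pytest.approx(3.0, abs=0.01)


class TestDropDetection:
    def test_synthetic_trial(self):
        trial = simulate_sync_trial(2.5, seed=0)
        assert detect_drop_event(trial.marker_z) == pytest.approx(2.5, abs=0.01)

    def test_flat_trajectory_error(self):
        with pytest.raises(NoDropError):
            detect_drop_event(np.full(500, 0.8))

    def test_shift_equivariance(self):
        trial = simulate_sync_trial(2.5, seed=0)
        shifted = np.concatenate([np.full(100, trial.marker_z[0]), trial.marker_z])
        t0 = detect_drop_event(trial.marker_z)
        t1 = detect_drop_event(shifted)
        assert t1 - t0 == pytest.approx(1.0, abs=1e-6)


class TestSynchronize:
    def test_single_pair_offset(self):
        res = synchronize([3.0], [1.0])
        assert res.offset == 2.0
        assert res.drift is None

    def test_two_pair_line_fit(self):
        # IMU-minus-marker offset grows 2.0 -> 2.6 over 599.4 s of marker time
        res = synchronize([10.0, 610.0], [8.0, 607.4])
        assert res.offset == pytest.approx(2.0, abs=0.01)
        assert abs(res.drift) == pytest.approx(0.6 / 599.4, rel=1e-9)
        assert res.residual == 0.0

    def test_identical_times(self):
        res = synchronize([5.0, 10.0], [5.0, 10.0])
        assert res.offset == 0.0
        assert res.drift == 0.0

    def test_mismatched_counts(self):
        with pytest.raises(PairingError):
            synchronize([1.0, 2.0], [1.0])

    def test_offset_recovery_from_trials(self):
        # impact on IMU clock shifted by a known offset
        trial = simulate_sync_trial(2.5, seed=1)
        t_imu = detect_impact_time(trial.accel) + 1.234
        t_marker = detect_drop_event(trial.marker_z)
        res = synchronize([t_imu], [t_marker])
        assert res.offset == pytest.approx(1.234, abs=0.01)

    def test_drift_recovery(self):
        # two sync trials bracketing a session with clock drift 1e-3 s/s
        truth_offset, truth_drift = 2.0, 1e-3
        marker_times = []
        imu_times = []
        for impact, base in ((2.5, 0.0), (2.5, 600.0)):
            trial = simulate_sync_trial(impact, seed=int(base))
            tm = detect_drop_event(trial.marker_z) + base
            ti = detect_impact_time(trial.accel) + base
            marker_times.append(tm)
            imu_times.append(ti + truth_offset + truth_drift * tm)
        res = synchronize(imu_times, marker_times)
        assert res.offset == pytest.approx(truth_offset, abs=0.02)
        assert res.drift == pytest.approx(truth_drift, rel=0.10)


class TestZeniDetector:
    def test_recovers_ground_truth(self):
        walk = simulate_walk(n_strides=10, seed=0)
        for side in ("left", "right"):
            ev = detect_events_zeni(
                walk.markers[f"{side}_heel"][:, 0],
                walk.markers[f"{side}_toe"][:, 0],
                walk.markers["sacrum"][:, 0],
                side=side,
            )
            gt = walk.events[side]
            assert len(ev.strikes[side]) == len(gt["strikes"])
            np.testing.assert_allclose(ev.strikes[side], gt["strikes"], atol=0.010)
            np.testing.assert_allclose(ev.offs[side], gt["offs"], atol=0.010)

    def test_direction_reversal_invariance(self):
        walk = simulate_walk(n_strides=6, seed=1)
        heel = walk.markers["left_heel"][:, 0]
        toe = walk.markers["left_toe"][:, 0]
        sac = walk.markers["sacrum"][:, 0]
        fwd = detect_events_zeni(heel, toe, sac, side="left")
        rev = detect_events_zeni(-heel, -toe, -sac, side="left")
        np.testing.assert_allclose(fwd.strikes["left"], rev.strikes["left"], atol=1e-9)

    def test_stationary_error(self):
        flat = np.zeros(1000)
        with pytest.raises(NoProgressionError):
            detect_events_zeni(flat, flat, flat)


class TestImuDetector:
    def test_recovers_ground_truth(self):
        walk = simulate_walk(n_strides=10, seed=0, clock_offset=0.0)
        for side in ("left", "right"):
            ev = detect_events_imu(walk.gyro_sagittal[side], side=side)
            gt = walk.events[side]
            assert len(ev.strikes[side]) == len(gt["strikes"])
            np.testing.assert_allclose(ev.strikes[side], gt["strikes"], atol=0.015)
            np.testing.assert_allclose(ev.offs[side], gt["offs"], atol=0.015)

    def test_zero_signal_error(self):
        with pytest.raises(InsufficientStridesError):
            detect_events_imu(np.zeros(2560))

    def test_amplitude_invariance(self):
        walk = simulate_walk(n_strides=6, seed=2, gyro_noise_sd=0.0)
        w = walk.gyro_sagittal["right"]
        e1 = detect_events_imu(w, side="right")
        e2 = detect_events_imu(2.0 * w, side="right")
        np.testing.assert_allclose(e1.strikes["right"], e2.strikes["right"], atol=1e-9)
        np.testing.assert_allclose(e1.offs["right"], e2.offs["right"], atol=1e-9)

    def test_cycle_count_agreement_with_markers(self):
        walk = simulate_walk(n_strides=8, seed=3)
        for side in ("left", "right"):
            ev_m = detect_events_zeni(
                walk.markers[f"{side}_heel"][:, 0],
                walk.markers[f"{side}_toe"][:, 0],
                walk.markers["sacrum"][:, 0],
                side=side,
            )
            ev_i = detect_events_imu(walk.gyro_sagittal[side], side=side)
            assert len(ev_m.strikes[side]) == len(ev_i.strikes[side])


class TestSegmentCycles:
    def test_five_strikes_four_cycles(self):
        times = np.arange(0, 6, 0.01)
        values = np.sin(times)
        events = EventSet(strikes={"left": np.array([1.0, 2.0, 3.0, 4.0, 5.0])})
        cycles = segment_cycles(times, values, events, "left")
        assert len(cycles) == 4
        assert [c.cycle_index for c in cycles] == [0, 1, 2, 3]

    def test_constant_stream(self):
        times = np.arange(0, 3, 0.01)
        events = EventSet(strikes={"left": np.array([0.5, 1.5, 2.5])})
        cycles = segment_cycles(times, np.full(times.size, 7.0), events, "left")
        for c in cycles:
            np.testing.assert_allclose(c.samples, 7.0)

    def test_linear_ramp_closed_form(self):
        # strikes at samples 0 and 200 of a 0 -> 20 deg ramp over 201 samples
        times = np.arange(201) / 100.0
        values = np.linspace(0.0, 20.0, 201)
        events = EventSet(strikes={"right": np.array([0.0, 2.0])})
        (cycle,) = segment_cycles(times, values, events, "right")
        np.testing.assert_allclose(cycle.samples, np.linspace(0.0, 20.0, 101), atol=1e-9)

    def test_too_few_strikes(self):
        times = np.arange(0, 2, 0.01)
        events = EventSet(strikes={"left": np.array([1.0])})
        with pytest.raises(NoCompleteCycleError):
            segment_cycles(times, np.zeros(times.size), events, "left")

    def test_duration_outlier_discarded(self):
        times = np.arange(0, 20, 0.01)
        values = np.sin(times)
        # median stride 1 s; the 5 s cycle deviates > 40% and is dropped
        strikes = np.array([1.0, 2.0, 3.0, 4.0, 9.0, 10.0, 11.0, 12.0])
        events = EventSet(strikes={"left": strikes})
        cycles = segment_cycles(times, values, events, "left")
        assert len(cycles) == 6


class TestFillGaps:
    def test_short_gap_interpolated(self):
        x = np.arange(100, dtype=float)
        x[10:15] = np.nan
        filled = fill_gaps(x, rate=100.0)
        np.testing.assert_allclose(filled, np.arange(100, dtype=float))

    def test_long_gap_rejected(self):
        x = np.arange(200, dtype=float)
        x[10:60] = np.nan  # 0.5 s at 100 Hz
        with pytest.raises(Exception, match="gap"):
            fill_gaps(x, rate=100.0)


class TestEventSet:
    def test_strictly_increasing_enforced(self):
        with pytest.raises(Exception, match="increasing"):
            EventSet(strikes={"left": np.array([2.0, 1.0])})

    def test_shifted(self):
        ev = EventSet(strikes={"left": np.array([1.0, 2.0])}, offs={"left": np.array([0.5])})
        sh = ev.shifted(1.5)
        np.testing.assert_allclose(sh.strikes["left"], [2.5, 3.5])
        np.testing.assert_allclose(sh.offs["left"], [2.0])
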