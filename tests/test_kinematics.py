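import numpy as np
import pandas as pd
import pytest

from graspadapt import kinematics as kin
from graspadapt.simulate import TrajectorySpec, simulate_trajectory


def _flat_trajectory(n=2000, fs=500.0):
    t = np.arange(n) / fs
    pos = {m: np.tile([float(i), 0.0, 0.0], (n, 1)) for i, m in enumerate(kin.MARKERS)}
    return kin.Trajectory(fs, t, pos)


class TestInterpolation:
    def test_complete_trace_untouched(self):
        traj = _flat_trajectory()
        out, mask = kin.interpolate_missing(traj)
        assert not mask.any()
        for m in kin.MARKERS:
            np.testing.assert_array_equal(out.positions[m], traj.positions[m])

    def test_cubic_gap_filled_exactly(self):
        # cubic splines reproduce cubic polynomials exactly
        n, fs = 500, 500.0
        t = np.arange(n) / fs
        poly = 3.0 + 40 * t - 25 * t**2 + 10 * t**3
        traj = _flat_trajectory(n, fs)
        traj.positions["thumb"][:, 1] = poly
        truth = traj.positions["thumb"][:, 1].copy()
        traj.positions["thumb"][200:220] = np.nan
        out, mask = kin.interpolate_missing(traj)
        np.testing.assert_allclose(out.positions["thumb"][:, 1], truth, atol=1e-9)
        assert mask[200:220].all() and mask.sum() == 20

    def test_boundary_gaps_left_missing(self):
        traj = _flat_trajectory(500)
        traj.positions["index"][:10] = np.nan
        traj.positions["index"][-7:] = np.nan
        out, mask = kin.interpolate_missing(traj)
        assert np.isnan(out.positions["index"][:10]).all()
        assert np.isnan(out.positions["index"][-7:]).all()
        assert not mask.any()  # nothing was filled

    def test_nearly_empty_marker_rejected(self):
        traj = _flat_trajectory(100)
        traj.positions["wrist"][3:] = np.nan
        with pytest.raises(ValueError, match="fewer than 4"):
            kin.interpolate_missing(traj)


class TestSmoothing:
    def test_polynomials_pass_through(self):
        n, fs = 1000, 500.0
        t = np.arange(n) / fs
        traj = _flat_trajectory(n, fs)
        traj.positions["thumb"][:, 0] = 5.0           # constant
        traj.positions["thumb"][:, 1] = 100.0 * t      # linear ramp
        out = kin.smooth(traj)
        np.testing.assert_allclose(out.positions["thumb"][:, 0], 5.0, atol=1e-9)
        np.testing.assert_allclose(out.positions["thumb"][:, 1], 100.0 * t, atol=1e-8)

    def test_white_noise_attenuated_on_sine(self, rng):
        n, fs = 2000, 500.0
        t = np.arange(n) / fs
        clean = 30 * np.sin(2 * np.pi * 1.5 * t)
        traj = _flat_trajectory(n, fs)
        traj.positions["index"][:, 2] = clean + rng.normal(0, 1.0, n)
        out = kin.smooth(traj)
        mid = slice(200, -200)  # judge away from the edges
        v_in = np.var(traj.positions["index"][mid, 2] - clean[mid])
        v_out = np.var(out.positions["index"][mid, 2] - clean[mid])
        assert v_out < 0.5 * v_in

    def test_window_is_200ms_and_odd(self):
        assert kin._window_frames(500.0) == 101
        assert kin._window_frames(200.0) == 41

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            kin.smooth(_flat_trajectory(50, 500.0))


class TestSegmentation:
    def test_stationary_markers_never_start(self):
        with pytest.raises(kin.SegmentationError, match="onset"):
            kin.detect_movement_start(_flat_trajectory())

    def test_onset_close_to_construction(self, main_traj_spec):
        traj = simulate_trajectory(main_traj_spec, 80.0, 44.0)
        sm = kin.smooth(traj)
        start = kin.detect_movement_start(sm)
        # minimum-jerk transport over 300 mm in 1 s crosses 0.05 m/s about
        # 81 ms after movement onset (9000*tau^2*(1-tau)^2 = 50 mm/s)
        expected = main_traj_spec.start_delay + 0.081
        assert sm.t[start] == pytest.approx(expected, abs=0.05)

    def test_single_frame_spikes_do_not_trigger_onset(self):
        traj = _flat_trajectory()
        # alternate large jumps: speed exceeds threshold on isolated frames only
        traj.positions["thumb"][::10, 1] += 5.0
        traj.positions["index"][::10, 1] += 5.0
        with pytest.raises(kin.SegmentationError):
            kin.detect_movement_start(traj)

    @pytest.mark.parametrize("experiment, thresholds", [
        ("pilot", (0.1, 300.0)), ("main", (0.075, 150.0)),
    ])
    def test_touch_criteria_per_experiment(self, experiment, thresholds):
        assert kin.TOUCH_CRITERIA[experiment] == thresholds

    def test_touch_found_near_proximity_crossing(self, main_traj_spec):
        traj = simulate_trajectory(main_traj_spec, 80.0, 44.0)
        sm = kin.smooth(traj)
        start = kin.detect_movement_start(sm)
        touch = kin.detect_touch(sm, start, (0, 0, 0), "main")
        # midpoint crosses the 150 mm radius halfway through the reach
        t_cross = main_traj_spec.start_delay + 0.5 * main_traj_spec.movement_time
        assert sm.t[touch] == pytest.approx(t_cross, abs=0.1)

    def test_deceleration_far_from_object_skipped(self):
        # slow aperture while still 400 mm away must not count as touch
        n, fs = 3000, 500.0
        t = np.arange(n) / fs
        traj = _flat_trajectory(n, fs)
        y = np.where(t < 2.0, -400.0 + 100 * t, -200.0 + np.maximum(0, t - 4.0))
        y = np.where(t >= 4.0, np.minimum(0.0, -200.0 + 300 * (t - 4.0)), y)
        for m, off in (("thumb", -30.0), ("index", 30.0)):
            traj.positions[m][:, 1] = y
            traj.positions[m][:, 0] = off
        start = kin.detect_movement_start(traj)
        touch = kin.detect_touch(traj, start, (0, 0, 0), "main")
        assert traj.t[touch] > 2.0  # not during the early far-away pause

    def test_unknown_experiment_label(self):
        with pytest.raises(ValueError, match="unknown experiment"):
            kin.detect_touch(_flat_trajectory(), 0, (0, 0, 0), "replication")


class TestMgaExtraction:
    def test_construction_oracle(self, main_traj_spec):
        for mga, obj in ((65.0, 40.0), (80.0, 44.0), (90.0, 60.0)):
            traj = simulate_trajectory(main_traj_spec, mga, obj)
            seg = kin.segment_trial(traj, (0.0, 0.0, 0.0), "main")
            assert seg.mga_mm == pytest.approx(mga, abs=0.5)

    def test_monotone_closing_peaks_at_start(self):
        n, fs = 1000, 500.0
        traj = _flat_trajectory(n, fs)
        ap = np.linspace(90.0, 40.0, n)
        traj.positions["thumb"][:, 0] = -ap / 2
        traj.positions["index"][:, 0] = ap / 2
        mga, idx = kin.extract_mga(traj, 100, 900)
        assert idx == 100
        assert mga == pytest.approx(ap[100])

    def test_tie_breaks_to_earliest_frame(self):
        traj = _flat_trajectory(1000)
        ap = np.full(1000, 60.0)
        ap[[300, 600]] = 75.0  # two equal maxima
        traj.positions["thumb"][:, 0] = -ap / 2
        traj.positions["index"][:, 0] = ap / 2
        _, idx = kin.extract_mga(traj, 0, 1000)
        assert idx == 300

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="start < touch"):
            kin.extract_mga(_flat_trajectory(), 50, 50)


class TestExclusions:
    @staticmethod
    def _base_table(n=12):
        rng = np.random.default_rng(7)
        return pd.DataFrame({
            "v_mm": [40.0] * n, "h_mm": [44.0] * n,
            "mga_mm": 75.0 + rng.normal(0, 1.0, n),
            "mga_on_interpolated": False, "missing_fraction": 0.0,
        })

    def test_implausibly_small_mga_fires(self):
        tbl = self._base_table()
        tbl.loc[0, "mga_mm"] = 38.0  # below the 44 mm felt object
        out = kin.apply_exclusions(tbl)
        assert out.loc[0, "flag_mga_below_object"]
        assert out.loc[0, "excluded"]

    def test_missing_frames_rule_at_20_percent(self):
        tbl = self._base_table()
        tbl.loc[1, "missing_fraction"] = 0.25
        tbl.loc[2, "missing_fraction"] = 0.20  # boundary: not "more than 20%"
        out = kin.apply_exclusions(tbl)
        assert out.loc[1, "flag_missing_frames"]
        assert not out.loc[2, "flag_missing_frames"]

    def test_interpolated_mga_rule(self):
        tbl = self._base_table()
        tbl.loc[3, "mga_on_interpolated"] = True
        out = kin.apply_exclusions(tbl)
        assert out.loc[3, "flag_interpolated_mga"] and out.loc[3, "excluded"]

    def test_outlier_rule_is_3_iqr_from_cell_median(self):
        # constructed cell: median 75, IQR 6 -> 95 exceeds 75 + 3*6 = 93
        vals = [70.0, 72.0, 74.0, 76.0, 78.0, 80.0, 95.0]
        tbl = pd.DataFrame({
            "v_mm": 40.0, "h_mm": 44.0, "mga_mm": vals,
            "mga_on_interpolated": False, "missing_fraction": 0.0,
        })
        med = tbl["mga_mm"].median()
        iqr = tbl["mga_mm"].quantile(0.75) - tbl["mga_mm"].quantile(0.25)
        assert 95.0 > med + 3 * iqr
        out = kin.apply_exclusions(tbl)
        assert out["flag_mga_outlier"].tolist() == [False] * 6 + [True]

    def test_singleton_cell_skips_outlier_rule(self):
        tbl = self._base_table(1)
        tbl.loc[0, "mga_mm"] = 200.0
        out = kin.apply_exclusions(tbl)
        assert not out.loc[0, "flag_mga_outlier"]

    def test_excluded_is_or_of_flags(self):
        out = kin.apply_exclusions(self._base_table())
        flags = out[["flag_interpolated_mga", "flag_missing_frames",
                     "flag_mga_below_object", "flag_mga_outlier"]].any(axis=1)
        assert out["excluded"].equals(flags)


class TestPipelineInvariants:
    def test_noise_free_recovery_and_zero_exclusions(self, main_traj_spec):
        rows = []
        rng = np.random.default_rng(1)
        mgas = rng.uniform(65, 85, 10)
        for mga in mgas:
            traj = simulate_trajectory(main_traj_spec, mga, 44.0)
            seg = kin.segment_trial(traj, (0.0, 0.0, 0.0), "main")
            rows.append({"v_mm": 40.0, "h_mm": 44.0, "mga_mm": seg.mga_mm,
                         "mga_on_interpolated": False,
                         "missing_fraction": seg.missing_fraction,
                         "true_mga": mga})
        tbl = kin.apply_exclusions(pd.DataFrame(rows))
        assert np.all(np.abs(tbl["mga_mm"] - tbl["true_mga"]) < 0.5)
        assert not tbl["excluded"].any()

    def test_rigid_translation_invariance(self, main_traj_spec):
        shift = np.array([123.0, -77.0, 31.0])
        traj = simulate_trajectory(main_traj_spec, 80.0, 44.0)
        moved = traj.copy()
        for m in kin.MARKERS:
            moved.positions[m] += shift
        seg0 = kin.segment_trial(traj, (0.0, 0.0, 0.0), "main")
        seg1 = kin.segment_trial(moved, tuple(shift), "main")
        assert seg1.mga_mm == pytest.approx(seg0.mga_mm, abs=1e-9)
        assert seg1.start_index == seg0.start_index
        assert seg1.touch_index == seg0.touch_index


class TestTrajectoryIO:
    def test_frame_round_trip_preserves_missing(self, main_traj_spec):
        traj = simulate_trajectory(main_traj_spec, 80.0, 44.0,
                                   rng=np.random.default_rng(0))
        traj.positions["thumb"][100:110] = np.nan
        back = kin.Trajectory.from_frame(traj.to_frame())
        assert back.sampling_rate == traj.sampling_rate
        for m in kin.MARKERS:
            np.testing.assert_allclose(back.positions[m], traj.positions[m],
                                       equal_nan=True)
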