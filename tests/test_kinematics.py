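"""Filtering, segmentation rules, and parameter extraction."""

import numpy as np
import pytest

from reachgrasp.errors import DataError, InvalidArgumentError
from reachgrasp.kinematics import (
    MovementWindow,
    SegmentationConfig,
    extract_grasp_params,
    extract_reach_params,
    lowpass,
    process_trial,
    segment_grasp,
    segment_reach_displacement,
    segment_reach_velocity,
    speed,
)
from reachgrasp.stimuli import Condition
from reachgrasp.synthgen import preset, simulate_trial, speed_profile
from reachgrasp.trajio import Trajectory, TrialRecord

from .conftest import EXP1_TABLE, EXP2_TABLE

SEG1 = SegmentationConfig(variant="displacement_exp1")
SEG2 = SegmentationConfig(variant="velocity_exp2")


def _traj(pos, rate=60.0, t0=0.0):
    pos = np.asarray(pos, dtype=float)
    t = t0 + np.arange(pos.shape[0]) * 1000.0 / rate
    return Trajectory(t, pos[:, 0], pos[:, 1], pos[:, 2])


class TestLowpass:
    def test_constant_series_unchanged(self):
        x = np.full(120, 3.7)
        assert np.allclose(lowpass(x, 60.0, 10.0, 2), x, atol=1e-9)

    def test_passband_and_stopband(self):
        t = np.arange(0, 4, 1 / 60.0)
        low = np.sin(2 * np.pi * 2.0 * t)
        high = np.sin(2 * np.pi * 25.0 * t)
        low_out = lowpass(low, 60.0, 10.0, 2)
        high_out = lowpass(high, 60.0, 10.0, 2)
        mid = slice(30, -30)  # ignore edge transients
        assert np.abs(low_out[mid]).max() > 0.98
        assert np.abs(high_out[mid]).max() < 0.10

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lowpass(np.zeros(100), 60.0, 30.0, 2)


class TestSpeed:
    def test_uniform_straight_line(self):
        pos = np.outer(np.arange(40) * 10.0, [1.0, 0.0, 0.0])
        v = speed(_traj(pos))
        assert np.allclose(v, 600.0)

    def test_static_marker(self):
        v = speed(_traj(np.ones((30, 3))))
        assert np.allclose(v, 0.0)

    def test_minimum_jerk_peak_matches_closed_form(self):
        prof = speed_profile(0.5, 742.6, 330.0, 200.0)
        dt_s = 0.7426 / (prof.size - 1)
        arc = np.concatenate([[0.0], np.cumsum((prof[1:] + prof[:-1]) / 2 * dt_s)])
        pos = np.outer(arc, [1.0, 0.0, 0.0])
        t = np.arange(prof.size) * dt_s * 1000.0
        v = speed(Trajectory(t, pos[:, 0], pos[:, 1], pos[:, 2]))
        assert v.max() == pytest.approx(1.875 * 330.0 / 0.7426, rel=0.01)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            speed(_traj(np.zeros((2, 3)), rate=60.0))


class TestSegmentReachDisplacement:
    def test_onset_at_constructed_step(self):
        # per-axis steps ramp 0.4 -> 4.0 -> 0.1 mm/frame starting at frame 12
        steps = np.concatenate([np.linspace(0.4, 4.0, 10),
                                np.linspace(4.0, 0.1, 14), np.zeros(4)])
        pos = np.zeros((12 + steps.size, 3))
        pos[12:] = np.cumsum(steps)[:, None]
        traj = _traj(pos)
        window = segment_reach_displacement(traj, grasp_end_ms=500.0, cfg=SEG1)
        assert window is not None
        assert window.onset_ms == pytest.approx(traj.t_ms[12])

    def test_offset_tie_break_closest_to_grasp_end(self):
        # per-axis motion stops at different frames -> candidates 700/710/720 ms
        rate = 100.0
        n = 90
        pos = np.zeros((n, 3))
        stops = {0: 70, 1: 71, 2: 72}  # frames -> 700, 710, 720 ms
        for axis, stop in stops.items():
            pos[1:stop, axis] = np.cumsum(np.full(stop - 1, 1.0))
            pos[stop:, axis] = pos[stop - 1, axis]
        # velocity peak well inside the motion
        pos[20:30, :] += 5.0
        traj = _traj(pos, rate=rate)
        window = segment_reach_displacement(traj, grasp_end_ms=708.0, cfg=SEG1)
        assert window is not None
        assert window.offset_ms == pytest.approx(710.0)

    def test_no_motion_returns_none(self):
        window = segment_reach_displacement(_traj(np.zeros((40, 3))), 300.0, SEG1)
        assert window is None

    def test_noiseless_preset_reach_times(self):
        config = preset("exp1_italian", noiseless=True)
        for cell, (reach_ms, _, _) in EXP1_TABLE.items():
            trial = simulate_trial(Condition(cell[0], cell[1], "x"), {}, config, 5)
            kin = process_trial(trial, SEG1)
            assert kin.reach is not None
            assert abs(kin.reach.reach_time_ms - reach_ms) <= 1000.0 / 60.0


class TestSegmentReachVelocity:
    def test_direct_scan_example(self):
        v = np.array([0.0, 0.5, 2.0, 5.0, 2.0, 0.5, 0.0])
        t = np.arange(7) * 5.0
        window = segment_reach_velocity(v, t, SEG2)
        assert window.onset_ms == pytest.approx(10.0)
        assert window.offset_ms == pytest.approx(20.0)

    def test_all_above_threshold_full_support(self):
        v = np.full(50, 3.0)
        t = np.arange(50) * 5.0
        window = segment_reach_velocity(v, t, SEG2)
        assert window.onset_ms == t[0] and window.offset_ms == t[-1]

    def test_never_above_threshold(self):
        assert segment_reach_velocity(np.zeros(30), np.arange(30) * 5.0, SEG2) is None

    def test_noiseless_exp2_preset_reach_time(self):
        config = preset("exp2_german", noiseless=True)
        trial = simulate_trial(Condition("HE", "IV", "er liefert"), {}, config, 5)
        kin = process_trial(trial, SEG2)
        assert kin.reach is not None
        assert abs(kin.reach.reach_time_ms - 894.5) <= 5.0


class TestSegmentGrasp:
    def test_onset_threshold_from_baseline(self):
        ap = np.full(40, 5.0)
        ap[8:] = 5.0 + np.cumsum(np.full(32, 0.6))
        ap[25:] = ap[24]  # plateau after opening
        ap[20:25] = [ap[19] - 2 * i for i in range(1, 6)]  # closing
        t = np.arange(40) * 1000.0 / 60.0
        window = segment_grasp(ap, t, SEG1)
        assert window is not None
        assert window.onset_ms == pytest.approx(t[8])

    def test_symmetric_triangle_peak_at_midpoint(self):
        tau = np.linspace(0, 1, 61)
        tri = 5.0 + 60.0 * np.minimum(tau, 1 - tau) * 2
        ap = np.concatenate([tri, np.full(10, tri[-1])])  # plateau after closure
        t = np.arange(ap.size) * 1000.0 / 60.0
        window = segment_grasp(ap, t, SEG1)
        params, degenerate = extract_grasp_params(ap, t, window)
        assert not degenerate
        assert params.pct_t_max_aperture == pytest.approx(50.0, abs=3.0)

    def test_noiseless_fixture_peak_fraction(self):
        config = preset("exp1_italian", noiseless=True)
        trial = simulate_trial(Condition("I", "AV", "x"), {}, config, 2)
        kin = process_trial(trial, SEG1)
        assert kin.grasp is not None
        frame_pct = 100.0 * (1000.0 / 60.0) / kin.grasp.grasp_time_ms
        assert abs(kin.grasp.pct_t_max_aperture - 66.0) <= 1.5 * frame_pct
        assert abs(kin.grasp.max_aperture_mm - 85.0) <= 0.5


class TestExtractParams:
    def test_symmetric_profile_pct_50(self):
        v = speed_profile(0.5, 700.0, 330.0, 200.0)
        t = np.arange(v.size) * 5.0
        window = MovementWindow(onset_ms=t[0], offset_ms=t[-1])
        params, degenerate = extract_reach_params(v, t, window)
        assert degenerate is False
        assert params.pct_t_vpeak == pytest.approx(50.0, abs=100.0 / v.size)

    def test_noiseless_preset_pct_t_vpeak(self):
        config = preset("exp1_italian", noiseless=True)
        trial = simulate_trial(Condition("YOU", "IV", "x"), {}, config, 9)
        kin = process_trial(trial, SEG1)
        assert abs(kin.reach.pct_t_vpeak - 47.4) <= 2.5  # one frame equivalent

    def test_rate_doubling_stable(self):
        from dataclasses import replace

        base = preset("exp1_italian", noiseless=True)
        coarse = simulate_trial(Condition("I", "AV", "x"), {}, base, 0)
        fine = simulate_trial(
            Condition("I", "AV", "x"), {},
            replace(base, sampling_rate_hz=120.0), 0,
        )
        # above 100 Hz the generator calibrates against the velocity rule
        k_coarse = process_trial(coarse, SEG1).reach
        k_fine = process_trial(fine, SEG2).reach
        coarse_frame_pct = 100.0 * (1000.0 / 60.0) / k_coarse.reach_time_ms
        assert abs(k_fine.pct_t_vpeak - k_coarse.pct_t_vpeak) <= coarse_frame_pct

    def test_peak_on_boundary_is_degenerate(self):
        v = np.linspace(0, 100, 50)  # strictly increasing: peak at window end
        t = np.arange(50) * 5.0
        window = MovementWindow(onset_ms=t[0], offset_ms=t[-1])
        params, degenerate = extract_reach_params(v, t, window)
        assert params is None and degenerate


class TestProcessTrial:
    def test_velocity_variant_reach_only(self):
        config = preset("exp2_german", noiseless=True)
        trial = simulate_trial(Condition("I", "AV", "x"), {}, config, 1)
        kin = process_trial(trial, SEG2)
        assert kin.reach is not None and kin.grasp is None

    def test_zero_motion_flags_not_raises(self):
        n = 60
        t = np.arange(n) * 1000.0 / 60.0
        flat = {m: Trajectory(t, np.zeros(n), np.zeros(n), np.zeros(n))
                for m in ("wrist", "index", "thumb")}
        trial = TrialRecord("s01", "t1", Condition("I", "AV", "x"), flat)
        kin = process_trial(trial, SEG1)
        assert kin.segmentation_failure and kin.reach is None

    def test_monotone_in_peak_fraction(self):
        # larger configured % latency -> larger extracted % latency
        from dataclasses import replace

        config = preset("exp1_italian", noiseless=True)
        extracted = []
        for pct in (40.0, 47.0, 54.0, 61.0):
            means = {
                cell: replace(cm, pct_t_vpeak=pct)
                for cell, cm in config.condition_means.items()
            }
            cfg = replace(config, condition_means=means)
            trial = simulate_trial(Condition("I", "AV", "x"), {}, cfg, 0)
            extracted.append(process_trial(trial, SEG1).reach.pct_t_vpeak)
        assert all(b > a for a, b in zip(extracted, extracted[1:]))

    def test_scaling_invariance_of_pct(self):
        # spatially scaling a noiseless trial leaves % latency unchanged
        config = preset("exp1_italian", noiseless=True)
        trial = simulate_trial(Condition("I", "AV", "x"), {}, config, 4)
        kin1 = process_trial(trial, SEG1)
        scaled = {
            m: Trajectory(tr.t_ms, 2 * tr.x_mm, 2 * tr.y_mm, 2 * tr.z_mm)
            for m, tr in trial.markers.items()
        }
        trial2 = TrialRecord("s", "t", trial.condition, scaled)
        kin2 = process_trial(trial2, SEG1)
        frame_pct = 100.0 * (1000.0 / 60.0) / kin1.reach.reach_time_ms
        assert abs(kin1.reach.pct_t_vpeak - kin2.reach.pct_t_vpeak) <= 1.5 * frame_pct
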