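"""Step-onset detection, timing validity, crossing metrics, foot placement."""

import numpy as np
import pytest

from stepgaze import (FootTrajectory, GaitParams, TrajectoryError,
                      classify_trial_timing, compute_crossing_metrics,
                      compute_foot_placement, detect_step_onset,
                      find_stance_intervals, simulate_foot_trajectories,
                      trial_gait_metrics)
from stepgaze.synthetic_cohort import WalkwayGeometry, draw_step_onset


def ramp_trajectory(onset_ms=700.0, rate_cm_s=10.0, dt=10.0, dur=2000.0,
                    x0=0.0, t0=0.0, trial_id=0):
    t = np.arange(t0, t0 + dur, dt)
    x = np.where(t >= onset_ms, x0 + rate_cm_s * (t - onset_ms) / 1000.0, x0)
    return FootTrajectory(trial_id=trial_id, limb="lead", side="right",
                          t_ms=t, x_cm=x, y_cm=np.zeros_like(t),
                          z_cm=np.zeros_like(t))


def brute_force_onset(traj, cue_time=0.0, threshold=0.5):
    """Independent oracle: plain scan over every sample."""
    base_idx = next(i for i, t in enumerate(traj.t_ms) if t >= cue_time)
    x0, z0 = traj.x_cm[base_idx], traj.z_cm[base_idx]
    for i in range(base_idx, len(traj.t_ms)):
        if traj.x_cm[i] - x0 >= threshold or traj.z_cm[i] - z0 >= threshold:
            return traj.t_ms[i]
    return None


class TestOnsetDetection:
    def test_ramp_reaches_threshold_at_expected_sample(self):
        # 10 cm/s from 700 ms: 0.5 cm at 750 ms, exactly on a sample
        traj = ramp_trajectory(onset_ms=700.0, rate_cm_s=10.0)
        assert detect_step_onset(traj) == pytest.approx(750.0)

    def test_flat_trace_has_no_onset(self):
        traj = ramp_trajectory(rate_cm_s=0.0)
        assert detect_step_onset(traj) is None

    def test_upward_deviation_also_triggers(self):
        t = np.arange(0.0, 1500.0, 10.0)
        z = np.where(t >= 600.0, 0.6, 0.0)
        traj = FootTrajectory(trial_id=0, limb="lead", side="left", t_ms=t,
                              x_cm=np.zeros_like(t), y_cm=np.zeros_like(t),
                              z_cm=z)
        assert detect_step_onset(traj) == pytest.approx(600.0)

    def test_translation_invariance_in_time_and_position(self):
        a = ramp_trajectory(onset_ms=700.0, x0=0.0, t0=0.0)
        b = ramp_trajectory(onset_ms=900.0, x0=55.0, t0=0.0)
        assert detect_step_onset(b) - detect_step_onset(a) == pytest.approx(200.0)

    def test_agrees_with_brute_force_scan_on_synthetic_walks(self, gait, geometry,
                                                             crossing_trial, rng):
        for _ in range(25):
            lead, trail, truth = simulate_foot_trajectories(
                crossing_trial, gait, geometry, rng)
            for traj in (lead, trail):
                assert detect_step_onset(traj) == brute_force_onset(traj)

    def test_detected_onset_matches_embedded_truth_exactly(self, gait, geometry,
                                                           crossing_trial, rng):
        for _ in range(50):
            lead, _, truth = simulate_foot_trajectories(crossing_trial, gait,
                                                        geometry, rng)
            detected = detect_step_onset(lead)
            assert detected >= truth["onset_ms"] - 1e-9
            assert abs(detected - truth["onset_ms"]) <= 10.0  # one sample

    def test_trajectory_starting_after_cue_is_error(self):
        traj = ramp_trajectory(t0=100.0)
        with pytest.raises(TrajectoryError):
            detect_step_onset(traj, cue_time=0.0)


class TestTimingValidity:
    @pytest.mark.parametrize("onset,status", [
        (350.0, "too_fast"),
        (377.8, "too_fast"),     # boundary: validity requires onset > 377.8
        (380.0, "valid"),
        (741.0, "valid"),
        (1000.0, "valid"),       # inclusive upper bound
        (1100.0, "too_slow"),
        (None, "no_onset"),
    ])
    def test_window_boundaries(self, onset, status):
        assert classify_trial_timing(onset).status == status

    def test_injected_violations_are_classified(self, gait, rng):
        fast = slow = 0
        for _ in range(3000):
            onset, label = draw_step_onset(gait, rng)
            verdict = classify_trial_timing(onset)
            if label == "too_fast":
                fast += 1
                assert verdict.status == "too_fast"
                assert onset < 377.8
            elif label == "too_slow":
                slow += 1
                assert verdict.status == "too_slow"
            else:
                assert verdict.status == "valid"
        assert fast + slow < 100  # rare by construction


class TestCrossingMetrics:
    def test_constructed_arc_recovers_drawn_clearance_and_distance(
            self, gait, geometry, crossing_trial, rng):
        lead, trail, truth = simulate_foot_trajectories(
            crossing_trial, gait, geometry, rng,
            draws={"onset_ms": 740.0, "lead_clearance": 10.0,
                   "trail_clearance": 11.3, "step1_offset": (0.0, 0.0),
                   "step2_offset": (0.0, 0.0)})
        m = compute_crossing_metrics(lead, trail, geometry.obstacle_x)
        assert m["lead_clearance"] == pytest.approx(10.0, abs=0.05)
        assert m["trail_clearance"] == pytest.approx(11.3, abs=0.05)
        assert m["lead_horizontal_distance"] == pytest.approx(84.0, abs=0.1)
        assert m["trail_horizontal_distance"] == pytest.approx(27.6, abs=0.1)
        assert not m["contact"]

    def test_peak_below_obstacle_top_flags_contact(self, gait, geometry,
                                                   crossing_trial, rng):
        lead, trail, truth = simulate_foot_trajectories(
            crossing_trial, gait, geometry, rng,
            draws={"onset_ms": 700.0, "lead_clearance": -1.0,
                   "trail_clearance": 11.3})
        m = compute_crossing_metrics(lead, trail, geometry.obstacle_x)
        assert m["lead_clearance"] < 0
        assert m["contact"]

    def test_non_crossing_trajectory_is_error(self):
        traj = ramp_trajectory(rate_cm_s=0.0)
        with pytest.raises(TrajectoryError, match="never crosses"):
            compute_crossing_metrics(traj, traj, obstacle_x=160.0)

    def test_cohort_means_recover_generator_distances(self, gait, geometry,
                                                      crossing_trial, rng):
        hds_l, hds_t, cls_l = [], [], []
        for _ in range(250):
            lead, trail, truth = simulate_foot_trajectories(
                crossing_trial, gait, geometry, rng)
            m = compute_crossing_metrics(lead, trail, geometry.obstacle_x)
            # detector vs embedded truth: interpolation-level agreement
            assert m["lead_horizontal_distance"] == pytest.approx(
                truth["lead_horizontal_distance"], abs=0.05)
            assert m["lead_clearance"] == pytest.approx(
                truth["lead_clearance"], abs=0.05)
            hds_l.append(m["lead_horizontal_distance"])
            hds_t.append(m["trail_horizontal_distance"])
            cls_l.append(m["lead_clearance"])
        # single-trial scatter SD ~4.8/5.7 cm: 3 sigma bands on 250-trial means
        assert np.mean(hds_l) == pytest.approx(84.0, abs=1.0)
        assert np.mean(hds_t) == pytest.approx(27.6, abs=1.2)
        assert np.mean(cls_l) == pytest.approx(10.0, abs=1.1)


class TestFootPlacement:
    def test_foot_resting_on_gabor_center_is_zero(self):
        t = np.arange(0.0, 500.0, 10.0)
        traj = FootTrajectory(trial_id=0, limb="lead", side="right", t_ms=t,
                              x_cm=np.full_like(t, 76.0),
                              y_cm=np.full_like(t, -10.0),
                              z_cm=np.zeros_like(t))
        assert compute_foot_placement(traj, (76.0, -10.0)) == pytest.approx(0.0)

    def test_three_four_five_offset(self, gait, geometry, crossing_trial, rng):
        lead, _, _ = simulate_foot_trajectories(
            crossing_trial, gait, geometry, rng,
            draws={"onset_ms": 740.0, "step1_offset": (3.0, 4.0)})
        d = compute_foot_placement(lead, geometry.location_xy("R1"))
        assert d == pytest.approx(5.0, abs=0.05)

    def test_no_stance_is_error(self):
        t = np.arange(0.0, 300.0, 10.0)
        traj = FootTrajectory(trial_id=0, limb="lead", side="right", t_ms=t,
                              x_cm=100.0 * t / 1000.0, y_cm=np.zeros_like(t),
                              z_cm=np.zeros_like(t))
        with pytest.raises(TrajectoryError, match="stance"):
            compute_foot_placement(traj, (0.0, 0.0))

    def test_placement_recovers_embedded_offsets(self, gait, geometry,
                                                 crossing_trial, rng):
        for _ in range(40):
            lead, trail, truth = simulate_foot_trajectories(
                crossing_trial, gait, geometry, rng)
            p1 = compute_foot_placement(lead, geometry.location_xy("R1"))
            assert p1 == pytest.approx(truth["foot_placement_step1"], abs=0.05)


class TestTrialSummary:
    def test_stationary_trace_yields_no_onset_verdict(self, gait, geometry,
                                                      stationary_trial, rng):
        lead, trail, truth = simulate_foot_trajectories(stationary_trial, gait,
                                                        geometry, rng)
        assert truth["onset_ms"] is None
        m = trial_gait_metrics(lead, trail, geometry.obstacle_x)
        assert m.timing.status == "no_onset"
        assert m.lead_clearance is None

    def test_valid_crossing_produces_full_metrics(self, gait, geometry,
                                                  crossing_trial, rng):
        lead, trail, _ = simulate_foot_trajectories(
            crossing_trial, gait, geometry, rng, draws={"onset_ms": 740.0})
        m = trial_gait_metrics(lead, trail, geometry.obstacle_x,
                               step1_xy=geometry.location_xy("R1"),
                               step2_xy=geometry.location_xy("L2"))
        assert m.timing.valid
        assert m.step_onset_ms == pytest.approx(740.0)
        assert m.lead_clearance is not None
        assert m.foot_placement_step1 is not None

    def test_stance_detection_finds_low_speed_low_height_runs(self, gait,
                                                              geometry,
                                                              crossing_trial,
                                                              rng):
        lead, _, truth = simulate_foot_trajectories(
            crossing_trial, gait, geometry, rng, draws={"onset_ms": 700.0})
        stances = find_stance_intervals(lead)
        assert len(stances) >= 3  # start, step-1 stance, landing
        # the step-1 stance sits at the drawn stance position
        xs = [float(np.mean(lead.x_cm[a:b + 1])) for a, b in stances]
        assert any(abs(x - truth["stance1"][0]) < 0.1 for x in xs)
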