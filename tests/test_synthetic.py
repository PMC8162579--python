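"""The synthetic experiment: gait kinematics, marker synthesis, and
dynamically consistent ground reactions."""

import filecmp

import numpy as np
import pytest

from markerreg.analysis import detect_gait_events
from markerreg.dynamics import CoordinateTrajectory, inverse_dynamics
from markerreg.fileio import read_mot
from markerreg.kinematics import forward_kinematics, _fk_core
from markerreg.synthetic import (
    GaitSpec,
    generate_gait,
    make_dataset,
    static_pose,
    synthesize_grf,
    synthesize_markers,
)


class TestGaitSpec:
    def test_walking_cycle_consistency(self):
        spec = GaitSpec(speed=0.4, step_length=0.33)
        assert spec.cycle_time == pytest.approx(1.65)
        assert spec.stride_length == pytest.approx(0.66)

    def test_speed_step_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GaitSpec(speed=0.0, step_length=0.33)
        with pytest.raises(ValueError):
            GaitSpec(speed=0.4, step_length=0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            GaitSpec(rate=-5.0)


class TestGenerateGait:
    def test_average_forward_speed(self, robot, gait_spec):
        """Mean forward root velocity over whole cycles equals 0.4 m/s."""
        traj = generate_gait(gait_spec, robot)
        x = traj.column("pelvis_tx")
        v = (x[-1] - x[0]) / (traj.time[-1] - traj.time[0])
        assert v == pytest.approx(gait_spec.speed, abs=1e-6)

    def test_consecutive_strikes_one_stride_apart(self, robot, gait_spec, clean_trial):
        """Ipsilateral foot-strike positions differ by 2 × 0.33 m."""
        ev = detect_gait_events(clean_trial.grf[0], clean_trial.body_weight)
        assert len(ev.strikes) >= 2
        heel_x = []
        for ts in ev.strikes[:2]:
            i = int(round(ts * gait_spec.rate))
            sol = forward_kinematics(robot, clean_trial.truth.values[i])
            heel_x.append(sol.marker_positions["RHEE"][0])
        assert heel_x[1] - heel_x[0] == pytest.approx(
            gait_spec.stride_length, abs=1e-3
        )

    def test_standing_spec_is_constant(self, robot):
        spec = GaitSpec.standing_spec(duration=0.5)
        traj = generate_gait(spec, robot)
        np.testing.assert_allclose(
            traj.values, np.tile(traj.values[0], (traj.n_frames, 1)), atol=1e-14
        )

    def test_swing_foot_clears_ground(self, robot, gait_spec, clean_trial):
        """Foot markers stay above the ground plane while the foot swings."""
        T = gait_spec.cycle_time
        phi = np.mod(clean_trial.truth.time / T - gait_spec.strike_phase, 1.0)
        swing = (phi > gait_spec.stance_fraction + 0.02) & (phi < 0.98)
        foot_markers = ["RHEE", "RTOE", "RMT5"]
        cols = [clean_trial.markers.names.index(m) for m in foot_markers]
        heights = clean_trial.markers.positions[swing][:, cols, 1]
        assert heights.min() > 0.0

    def test_knee_stays_off_singularity(self, robot, gait_spec):
        traj = generate_gait(gait_spec, robot)
        for side in "rl":
            k = traj.column(f"knee_flexion_{side}")
            assert k.min() > np.deg2rad(5.0)


class TestSynthesizeMarkers:
    def test_zero_noise_equals_fk(self, robot, clean_trial):
        i = 57
        sol = forward_kinematics(robot, clean_trial.truth.values[i])
        for j, name in enumerate(clean_trial.markers.names):
            np.testing.assert_allclose(
                clean_trial.markers.positions[i, j],
                sol.marker_positions[name],
                atol=1e-12,
            )

    def test_empirical_noise_sd(self, robot, gait_spec):
        traj = generate_gait(GaitSpec.standing_spec(duration=0.5), robot)
        sigma = 0.002
        clean = synthesize_markers(robot, traj, 0.0, 0)
        noisy = synthesize_markers(robot, traj, sigma, 123)
        resid = (noisy.positions - clean.positions).ravel()
        assert resid.size > 10_000
        assert abs(np.std(resid) - sigma) / sigma < 0.05

    def test_frame_count_at_200_hz(self, robot, gait_spec, clean_trial):
        assert clean_trial.markers.rate == 200.0
        assert clean_trial.markers.n_frames == int(
            round(gait_spec.duration * 200.0)
        ) + 1

    def test_negative_sigma_rejected(self, robot, clean_trial):
        with pytest.raises(ValueError):
            synthesize_markers(robot, clean_trial.truth, -1e-3, 0)


class TestSynthesizeGrf:
    def test_static_single_foot_weight_and_cop(self, robot):
        """Standing on the right foot: vertical force equals body weight and
        the COP falls inside the foot's marker bounding box."""
        q = static_pose(robot)
        idx = {n: i for i, n in enumerate(robot.coordinate_names)}
        q[idx["knee_flexion_l"]] = 1.3  # lift the left foot
        q[idx["hip_flexion_l"]] = 0.9

        def com_minus_ankle_z(beta):
            qq = q.copy()
            qq[idx["hip_adduction_r"]] = beta
            poses, _ = _fk_core(robot, qq)
            mz = sum(
                s.mass * (poses[s.name][0] @ s.com_local + poses[s.name][1])[2]
                for s in robot.segments.values()
            )
            return mz / robot.total_mass - poses["foot_r"][1][2]

        lo, hi = 0.0, 0.5
        for _ in range(60):  # bisect the adduction that centers COM over foot
            mid = 0.5 * (lo + hi)
            if com_minus_ankle_z(mid) * com_minus_ankle_z(lo) <= 0:
                hi = mid
            else:
                lo = mid
        q[idx["hip_adduction_r"]] = 0.5 * (lo + hi)

        n = 10
        traj = CoordinateTrajectory(
            np.arange(n) / 200.0, np.tile(q, (n, 1)), robot.coordinate_names, 200.0
        )
        grf = synthesize_grf(robot, traj)  # stance inferred from foot height
        weight = robot.total_mass * 9.80665
        assert grf[0].force[5, 1] == pytest.approx(weight, abs=1e-9)
        assert grf[1].force[5, 1] == pytest.approx(0.0, abs=1e-9)
        poses, _ = _fk_core(robot, q)
        r, p = poses["foot_r"]
        marks = np.array(
            [r @ off + p for off in robot.segments["foot_r"].markers.values()]
        )
        cop = grf[0].cop[5]
        assert marks[:, 0].min() - 0.01 < cop[0] < marks[:, 0].max() + 0.01
        assert marks[:, 2].min() - 0.01 < cop[2] < marks[:, 2].max() + 0.01

    def test_vertical_impulse_bookkeeping(self, clean_trial, gait_spec):
        """Total vertical impulse over one cycle ≈ body weight × duration."""
        T = gait_spec.cycle_time
        rate = gait_spec.rate
        i0, i1 = 0, int(round(T * rate))
        fy = clean_trial.grf[0].force[i0:i1, 1] + clean_trial.grf[1].force[i0:i1, 1]
        assert np.mean(fy) == pytest.approx(clean_trial.body_weight, rel=0.02)

    def test_root_residuals_vanish_in_single_support(self, robot, clean_trial, gait_spec):
        moments = inverse_dynamics(robot, clean_trial.truth, clean_trial.grf)
        # single support of the right foot, first cycle, away from the ends
        T = gait_spec.cycle_time
        t0 = (gait_spec.strike_phase + 0.15) * T
        t1 = (gait_spec.strike_phase + 0.45) * T
        sel = (moments.time >= t0) & (moments.time <= t1)
        residual_force = moments.moments[sel][:, :3]
        assert np.abs(residual_force).max() < 0.01 * clean_trial.body_weight


class TestMakeDataset:
    def test_files_byte_identical_under_seed(self, tmp_path, gait_spec):
        a, b = tmp_path / "a", tmp_path / "b"
        make_dataset(gait_spec, noise_sigma=0.0005, seed=9, out_dir=a)
        make_dataset(gait_spec, noise_sigma=0.0005, seed=9, out_dir=b)
        for name in (
            "static.trc",
            "walking.trc",
            "encoders.mot",
            "truth_angles.mot",
            "grf.mot",
            "metadata.json",
        ):
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_different_seed_differs(self, tmp_path, gait_spec):
        a, b = tmp_path / "a", tmp_path / "b"
        make_dataset(gait_spec, noise_sigma=0.0005, seed=1, out_dir=a)
        make_dataset(gait_spec, noise_sigma=0.0005, seed=2, out_dir=b)
        assert not filecmp.cmp(a / "walking.trc", b / "walking.trc", shallow=False)

    def test_encoder_file_has_twelve_angle_columns(self, tmp_path, gait_spec):
        out = tmp_path / "d"
        make_dataset(gait_spec, seed=0, out_dir=out)
        table = read_mot(out / "encoders.mot")
        assert len(table.names) == 12
        assert table.in_degrees

    def test_static_trial_duration_and_pose(self, clean_trial):
        assert clean_trial.static_markers.n_frames >= 200
        assert clean_trial.static_markers.rate == 200.0
        # constant pose
        np.testing.assert_allclose(
            clean_trial.static_markers.positions.std(axis=0), 0.0, atol=1e-12
        )
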