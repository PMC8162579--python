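"""Marker registration: exact static residuals for all methods, pose
recovery, the simulated-user error model, and error monotonicity."""

import numpy as np
import pytest

from markerreg.dynamics import CoordinateTrajectory
from markerreg.frames import AxisSpec, FrameDefinition, default_frame_definitions
from markerreg.ik import solve_trajectory
from markerreg.kinematics import forward_kinematics
from markerreg.model import Segment, KinematicModel
from markerreg.registration import (
    VIRTUAL_AXIS_LENGTH,
    encoder_register,
    orientation_register,
    place_markers_at_pose,
    simulate_user_placement,
    user_register,
)
from markerreg.synthetic import synthesize_markers

from conftest import free_root, pin_with_markers


def fk_markers(model, q):
    return forward_kinematics(model, q).marker_positions


class TestPlaceMarkers:
    def test_identity_segment(self):
        model = KinematicModel(
            [Segment(name="base", markers={"M": (0, 0, 0)})], [free_root("base")]
        )
        placed = place_markers_at_pose(
            model, np.zeros(6), {"M": np.array([1.0, 0.0, 0.0])}
        )
        np.testing.assert_allclose(placed.marker_offset("M"), [1, 0, 0], atol=1e-15)

    def test_rotated_segment_inverse_transform(self):
        model = KinematicModel(
            [Segment(name="base", markers={"M": (0, 0, 0)})], [free_root("base")]
        )
        q = np.zeros(6)
        q[3] = np.pi / 2  # +90° about Z
        placed = place_markers_at_pose(model, q, {"M": np.array([0.0, 1.0, 0.0])})
        np.testing.assert_allclose(placed.marker_offset("M"), [1, 0, 0], atol=1e-12)

    def test_fixture_exact_reproduction(self, robot, in_range_q):
        rng = np.random.default_rng(0)
        statics = {
            k: v + rng.normal(0, 0.01, 3) for k, v in fk_markers(robot, in_range_q).items()
        }
        placed = place_markers_at_pose(robot, in_range_q, statics)
        after = fk_markers(placed, in_range_q)
        err = max(np.linalg.norm(after[k] - statics[k]) for k in statics)
        assert err < 1e-12

    def test_unknown_marker_raises(self, robot, in_range_q):
        with pytest.raises(KeyError):
            place_markers_at_pose(robot, in_range_q, {"NOPE": np.zeros(3)})


class TestEncoderRegistration:
    def test_exact_information_recovers_true_offsets(self, clean_trial):
        robot = clean_trial.model
        result = encoder_register(
            robot,
            clean_trial.static_markers.mean_positions(),
            clean_trial.static_encoders,
        )
        assert result.static_marker_rmse < 1e-9
        np.testing.assert_allclose(
            result.static_pose, clean_trial.static_q, atol=1e-9
        )
        for name in robot.marker_names:
            np.testing.assert_allclose(
                result.registered_model.marker_offset(name),
                robot.marker_offset(name),
                atol=1e-9,
            )

    def test_missing_encoder_channel_raises(self, clean_trial):
        enc = dict(clean_trial.static_encoders)
        enc.pop("knee_flexion_r")
        with pytest.raises(ValueError, match="knee_flexion_r"):
            encoder_register(
                clean_trial.model, clean_trial.static_markers.mean_positions(), enc
            )


class TestOrientationRegistration:
    def test_consistency_round_trip(self, clean_trial):
        robot = clean_trial.model
        result = orientation_register(
            robot,
            clean_trial.static_markers.mean_positions(),
            default_frame_definitions(),
        )
        assert result.static_marker_rmse < 1e-9
        assert np.max(np.abs(result.static_pose - clean_trial.static_q)) < 1e-6
        for name in robot.marker_names:
            np.testing.assert_allclose(
                result.registered_model.marker_offset(name),
                robot.marker_offset(name),
                atol=1e-8,
            )

    def test_one_dof_toy_matches_grid_scan(self):
        """Single hinge with a framed link rotated a known 7°: the recovered
        angle must match brute-force minimization of the virtual-frame-point
        objective on a fine grid."""
        markers = {
            "L1": (0.3, 0.0, 0.0),
            "L2": (0.3, 0.2, 0.0),
            "L3": (0.3, 0.0, 0.2),
        }
        model = pin_with_markers(markers)
        defn = FrameDefinition(
            segment="link",
            origin=["L1"],
            primary=AxisSpec(["L1"], ["L2"], "y"),
            secondary=AxisSpec(["L1"], ["L3"], "z"),
        )
        base_defn = FrameDefinition(
            segment="base",
            origin=["B1"],
            primary=AxisSpec(["B2"], ["B1"], "x"),
            secondary=AxisSpec(["B1"], ["B3"], "y"),
        )
        q_true = np.zeros(model.n_coordinates)
        q_true[model.coordinate_index("pin")] = np.deg2rad(7.0)
        statics = fk_markers(model, q_true)
        result = orientation_register(model, statics, [base_defn, defn])

        # independent grid scan of the orientation objective over the hinge
        from markerreg.frames import build_frame, model_frames

        exp_frames = {
            d.segment: build_frame(d, statics) for d in (base_defn, defn)
        }
        local = model_frames(model, [base_defn, defn])

        def objective(angle):
            q = np.zeros(model.n_coordinates)
            q[model.coordinate_index("pin")] = angle
            sol = forward_kinematics(model, q)
            total = 0.0
            for seg, lf in local.items():
                world = sol.segment_transforms[seg].compose(lf.transform)
                target = exp_frames[seg].transform
                total += np.sum((world.translation - target.translation) ** 2)
                for k in range(3):
                    a = world.translation + VIRTUAL_AXIS_LENGTH * world.rotation[:, k]
                    b = target.translation + VIRTUAL_AXIS_LENGTH * target.rotation[:, k]
                    total += np.sum((a - b) ** 2)
            return total

        grid = np.arange(np.deg2rad(2.0), np.deg2rad(12.0), 1e-5)
        best = grid[np.argmin([objective(a) for a in grid])]
        recovered = result.static_pose[model.coordinate_index("pin")]
        assert abs(recovered - best) < 1e-4


class TestSimulatedUser:
    def test_zero_sigma_identity(self, robot):
        out = simulate_user_placement(robot, sigma=0.0, seed=1)
        for name in robot.marker_names:
            np.testing.assert_array_equal(
                out.marker_offset(name), robot.marker_offset(name)
            )

    def test_seed_determinism(self, robot):
        a = simulate_user_placement(robot, sigma=0.01, seed=42)
        b = simulate_user_placement(robot, sigma=0.01, seed=42)
        assert a.to_json() == b.to_json()

    def test_negative_sigma_raises(self, robot):
        with pytest.raises(ValueError):
            simulate_user_placement(robot, sigma=-0.001, seed=0)

    def test_empirical_sigma(self, robot):
        """Pooled per-axis SD over ~10⁴ perturbation draws within 5% of σ."""
        sigma = 0.008
        draws = []
        for seed in range(100):
            out = simulate_user_placement(robot, sigma=sigma, seed=seed)
            for name in robot.marker_names:
                draws.extend(
                    (out.marker_offset(name) - robot.marker_offset(name)).tolist()
                )
        sd = np.std(draws)
        assert abs(sd - sigma) / sigma < 0.05


class TestUserRegistration:
    def test_zero_error_user_equals_encoder(self, clean_trial):
        robot = clean_trial.model
        statics = clean_trial.static_markers.mean_positions()
        enc = encoder_register(robot, statics, clean_trial.static_encoders)
        usr = user_register(
            simulate_user_placement(robot, sigma=0.0, seed=0), statics
        )
        assert np.max(np.abs(usr.static_pose - enc.static_pose)) < 1e-6
        for name in robot.marker_names:
            np.testing.assert_allclose(
                usr.registered_model.marker_offset(name),
                enc.registered_model.marker_offset(name),
                atol=1e-7,
            )

    @pytest.mark.parametrize("sigma_mm", [0, 5, 10, 20])
    def test_static_rmse_zero_regardless_of_placement_error(
        self, clean_trial, sigma_mm
    ):
        """Zero static residual never implies accurate registration: the
        residual is zero by construction for any placement error."""
        statics = clean_trial.static_markers.mean_positions()
        manual = simulate_user_placement(
            clean_trial.model, sigma=sigma_mm / 1000.0, seed=3
        )
        result = user_register(manual, statics)
        assert result.static_marker_rmse < 1e-9

    def test_downstream_error_monotone_in_sigma(self, clean_trial, gait_spec):
        """Median downstream joint-angle RMSE is nondecreasing in the
        placement-error magnitude (continuity to the encoder limit at 0)."""
        robot = clean_trial.model
        statics = clean_trial.static_markers.mean_positions()
        n_sub = 80
        truth = clean_trial.truth
        sub = CoordinateTrajectory(
            truth.time[:n_sub], truth.values[:n_sub], truth.names, truth.rate
        )
        series = synthesize_markers(robot, sub, 0.0, 0)
        medians = []
        for sigma in (0.0, 0.001, 0.005, 0.010):
            rmses = []
            for seed in range(10):
                manual = simulate_user_placement(robot, sigma=sigma, seed=seed)
                reg = user_register(manual, statics)
                ik = solve_trajectory(
                    reg.registered_model, series, q0=reg.static_pose
                )
                err = ik.trajectory.values[:, 6:] - sub.values[:, 6:]
                rmses.append(np.sqrt(np.mean(err**2)))
            medians.append(np.median(rmses))
        assert all(a <= b + 1e-12 for a, b in zip(medians, medians[1:]))
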