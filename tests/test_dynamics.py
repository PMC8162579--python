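"""Differentiation and inverse dynamics against closed-form and symbolic
Lagrangian oracles."""

import numpy as np
import pytest

from markerreg.dynamics import (
    CoordinateTrajectory,
    GroundReaction,
    differentiate,
    inverse_dynamics,
    inverse_dynamics_frame,
    spatial_kinematics,
    total_body_wrench,
)
from markerreg.model import KinematicModel, Segment
from markerreg.kinematics import forward_kinematics

from conftest import free_root, hinge


def make_traj(values, rate=200.0, names=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    names = names or [f"c{i}" for i in range(values.shape[1])]
    return CoordinateTrajectory(
        np.arange(values.shape[0]) / rate, values, names, rate
    )


class TestDifferentiate:
    def test_constant_is_zero(self):
        qd, qdd = differentiate(make_traj(np.full(50, 1.7)))
        np.testing.assert_allclose(qd, 0.0, atol=1e-12)
        np.testing.assert_allclose(qdd, 0.0, atol=1e-9)

    def test_linear_exact(self):
        alpha = 2.5
        t = np.arange(60) / 200.0
        qd, qdd = differentiate(make_traj(alpha * t))
        np.testing.assert_allclose(qd, alpha, atol=1e-10)
        np.testing.assert_allclose(qdd[2:-2], 0.0, atol=1e-10)

    def test_sinusoid_acceleration_error(self):
        f = 1.0
        rate = 200.0
        t = np.arange(400) / rate
        q = np.sin(2 * np.pi * f * t)
        _, qdd = differentiate(make_traj(q, rate))
        exact = -((2 * np.pi * f) ** 2) * np.sin(2 * np.pi * f * t)
        assert np.max(np.abs(qdd[2:-2, 0] - exact[2:-2])) < 1e-3

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 5"):
            differentiate(make_traj(np.zeros(4)))


def double_pendulum_model(l1, l2, m1, m2, lc1, lc2, i1, i2, g=9.80665):
    """Root-fixed base with two Z-hinged links hanging along −Y."""
    base = Segment(name="base")
    link1 = Segment(
        name="link1", mass=m1, com_local=(0, -lc1, 0), inertia_local=np.diag([0, 0, i1])
    )
    link2 = Segment(
        name="link2", mass=m2, com_local=(0, -lc2, 0), inertia_local=np.diag([0, 0, i2])
    )
    return KinematicModel(
        [base, link1, link2],
        [
            free_root("base"),
            hinge("q1", "base", "link1", (0, 0, 0)),
            hinge("q2", "link1", "link2", (0, -l1, 0)),
        ],
        gravity=(0, -g, 0),
    )


class TestInverseDynamicsFrame:
    def test_zero_gravity_static_is_zero(self, robot, in_range_q):
        data = robot.to_dict()
        data["gravity"] = [0.0, 0.0, 0.0]
        weightless = KinematicModel.from_dict(data)
        tau = inverse_dynamics_frame(
            weightless, in_range_q, np.zeros(18), np.zeros(18)
        )
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)

    def test_static_ankle_moment_lever_arm(self):
        """Massless leg standing still: the ankle moment must equal the
        closed-form lever arm |F|·d of a vertical load offset d from the
        ankle axis."""
        base = Segment(name="base")
        foot = Segment(name="foot")
        model = KinematicModel(
            [base, foot],
            [free_root("base"), hinge("ankle", "base", "foot", (0, -0.4, 0))],
        )
        q = np.zeros(model.n_coordinates)
        q[1] = 0.46  # ankle at 0.06 m above ground
        weight = 152.0
        d = 0.037
        ankle_world = np.array([0.0, 0.06, 0.0])
        cop = ankle_world + np.array([d, -0.06, 0.0])
        tau = inverse_dynamics_frame(
            model,
            q,
            np.zeros(7),
            np.zeros(7),
            external=[("foot", np.array([0.0, weight, 0.0]), cop, np.zeros(3))],
        )
        assert abs(abs(tau[model.coordinate_index("ankle")]) - weight * d) < 1e-9

    def test_double_pendulum_matches_lagrangian_oracle(self):
        """Prescribed sinusoidal motion of a planar double pendulum: hinge
        torques must match symbolically derived Euler–Lagrange dynamics."""
        pytest.importorskip("sympy")
        from oracles import double_pendulum_lagrangian_torques

        l1, l2 = 0.31, 0.27
        m1, m2 = 1.3, 0.8
        lc1, lc2 = 0.14, 0.12
        i1, i2 = 0.011, 0.006
        g = 9.80665
        model = double_pendulum_model(l1, l2, m1, m2, lc1, lc2, i1, i2, g)
        q1f, qdf, qddf, tau_fn = double_pendulum_lagrangian_torques(
            l1, l2, m1, m2, lc1, lc2, i1, i2, g,
            ((0.6, 2.1, 0.3), (0.9, 3.4, -0.5)),
        )
        i1_idx = model.coordinate_index("q1")
        i2_idx = model.coordinate_index("q2")
        for tv in np.linspace(0.0, 2.0, 9):
            q = np.zeros(model.n_coordinates)
            qd = np.zeros(model.n_coordinates)
            qdd = np.zeros(model.n_coordinates)
            q[[i1_idx, i2_idx]] = q1f(tv)
            qd[[i1_idx, i2_idx]] = qdf(tv)
            qdd[[i1_idx, i2_idx]] = qddf(tv)
            tau = inverse_dynamics_frame(model, q, qd, qdd)
            expected = np.asarray(tau_fn(tv))
            scale = max(1.0, np.max(np.abs(expected)))
            assert (
                np.max(np.abs(tau[[i1_idx, i2_idx]] - expected)) / scale < 1e-8
            )

    def test_superposition_in_external_load(self, robot, in_range_q):
        rng = np.random.default_rng(4)
        qd = rng.normal(0, 0.5, 18)
        qdd = rng.normal(0, 2.0, 18)
        cop = np.array([0.2, 0.0, 0.1])
        f1, f2 = rng.normal(0, 50, 3), rng.normal(0, 50, 3)
        m0 = np.zeros(3)

        def tau(f):
            return inverse_dynamics_frame(
                robot, in_range_q, qd, qdd, [("foot_r", f, cop, m0)]
            )

        np.testing.assert_allclose(
            tau(f1 + f2), tau(f1) + tau(f2) - tau(np.zeros(3)), atol=1e-9
        )

    def test_static_gravitational_moments_closed_form(self, robot, in_range_q):
        """At rest with no external load, each joint moment is the pure
        gravitational moment: Σ_distal (c_s − p) × m_s·(−g) projected on the
        axis (computed here independently from FK positions)."""
        tau = inverse_dynamics_frame(robot, in_range_q, np.zeros(18), np.zeros(18))
        sol = forward_kinematics(robot, in_range_q)
        states, axes = spatial_kinematics(robot, in_range_q, np.zeros(18), np.zeros(18))
        path = robot.path_coordinates()
        g = robot.gravity
        for name in ("knee_flexion_r", "hip_adduction_l", "ankle_inversion_r"):
            i = robot.coordinate_index(name)
            expected = 0.0
            for seg in robot.segments.values():
                if i not in path[seg.name]:
                    continue
                c = sol.segment_transforms[seg.name].apply(seg.com_local)
                expected += np.dot(
                    np.cross(axes[i].axis, c - axes[i].point), -seg.mass * g
                )
            assert tau[i] == pytest.approx(expected, abs=1e-9)


class TestInverseDynamicsTrajectory:
    def test_grf_time_misalignment_raises(self, robot):
        n = 10
        traj = CoordinateTrajectory(
            np.arange(n) / 200.0,
            np.tile(np.zeros(18), (n, 1)),
            robot.coordinate_names,
            200.0,
        )
        grf = GroundReaction(
            time=np.arange(n) / 200.0 + 0.5,
            force=np.zeros((n, 3)),
            cop=np.zeros((n, 3)),
            free_moment=np.zeros((n, 3)),
            applied_body="foot_r",
        )
        with pytest.raises(ValueError, match="aligned"):
            inverse_dynamics(robot, traj, grf)

    def test_total_wrench_is_weight_at_rest(self, robot, in_range_q):
        states, _ = spatial_kinematics(robot, in_range_q, np.zeros(18), np.zeros(18))
        force, _ = total_body_wrench(robot, states)
        np.testing.assert_allclose(
            force, [0.0, robot.total_mass * 9.80665, 0.0], atol=1e-9
        )
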