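"""Independent test oracles, deliberately coded apart from the production
paths they check."""

import numpy as np


def double_pendulum_lagrangian_torques(
    l1, l2, m1, m2, lc1, lc2, i1, i2, g, traj_params
):
    """Symbolic Euler–Lagrange joint torques of a planar double pendulum
    under prescribed sinusoidal motion.

    ``traj_params`` = ((a1, w1, p1), (a2, w2, p2)) for q_i = a·sin(w·t + p).
    Returns callables (q(t), qd(t), qdd(t), tau(t)) each giving a pair.
    """
    import sympy

    t = sympy.symbols("t")
    q1 = sympy.Function("q1")(t)
    q2 = sympy.Function("q2")(t)
    phi1, phi2 = q1, q1 + q2
    x1 = lc1 * sympy.sin(phi1)
    y1 = -lc1 * sympy.cos(phi1)
    x2 = l1 * sympy.sin(phi1) + lc2 * sympy.sin(phi2)
    y2 = -l1 * sympy.cos(phi1) - lc2 * sympy.cos(phi2)
    ke = (
        m1 * (sympy.diff(x1, t) ** 2 + sympy.diff(y1, t) ** 2) / 2
        + m2 * (sympy.diff(x2, t) ** 2 + sympy.diff(y2, t) ** 2) / 2
        + i1 * sympy.diff(phi1, t) ** 2 / 2
        + i2 * sympy.diff(phi2, t) ** 2 / 2
    )
    pe = m1 * g * y1 + m2 * g * y2
    lag = ke - pe
    taus = [
        (
            sympy.diff(sympy.diff(lag, sympy.Derivative(qi, t)), t)
            - sympy.diff(lag, qi)
        ).doit()
        for qi in (q1, q2)
    ]
    (a1, w1, p1), (a2, w2, p2) = traj_params
    traj1 = a1 * sympy.sin(w1 * t + p1)
    traj2 = a2 * sympy.sin(w2 * t + p2)
    subs = [
        (sympy.Derivative(q1, (t, 2)), sympy.diff(traj1, t, 2)),
        (sympy.Derivative(q2, (t, 2)), sympy.diff(traj2, t, 2)),
        (sympy.Derivative(q1, t), sympy.diff(traj1, t)),
        (sympy.Derivative(q2, t), sympy.diff(traj2, t)),
        (q1, traj1),
        (q2, traj2),
    ]
    taus = [tau.subs(subs) for tau in taus]
    return (
        sympy.lambdify(t, [traj1, traj2], "numpy"),
        sympy.lambdify(t, [sympy.diff(traj1, t), sympy.diff(traj2, t)], "numpy"),
        sympy.lambdify(t, [sympy.diff(traj1, t, 2), sympy.diff(traj2, t, 2)], "numpy"),
        sympy.lambdify(t, taus, "numpy"),
    )


def one_dof_marker_objective(model, angle, targets, coord="pin"):
    """Weighted least-squares marker objective as an explicit function of a
    single hinge angle (for dense grid scans)."""
    from markerreg.kinematics import marker_positions

    q = np.zeros(model.n_coordinates)
    q[model.coordinate_index(coord)] = angle
    names = list(targets)
    xs = marker_positions(model, q, names)
    obs = np.asarray([targets[n] for n in names])
    return float(np.sum((xs - obs) ** 2))
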