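"""Rigid-body inverse dynamics.

Given a coordinate trajectory and measured external (ground-reaction)
wrenches, compute the net generalized force on every coordinate: an outward
Newton–Euler pass propagates angular velocity/acceleration and linear
acceleration down the segment tree, and the required per-segment wrenches
(``m(a_com − g)`` and ``I·α + ω×I·ω``) are projected onto each coordinate's
instantaneous spatial axis (Jacobian-transpose formulation, algebraically
identical to the inward force/moment recursion). External wrenches are
applied at the center of pressure of the declared stance foot, with the free
moment added directly.

Rotational coordinates yield joint moments (N·m); the six root coordinates
yield the residual force (N) and moment that ground-truth-consistent data
should drive to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .kinematics import rotation_about


@dataclass
class CoordinateTrajectory:
    """Uniformly sampled generalized-coordinate time series (rad / m)."""

    time: np.ndarray
    values: np.ndarray
    names: List[str]
    rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).reshape(-1)
        self.values = np.asarray(self.values, dtype=float)
        n = self.time.size
        if self.values.shape != (n, len(self.names)):
            raise ValueError("values shape inconsistent with time/names")
        if n > 1 and np.any(np.abs(np.diff(self.time) - 1.0 / self.rate) > 1e-6):
            raise ValueError("sampling must be uniform at the declared rate")

    @property
    def n_frames(self) -> int:
        return self.time.size

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass
class GroundReaction:
    """One plate/foot: force (N), center of pressure (m, ground frame) and
    free moment (N·m), applied to ``applied_body``."""

    time: np.ndarray
    force: np.ndarray
    cop: np.ndarray
    free_moment: np.ndarray
    applied_body: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).reshape(-1)
        for attr in ("force", "cop", "free_moment"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (self.time.size, 3):
                raise ValueError(f"{attr} must have shape (n_frames, 3)")
            setattr(self, attr, arr)
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")

    @property
    def vertical_force(self) -> np.ndarray:
        return self.force[:, 1]


@dataclass
class MomentTrajectory:
    """Generalized moments/forces per coordinate, aligned with a trajectory."""

    time: np.ndarray
    moments: np.ndarray
    names: List[str]

    def column(self, name: str) -> np.ndarray:
        return self.moments[:, self.names.index(name)]


# ---------------------------------------------------------------------- #
#  Differentiation
# ---------------------------------------------------------------------- #


def differentiate(traj: CoordinateTrajectory):
    """Velocities and accelerations by finite differences.

    Fourth-order central stencils on the interior (needed so that 1 Hz
    motion sampled at 200 Hz is differentiated to well below 1e-3 s⁻²
    acceleration error), second-order one-sided stencils at the first and
    last two samples. Requires at least 5 samples.
    """
    if traj.n_frames < 5:
        raise ValueError("differentiation requires at least 5 samples")
    h = 1.0 / traj.rate
    qd = _derivative(traj.values, h)
    qdd = _second_derivative(traj.values, h)
    return qd, qdd


def _derivative(y: np.ndarray, h: float) -> np.ndarray:
    d = np.empty_like(y)
    d[2:-2] = (-y[4:] + 8 * y[3:-1] - 8 * y[1:-3] + y[:-4]) / (12 * h)
    for i in (0, 1):
        d[i] = (-3 * y[i] + 4 * y[i + 1] - y[i + 2]) / (2 * h)
    for i in (-1, -2):
        d[i] = (3 * y[i] - 4 * y[i - 1] + y[i - 2]) / (2 * h)
    return d


def _second_derivative(y: np.ndarray, h: float) -> np.ndarray:
    d = np.empty_like(y)
    d[2:-2] = (
        -y[4:] + 16 * y[3:-1] - 30 * y[2:-2] + 16 * y[1:-3] - y[:-4]
    ) / (12 * h * h)
    for i in (0, 1):
        d[i] = (2 * y[i] - 5 * y[i + 1] + 4 * y[i + 2] - y[i + 3]) / (h * h)
    for i in (-1, -2):
        d[i] = (2 * y[i] - 5 * y[i - 1] + 4 * y[i - 2] - y[i - 3]) / (h * h)
    return d


# ---------------------------------------------------------------------- #
#  Spatial kinematics (outward pass)
# ---------------------------------------------------------------------- #


@dataclass
class SegmentState:
    """World-frame state of one segment at one instant."""

    rotation: np.ndarray
    origin: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    a_origin: np.ndarray  # acceleration of the material point at the origin
    com: np.ndarray = field(default=None)
    a_com: np.ndarray = field(default=None)


@dataclass
class CoordinateAxisState:
    kind: str
    axis: np.ndarray
    point: np.ndarray


def spatial_kinematics(model, q, qd, qdd):
    """Outward pass: per-segment rigid-body states and per-coordinate
    instantaneous spatial axes at configuration (q, q̇, q̈)."""
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    qdd = np.asarray(qdd, dtype=float)
    states: Dict[str, SegmentState] = {
        model.ground: SegmentState(
            np.eye(3), np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3)
        )
    }
    axes: List[Optional[CoordinateAxisState]] = [None] * model.n_coordinates
    idx = model.coordinate_indices
    for joint in model.joints.values():
        ps = states[joint.parent_segment]
        r, p = ps.rotation, ps.origin
        w, al, a = ps.omega.copy(), ps.alpha.copy(), ps.a_origin.copy()
        # fixed offset to the joint frame
        r = r @ joint.frame_in_parent.rotation
        d = ps.rotation @ joint.frame_in_parent.translation
        p = p + d
        a = a + np.cross(al, d) + np.cross(w, np.cross(w, d))
        for axis in joint.axes:
            i = idx[axis.coordinate]
            s = r @ axis.direction
            axes[i] = CoordinateAxisState(axis.kind, s, p.copy())
            if axis.kind == "rotation":
                al = al + s * qdd[i] + np.cross(w, s) * qd[i]
                w = w + s * qd[i]
                r = r @ rotation_about(axis.direction, q[i])
            else:
                d = s * q[i]
                p = p + d
                a = (
                    a
                    + np.cross(al, d)
                    + np.cross(w, np.cross(w, d))
                    + 2.0 * np.cross(w, s * qd[i])
                    + s * qdd[i]
                )
        fc = joint.frame_in_child
        rc = r @ fc.rotation.T
        d = -(rc @ fc.translation)
        pc = p + d
        ac = a + np.cross(al, d) + np.cross(w, np.cross(w, d))
        states[joint.child_segment] = SegmentState(rc, pc, w, al, ac)
    # COM kinematics
    for seg in model.segments.values():
        st = states[seg.name]
        d = st.rotation @ seg.com_local
        st.com = st.origin + d
        st.a_com = (
            st.a_origin + np.cross(st.alpha, d) + np.cross(st.omega, np.cross(st.omega, d))
        )
    return states, axes


def total_body_wrench(model, states) -> tuple:
    """Net force and moment (about the world origin) the environment must
    apply for the body to follow the given motion under gravity."""
    force = np.zeros(3)
    moment = np.zeros(3)
    g = model.gravity
    for seg in model.segments.values():
        st = states[seg.name]
        f = seg.mass * (st.a_com - g)
        iw = st.rotation @ seg.inertia_local @ st.rotation.T
        n = iw @ st.alpha + np.cross(st.omega, iw @ st.omega)
        force += f
        moment += np.cross(st.com, f) + n
    return force, moment


def inverse_dynamics_frame(
    model,
    q,
    qd,
    qdd,
    external: Sequence[tuple] = (),
) -> np.ndarray:
    """Generalized forces at one instant.

    ``external`` is a sequence of ``(segment_name, force, point, free_moment)``
    wrenches applied by the environment (e.g. a ground reaction at its COP).
    Returns one value per coordinate: N·m for rotational, N for
    translational (root residuals).
    """
    states, axes = spatial_kinematics(model, q, qd, qdd)
    path = model.path_coordinates()
    g = model.gravity
    n = model.n_coordinates
    tau = np.zeros(n)
    for seg in model.segments.values():
        st = states[seg.name]
        f = seg.mass * (st.a_com - g)
        iw = st.rotation @ seg.inertia_local @ st.rotation.T
        nt = iw @ st.alpha + np.cross(st.omega, iw @ st.omega)
        for i in path[seg.name]:
            ax = axes[i]
            if ax.kind == "rotation":
                tau[i] += np.cross(ax.axis, st.com - ax.point) @ f + ax.axis @ nt
            else:
                tau[i] += ax.axis @ f
    for seg_name, force, point, free_moment in external:
        for i in path[seg_name]:
            ax = axes[i]
            if ax.kind == "rotation":
                tau[i] -= np.cross(ax.axis, point - ax.point) @ force
                tau[i] -= ax.axis @ free_moment
            else:
                tau[i] -= ax.axis @ force
    return tau


def inverse_dynamics(
    model,
    traj: CoordinateTrajectory,
    grf: "GroundReaction | Sequence[GroundReaction]",
) -> MomentTrajectory:
    """Inverse dynamics over a trajectory with measured ground reactions.

    The ground-reaction time base must cover the trajectory; each plate's
    wrench is applied at its COP on its declared stance foot. Coordinates
    are differentiated by :func:`differentiate` (no additional filtering is
    applied here; filter upstream).
    """
    grfs = [grf] if isinstance(grf, GroundReaction) else list(grf)
    for g in grfs:
        if (
            g.time.size != traj.n_frames
            or np.any(np.abs(g.time - traj.time) > 1e-9)
        ):
            raise ValueError(
                f"ground reaction for '{g.applied_body}' is not aligned with "
                "the coordinate trajectory time base"
            )
    qd, qdd = differentiate(traj)
    out = np.zeros((traj.n_frames, model.n_coordinates))
    for i in range(traj.n_frames):
        external = [
            (g.applied_body, g.force[i], g.cop[i], g.free_moment[i]) for g in grfs
        ]
        out[i] = inverse_dynamics_frame(
            model, traj.values[i], qd[i], qdd[i], external
        )
    return MomentTrajectory(traj.time.copy(), out, model.coordinate_names)
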