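"""Forward kinematics of rigid-body kinematic chains.

Maps generalized coordinates ``q`` to world-frame segment poses and marker
positions, and provides the analytic (geometric) marker Jacobian used by the
inverse-kinematics solvers.

Conventions
-----------
* World frame: right-handed, Y up, X forward (direction of travel).
* Lengths in meters, angles in radians.
* A joint's motion is composed as intrinsic successive transforms about its
  declared axes, sandwiched between the fixed parent- and child-side frames:
  ``T_child = T_parent · F_p · A_1(q_1) · … · A_k(q_k) · F_c⁻¹``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model import KinematicModel


@dataclass
class RigidTransform:
    """Proper rigid transform: ``x_world = rotation @ x_local + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first in local coordinates)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point (3,) or many points (n, 3) into the world."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def is_proper(self, tol: float = 1e-10) -> bool:
        r = self.rotation
        return (
            np.allclose(r.T @ r, np.eye(3), atol=tol)
            and abs(np.linalg.det(r) - 1.0) < tol
        )


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues' formula)."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


@dataclass
class CoordinateFrameInfo:
    """Instantaneous world-frame geometry of one generalized coordinate.

    For a rotational coordinate, ``axis`` is the world direction of the
    rotation axis and ``point`` a world point on it; for a translational
    coordinate, ``axis`` is the world direction of motion.
    """

    kind: str
    axis: np.ndarray
    point: np.ndarray


@dataclass
class PoseSolution:
    """World pose of every segment and world position of every marker."""

    segment_transforms: Dict[str, RigidTransform]
    marker_positions: Dict[str, np.ndarray]
    coordinate_info: Sequence[CoordinateFrameInfo] = field(repr=False, default=())


def _fk_core(model: "KinematicModel", q: np.ndarray):
    """Single outward pass: returns ({segment: (R, p)}, [CoordinateFrameInfo])."""
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_coordinates,):
        raise ValueError(
            f"coordinate vector has length {q.size}, model has "
            f"{model.n_coordinates} coordinates"
        )
    poses: Dict[str, tuple] = {model.ground: (np.eye(3), np.zeros(3))}
    info: list = [None] * model.n_coordinates
    idx = model.coordinate_indices
    for joint in model.joints.values():
        rp, pp = poses[joint.parent_segment]
        r = rp @ joint.frame_in_parent.rotation
        p = pp + rp @ joint.frame_in_parent.translation
        for axis in joint.axes:
            i = idx[axis.coordinate]
            s = r @ axis.direction
            if axis.kind == "rotation":
                info[i] = CoordinateFrameInfo("rotation", s, p.copy())
                r = r @ rotation_about(axis.direction, q[i])
            else:
                info[i] = CoordinateFrameInfo("translation", s, p.copy())
                p = p + s * q[i]
        fc = joint.frame_in_child
        rc = r @ fc.rotation.T
        pc = p - rc @ fc.translation
        poses[joint.child_segment] = (rc, pc)
    return poses, info


def forward_kinematics(model: "KinematicModel", q: np.ndarray) -> PoseSolution:
    """World pose of every segment and position of every marker at ``q``."""
    poses, info = _fk_core(model, q)
    transforms = {
        name: RigidTransform(r.copy(), p.copy()) for name, (r, p) in poses.items()
    }
    markers: Dict[str, np.ndarray] = {}
    for seg in model.segments.values():
        r, p = poses[seg.name]
        for mname, offset in seg.markers.items():
            markers[mname] = r @ offset + p
    return PoseSolution(transforms, markers, tuple(info))


def marker_positions(
    model: "KinematicModel", q: np.ndarray, marker_names: Sequence[str]
) -> np.ndarray:
    """(m, 3) world positions of the named markers at ``q``."""
    poses, _ = _fk_core(model, q)
    out = np.empty((len(marker_names), 3))
    for row, name in enumerate(marker_names):
        seg = model.marker_segment(name)
        r, p = poses[seg]
        out[row] = r @ model.marker_offset(name) + p
    return out


def marker_jacobian(
    model: "KinematicModel",
    q: np.ndarray,
    marker_subset: Sequence[str] | None = None,
    _precomputed=None,
) -> np.ndarray:
    """Analytic Jacobian ∂(stacked marker world positions)/∂q, shape (3m, n).

    Columns are geometric: a rotational coordinate with world axis ``s``
    through point ``p`` contributes ``s × (x − p)`` to marker ``x``; a
    translational coordinate contributes ``s``. Coordinates that do not lie
    on the path from ground to the marker's segment contribute zero.
    """
    names = list(marker_subset) if marker_subset is not None else model.marker_names
    if _precomputed is None:
        poses, info = _fk_core(model, q)
    else:
        poses, info = _precomputed
    n = model.n_coordinates
    path = model.path_coordinates()
    jac = np.zeros((3 * len(names), n))
    for row, name in enumerate(names):
        seg = model.marker_segment(name)
        r, p = poses[seg]
        x = r @ model.marker_offset(name) + p
        for i in path[seg]:
            ci = info[i]
            if ci.kind == "rotation":
                jac[3 * row : 3 * row + 3, i] = np.cross(ci.axis, x - ci.point)
            else:
                jac[3 * row : 3 * row + 3, i] = ci.axis
    return jac
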