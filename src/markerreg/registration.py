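"""Marker registration: placing model markers to coincide with experimental
markers at a static calibration pose.

Three methods are implemented, differing only in how the static pose is
found before the markers are (re)placed:

* **encoder** — the twelve joint angles come from the robot's joint
  encoders (ground truth); the six root coordinates, which no encoder can
  supply, are solved by a least-squares pelvis-marker fit with the joint
  angles frozen.
* **orientation** — anatomical reference frames are built from the static
  experimental markers; the model is posed so its (geometry-derived)
  anatomical frames best match them in the least-squares sense. The
  orientation tracking is realized through virtual frame points — each
  frame contributes its origin and three points 0.1 m along its axes as
  unit-weight targets to the same marker-tracking solver — a swappable
  strategy for a dedicated rotation-residual solver.
* **user** — a stochastic surrogate for manual GUI placement: the model
  carries manually placed (perturbed) marker offsets, and the pose is
  solved by ordinary marker IK with those offsets.

Whatever the pose, each model marker is then moved so its world position at
that pose equals the experimental position exactly; the recomputed static
marker RMSE is therefore zero to machine precision for every method — which
is precisely why a small static residual cannot diagnose registration error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .frames import FrameDefinition, build_frame, model_frames
from .ik import IKProblem, solve_frame
from .kinematics import _fk_core, marker_positions
from .model import JOINT_COORDS, KinematicModel, Segment

VIRTUAL_AXIS_LENGTH = 0.1  # m, lever arm of the virtual frame points


@dataclass
class RegistrationResult:
    registered_model: KinematicModel
    static_pose: np.ndarray
    method: str
    static_marker_rmse: float


def _static_rmse(model, q_pose, static_markers: Dict[str, np.ndarray]) -> float:
    names = [n for n in static_markers if n in set(model.marker_names)]
    xs = marker_positions(model, q_pose, names)
    obs = np.asarray([static_markers[n] for n in names])
    return float(np.sqrt(np.mean(np.sum((xs - obs) ** 2, axis=1))))


def place_markers_at_pose(
    model: KinematicModel, q_pose: np.ndarray, static_markers: Dict[str, np.ndarray]
) -> KinematicModel:
    """Move each model marker so FK at ``q_pose`` reproduces the experimental
    world position exactly: new local offset = (segment world pose)⁻¹ · x."""
    poses, _ = _fk_core(model, q_pose)
    offsets = {}
    for name, world in static_markers.items():
        seg = model.marker_segment(name)  # raises KeyError for unknown markers
        r, p = poses[seg]
        offsets[name] = r.T @ (np.asarray(world, dtype=float) - p)
    return model.with_marker_offsets(offsets)


def encoder_register(
    model: KinematicModel,
    static_markers: Dict[str, np.ndarray],
    encoder_q: Dict[str, float],
) -> RegistrationResult:
    """Pose the model with ground-truth encoder joint angles, solve the root
    by pelvis-marker least squares, then place markers."""
    q = np.zeros(model.n_coordinates)
    joint_names = [n for n in model.coordinate_names if not n.startswith("pelvis")]
    missing = [n for n in joint_names if n not in encoder_q]
    if missing:
        raise ValueError(f"encoder data missing joint coordinates: {missing}")
    for name in joint_names:
        q[model.coordinate_index(name)] = float(encoder_q[name])

    pelvis_markers = {
        n: static_markers[n]
        for n in model.segments["pelvis"].markers
        if n in static_markers
    }
    root_names = [a.coordinate for a in model.root_joint.axes]
    result = solve_frame(
        IKProblem(
            model=model,
            targets=pelvis_markers,
            initial_guess=q,
            free_coords=root_names,
        )
    )
    q_pose = result.q
    registered = place_markers_at_pose(model, q_pose, static_markers)
    return RegistrationResult(
        registered_model=registered,
        static_pose=q_pose,
        method="encoder",
        static_marker_rmse=_static_rmse(registered, q_pose, static_markers),
    )


def _with_virtual_frame_points(
    model: KinematicModel, segment_frames
) -> tuple:
    """Copy of the model carrying four virtual markers per anatomical frame
    (origin + 0.1 m along each axis, expressed in the segment frame)."""
    work = model.copy()
    targets_template = []
    for seg_name, frame in segment_frames.items():
        seg: Segment = work.segments[seg_name]
        o = frame.transform.translation
        r = frame.transform.rotation
        pts = [o] + [o + VIRTUAL_AXIS_LENGTH * r[:, k] for k in range(3)]
        for k, p in enumerate(pts):
            vname = f"__frame_{seg_name}_{k}"
            seg.markers[vname] = p
            targets_template.append((vname, seg_name, k))
    # rebuild marker bookkeeping
    return KinematicModel.from_dict(work.to_dict()), targets_template


def orientation_register(
    model: KinematicModel,
    static_markers: Dict[str, np.ndarray],
    frame_definitions: Sequence[FrameDefinition],
    initial_guess: Optional[np.ndarray] = None,
) -> RegistrationResult:
    """Pose the model by least-squares tracking of marker-derived anatomical
    frame orientations (and origins), then place markers."""
    experimental = {
        d.segment: build_frame(d, static_markers) for d in frame_definitions
    }
    model_side = model_frames(model, frame_definitions)
    work, template = _with_virtual_frame_points(model, model_side)
    targets = {}
    for vname, seg_name, k in template:
        f = experimental[seg_name].transform
        if k == 0:
            targets[vname] = f.translation
        else:
            targets[vname] = f.translation + VIRTUAL_AXIS_LENGTH * f.rotation[:, k - 1]
    result = solve_frame(
        IKProblem(model=work, targets=targets, initial_guess=initial_guess)
    )
    q_pose = result.q
    registered = place_markers_at_pose(model, q_pose, static_markers)
    return RegistrationResult(
        registered_model=registered,
        static_pose=q_pose,
        method="orientation",
        static_marker_rmse=_static_rmse(registered, q_pose, static_markers),
    )


def simulate_user_placement(
    model: KinematicModel,
    true_offsets: Optional[Dict[str, np.ndarray]] = None,
    sigma: float = 0.010,
    seed: int = 0,
) -> KinematicModel:
    """Stochastic surrogate for manual GUI marker placement: every marker's
    local offset is perturbed by an independent isotropic Gaussian (σ in
    meters). Reproducible under ``seed``."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    if true_offsets is None:
        true_offsets = {n: model.marker_offset(n) for n in model.marker_names}
    offsets = {
        name: np.asarray(off, dtype=float) + rng.normal(0.0, sigma, size=3)
        for name, off in true_offsets.items()
    }
    return model.with_marker_offsets(offsets)


def user_register(
    model_with_manual_markers: KinematicModel,
    static_markers: Dict[str, np.ndarray],
    initial_guess: Optional[np.ndarray] = None,
) -> RegistrationResult:
    """Pose the model by least-squares marker fit using the (possibly
    erroneous) manual offsets, then place markers. The static residual is
    still zero even though the pose is biased."""
    model = model_with_manual_markers
    known = set(model.marker_names)
    targets = {n: x for n, x in static_markers.items() if n in known}
    result = solve_frame(
        IKProblem(model=model, targets=targets, initial_guess=initial_guess)
    )
    q_pose = result.q
    registered = place_markers_at_pose(model, q_pose, static_markers)
    return RegistrationResult(
        registered_model=registered,
        static_pose=q_pose,
        method="user",
        static_marker_rmse=_static_rmse(registered, q_pose, static_markers),
    )


def encoder_dict_from_trajectory(traj, frame: int = 0) -> Dict[str, float]:
    """Joint-coordinate dictionary from one frame of an encoder trajectory."""
    return {
        name: float(traj.values[frame, traj.names.index(name)])
        for name in traj.names
        if name in JOINT_COORDS
    }
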