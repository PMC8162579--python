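"""Synthetic gait experiment for the humanoid-robot fixture.

Generates everything a real capture session would produce — a static
calibration trial, walking-trial marker trajectories (TRC), joint-encoder
angles (MOT), and ground-reaction wrenches (MOT) — from a known
ground-truth coordinate trajectory, so every downstream estimate can be
scored against truth.

The gait is a kinematic surrogate, not a controller simulation: ankle
trajectories are authored in task space (stationary during stance, a C²
quintic-smoothstep advance with a smooth clearance bump during swing) and
hip/knee/ankle flexion follow from closed-form planar two-link inverse
kinematics, with small sinusoidal frontal/transverse components. Ground
reactions are synthesized from whole-body Newton–Euler dynamics of the truth
kinematics — the total wrench is assigned to the stance foot (split by a
smooth weight during double support) with the center of pressure solved from
the moment balance — so inverse dynamics run on (truth, synthesized GRF)
closes with near-zero root residuals by construction.

Defaults follow the study conditions: walking speed 0.4 m/s, step length
0.33 m, 35 markers and encoders sampled at 200 Hz.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import model as model_mod
from .dynamics import (
    CoordinateTrajectory,
    GroundReaction,
    differentiate,
    spatial_kinematics,
    total_body_wrench,
)
from .fileio import (
    MarkerFrameSeries,
    MotTable,
    atomic_write_text,
    grf_to_table,
    write_mot,
    write_trc,
)
from .kinematics import _fk_core
from .model import JOINT_COORDS, KinematicModel, robot_fixture


@dataclass
class GaitSpec:
    """Parameters of the synthetic gait.

    ``speed`` (m/s) and ``step_length`` (m) fix the cycle: stride =
    2 × step_length, cycle duration = stride / speed. ``speed = step_length
    = 0`` denotes quiet standing. Angles in radians, lengths in meters.
    """

    speed: float = 0.4
    step_length: float = 0.33
    rate: float = 200.0
    n_cycles: int = 2
    hip_height: float = 0.50
    clearance: float = 0.04
    stance_fraction: float = 0.6
    strike_phase: float = 0.3  # right strikes at t = (k + strike_phase)·T
    pelvis_bob: float = 0.004
    pelvis_sway: float = 0.003
    hip_adduction_amp: float = np.deg2rad(1.5)
    hip_rotation_amp: float = np.deg2rad(1.5)
    ankle_inversion_amp: float = np.deg2rad(2.0)
    ankle_stance_height: float = model_mod.ANKLE_HEIGHT
    standing_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.speed < 0 or self.step_length < 0:
            raise ValueError("speed and step_length must be nonnegative")
        if (self.speed == 0) != (self.step_length == 0):
            raise ValueError(
                "speed and step_length must both be positive (walking) or "
                "both zero (standing)"
            )
        if not 0.5 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0.5, 1)")

    @property
    def standing(self) -> bool:
        return self.speed == 0.0

    @property
    def cycle_time(self) -> float:
        if self.standing:
            raise ValueError("standing spec has no gait cycle")
        return 2.0 * self.step_length / self.speed

    @property
    def stride_length(self) -> float:
        return 2.0 * self.step_length

    @property
    def duration(self) -> float:
        return (
            self.standing_duration
            if self.standing
            else self.n_cycles * self.cycle_time
        )

    @staticmethod
    def standing_spec(duration: float = 1.0, rate: float = 200.0) -> "GaitSpec":
        return GaitSpec(
            speed=0.0,
            step_length=0.0,
            rate=rate,
            hip_adduction_amp=0.0,
            hip_rotation_amp=0.0,
            ankle_inversion_amp=0.0,
            pelvis_bob=0.0,
            pelvis_sway=0.0,
            standing_duration=duration,
        )


def _smoothstep3(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smoothstep5(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 + u * (-15.0 + 6.0 * u))


def _leg_geometry(model: KinematicModel, side: str):
    l1 = -model.joints[f"knee_{side}"].frame_in_parent.translation[1]
    l2 = -model.joints[f"ankle_{side}"].frame_in_parent.translation[1]
    hip_z = model.joints[f"hip_{side}"].frame_in_parent.translation[2]
    return l1, l2, hip_z


def _planar_leg_ik(dx, dy, l1, l2):
    """Closed-form 2-link sagittal leg IK: hip and knee flexion plus the
    ankle flexion that keeps the foot level with the ground."""
    d2 = dx * dx + dy * dy
    cos_k = (d2 - l1 * l1 - l2 * l2) / (2.0 * l1 * l2)
    if np.any(cos_k > 1.0 - 1e-9):
        raise ValueError(
            "infeasible gait: leg fully extended (increase hip_height margin "
            "or reduce step length)"
        )
    if np.any(cos_k < -1.0 + 1e-9):
        raise ValueError("infeasible gait: target closer than the folded leg")
    k = np.arccos(cos_k)
    gamma = np.arctan2(l2 * np.sin(k), l1 + l2 * np.cos(k))
    theta = np.arctan2(dx, -dy) + gamma
    return theta, k, k - theta


def generate_gait(spec: GaitSpec, model: KinematicModel) -> CoordinateTrajectory:
    """Ground-truth coordinate trajectory for the given gait specification.

    The root advances at exactly ``spec.speed`` on average (the periodic
    bob/sway components integrate to zero over whole cycles) and successive
    ipsilateral foot strikes land exactly one stride (2 × step length)
    apart.
    """
    n = int(round(spec.duration * spec.rate)) + 1
    t = np.arange(n) / spec.rate
    q = np.zeros((n, model.n_coordinates))
    names = model.coordinate_names
    col = {name: i for i, name in enumerate(names)}

    if spec.standing:
        x_p = np.zeros(n)
        y_p = np.full(n, spec.hip_height)
        z_p = np.zeros(n)
    else:
        T = spec.cycle_time
        x_p = spec.speed * t
        y_p = spec.hip_height + spec.pelvis_bob * np.sin(4 * np.pi * t / T)
        z_p = spec.pelvis_sway * np.sin(2 * np.pi * t / T)

    q[:, col["pelvis_tx"]] = x_p
    q[:, col["pelvis_ty"]] = y_p
    q[:, col["pelvis_tz"]] = z_p

    h_a = spec.ankle_stance_height
    for side, half_shift in (("r", 0.0), ("l", 0.5)):
        l1, l2, _ = _leg_geometry(model, side)
        if spec.standing:
            ankle_x = np.zeros(n)
            ankle_y = np.full(n, h_a)
            phase_arg = np.zeros(n)
        else:
            T = spec.cycle_time
            off = spec.strike_phase + half_shift
            a = t / T - off
            k_cycle = np.floor(a)
            phi = a - k_cycle
            # land ahead by half the stance excursion so the hip-to-ankle
            # reach is symmetric about mid-stance (keeps the knee off its
            # straight-leg singularity at both strike and toe-off)
            land_ahead = spec.speed * spec.stance_fraction * T / 2.0
            strike_x = spec.speed * (k_cycle + off) * T + land_ahead
            swing = phi >= spec.stance_fraction
            u = (phi - spec.stance_fraction) / (1.0 - spec.stance_fraction)
            ankle_x = np.where(
                swing, strike_x + spec.stride_length * _smoothstep5(u), strike_x
            )
            bump = 64.0 * u**3 * (1.0 - u) ** 3
            ankle_y = h_a + np.where(swing, spec.clearance * bump, 0.0)
            phase_arg = 2 * np.pi * (t / T - off)

        theta, k, a_flex = _planar_leg_ik(ankle_x - x_p, ankle_y - y_p, l1, l2)
        q[:, col[f"hip_flexion_{side}"]] = theta
        q[:, col[f"knee_flexion_{side}"]] = k
        q[:, col[f"ankle_flexion_{side}"]] = a_flex
        q[:, col[f"hip_adduction_{side}"]] = spec.hip_adduction_amp * np.sin(phase_arg)
        q[:, col[f"hip_rotation_{side}"]] = spec.hip_rotation_amp * np.sin(
            phase_arg + np.pi / 3
        )
        q[:, col[f"ankle_inversion_{side}"]] = spec.ankle_inversion_amp * np.sin(
            phase_arg + np.pi / 6
        )
    return CoordinateTrajectory(time=t, values=q, names=names, rate=spec.rate)


def static_pose(model: KinematicModel, spec: Optional[GaitSpec] = None) -> np.ndarray:
    """Neutral standing pose (ankles under hips, feet level) as a coordinate
    vector."""
    spec = spec if spec is not None else GaitSpec.standing_spec()
    standing = replace(
        GaitSpec.standing_spec(duration=2.0 / spec.rate, rate=spec.rate),
        hip_height=spec.hip_height,
        ankle_stance_height=spec.ankle_stance_height,
    )
    return generate_gait(standing, model).values[0]


def synthesize_markers(
    model: KinematicModel,
    truth_q: CoordinateTrajectory,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MarkerFrameSeries:
    """Marker series from forward kinematics of the truth trajectory plus
    independent isotropic Gaussian measurement noise (σ in meters)."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    names = model.marker_names
    seg_of = {m: model.marker_segment(m) for m in names}
    offsets = np.asarray([model.marker_offset(m) for m in names])
    pos = np.empty((truth_q.n_frames, len(names), 3))
    for i in range(truth_q.n_frames):
        poses, _ = _fk_core(model, truth_q.values[i])
        for j, m in enumerate(names):
            r, p = poses[seg_of[m]]
            pos[i, j] = r @ offsets[j] + p
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, noise_sigma, size=pos.shape)
    return MarkerFrameSeries(names, truth_q.time.copy(), pos, truth_q.rate)


def support_weights(spec: GaitSpec, time: np.ndarray) -> np.ndarray:
    """(n, 2) smooth stance weights [right, left]; they sum to one.

    Full weight during single support; a cubic smoothstep hand-over across
    each double-support interval (stance_fraction − 0.5 of the cycle).
    """
    n = time.size
    if spec.standing:
        return np.full((n, 2), 0.5)
    T = spec.cycle_time
    ds = spec.stance_fraction - 0.5
    out = np.zeros((n, 2))
    for j, half_shift in ((0, 0.0), (1, 0.5)):
        phi = np.mod(time / T - spec.strike_phase - half_shift, 1.0)
        w = np.zeros(n)
        ramp_in = phi < ds
        w[ramp_in] = _smoothstep3(phi[ramp_in] / ds)
        mid = (phi >= ds) & (phi < 0.5)
        w[mid] = 1.0
        ramp_out = (phi >= 0.5) & (phi < spec.stance_fraction)
        w[ramp_out] = 1.0 - _smoothstep3((phi[ramp_out] - 0.5) / ds)
        out[:, j] = w
    return out


def _infer_support_weights(model, traj) -> np.ndarray:
    """Fallback stance weighting from foot heights (lower foot bears load)."""
    heights = np.zeros((traj.n_frames, 2))
    for i in range(traj.n_frames):
        poses, _ = _fk_core(model, traj.values[i])
        for j, seg in enumerate(("foot_r", "foot_l")):
            r, p = poses[seg]
            ys = [
                (r @ off + p)[1] for off in model.segments[seg].markers.values()
            ]
            heights[i, j] = min(ys)
    rel = heights - heights.min(axis=1, keepdims=True)
    c = np.clip(1.0 - rel / 0.01, 0.0, 1.0)
    return c / c.sum(axis=1, keepdims=True)


def synthesize_grf(
    model: KinematicModel,
    truth_q: CoordinateTrajectory,
    spec: Optional[GaitSpec] = None,
    support: Optional[np.ndarray] = None,
) -> List[GroundReaction]:
    """Dynamically consistent ground reactions for the truth kinematics.

    The whole-body Newton–Euler wrench is split between the feet by the
    stance weights (from ``spec`` phases, an explicit ``support`` array, or
    foot-height inference) and each share is expressed as a force at a
    center of pressure on the ground plane plus a vertical free moment.
    Where the vertical force is too small to define a COP (swing,
    hand-over edges) the wrench is carried as a full free moment about the
    ankle's ground projection, keeping the total exactly consistent.
    """
    qd, qdd = differentiate(truth_q)
    n = truth_q.n_frames
    if support is not None:
        w = np.asarray(support, dtype=float)
        if w.shape != (n, 2):
            raise ValueError("support must have shape (n_frames, 2)")
    elif spec is not None:
        w = support_weights(spec, truth_q.time)
    else:
        w = _infer_support_weights(model, truth_q)

    feet = ("foot_r", "foot_l")
    force = np.zeros((n, 2, 3))
    cop = np.zeros((n, 2, 3))
    free = np.zeros((n, 2, 3))
    min_fy = 1e-6 * model.total_mass * 9.80665
    for i in range(n):
        states, _ = spatial_kinematics(model, truth_q.values[i], qd[i], qdd[i])
        f_tot, m_tot = total_body_wrench(model, states)
        for j, foot in enumerate(feet):
            f = w[i, j] * f_tot
            m = w[i, j] * m_tot
            ankle = states[foot].origin
            anchor = np.array([ankle[0], 0.0, ankle[2]])
            if f[1] > min_fy:
                px = m[2] / f[1]
                pz = -m[0] / f[1]
                if (px - anchor[0]) ** 2 + (pz - anchor[2]) ** 2 < 0.35**2:
                    cop[i, j] = (px, 0.0, pz)
                    free[i, j] = (0.0, m[1] - pz * f[0] + px * f[2], 0.0)
                    force[i, j] = f
                    continue
            cop[i, j] = anchor
            free[i, j] = m - np.cross(anchor, f)
            force[i, j] = f
    return [
        GroundReaction(
            time=truth_q.time.copy(),
            force=force[:, j],
            cop=cop[:, j],
            free_moment=free[:, j],
            applied_body=feet[j],
        )
        for j in range(2)
    ]


# ---------------------------------------------------------------------- #
#  Full dataset
# ---------------------------------------------------------------------- #


@dataclass
class SyntheticTrial:
    """In-memory bundle of one synthetic experiment."""

    model: KinematicModel
    spec: GaitSpec
    seed: int
    noise_sigma: float
    truth: CoordinateTrajectory
    markers: MarkerFrameSeries
    static_markers: MarkerFrameSeries
    static_q: np.ndarray
    encoders: CoordinateTrajectory
    static_encoders: Dict[str, float]
    grf: List[GroundReaction]

    @property
    def body_weight(self) -> float:
        return self.model.total_mass * 9.80665


def _angles_table(traj: CoordinateTrajectory, model, name: str) -> MotTable:
    """Coordinate trajectory as a MOT table with rotations in degrees."""
    rotational = {
        a.coordinate
        for j in model.joints.values()
        for a in j.axes
        if a.kind == "rotation"
    }
    data = traj.values.copy()
    for i, cname in enumerate(traj.names):
        if cname in rotational:
            data[:, i] = np.rad2deg(data[:, i])
    return MotTable(list(traj.names), traj.time.copy(), data, True, name)


def make_dataset(
    spec: GaitSpec,
    noise_sigma: float = 0.0,
    seed: int = 0,
    out_dir=None,
    model: Optional[KinematicModel] = None,
) -> SyntheticTrial:
    """Generate the complete synthetic experiment; optionally write files.

    Deterministic under ``seed``: the same seed produces byte-identical
    files. Writes static/walking TRC, encoder, truth-angle and GRF MOT
    files plus JSON metadata into ``out_dir`` when given.
    """
    model = model if model is not None else robot_fixture()
    ss = np.random.SeedSequence(seed)
    seed_static, seed_walk = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]

    truth = generate_gait(spec, model)
    markers = synthesize_markers(model, truth, noise_sigma, seed_walk)
    grf = synthesize_grf(model, truth, spec=spec)

    q_static = static_pose(model, spec)
    n_static = int(round(1.0 * spec.rate)) + 1
    static_truth = CoordinateTrajectory(
        time=np.arange(n_static) / spec.rate,
        values=np.tile(q_static, (n_static, 1)),
        names=model.coordinate_names,
        rate=spec.rate,
    )
    static_markers = synthesize_markers(model, static_truth, noise_sigma, seed_static)

    joint_idx = [model.coordinate_index(c) for c in JOINT_COORDS]
    encoders = CoordinateTrajectory(
        time=truth.time.copy(),
        values=truth.values[:, joint_idx].copy(),
        names=list(JOINT_COORDS),
        rate=spec.rate,
    )
    static_encoders = {
        c: float(q_static[model.coordinate_index(c)]) for c in JOINT_COORDS
    }

    trial = SyntheticTrial(
        model=model,
        spec=spec,
        seed=seed,
        noise_sigma=noise_sigma,
        truth=truth,
        markers=markers,
        static_markers=static_markers,
        static_q=q_static,
        encoders=encoders,
        static_encoders=static_encoders,
        grf=grf,
    )
    if out_dir is not None:
        write_dataset(trial, out_dir)
    return trial


def write_dataset(trial: SyntheticTrial, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trc(trial.static_markers, out / "static.trc")
    write_trc(trial.markers, out / "walking.trc")
    write_mot(
        _angles_table(trial.encoders, trial.model, "encoders"), out / "encoders.mot"
    )
    write_mot(
        _angles_table(trial.truth, trial.model, "truth_angles"),
        out / "truth_angles.mot",
    )
    static_tab = MotTable(
        list(JOINT_COORDS),
        np.zeros(1),
        np.rad2deg(
            np.asarray([[trial.static_encoders[c] for c in JOINT_COORDS]])
        ),
        True,
        "static_encoders",
    )
    write_mot(static_tab, out / "static_encoders.mot")
    write_mot(grf_to_table(trial.grf), out / "grf.mot")
    meta = {
        "seed": trial.seed,
        "noise_sigma_m": trial.noise_sigma,
        "spec": {k: float(v) if isinstance(v, (int, float, np.floating)) else v
                 for k, v in asdict(trial.spec).items()},
        "model": trial.model.name,
        "body_weight_n": trial.body_weight,
    }
    atomic_write_text(out / "metadata.json", json.dumps(meta, indent=1) + "\n")
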