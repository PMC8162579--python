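"""Constrained inverse kinematics.

Per-frame weighted least-squares fit of model markers to observed world
positions over the generalized coordinates of a rigid-body kinematic chain:

    q* = argmin_q  Σ_i  w_i ‖x_i_obs − x_i(q)‖²

solved by a damped Gauss–Newton (Levenberg–Marquardt) iteration with the
analytic geometric Jacobian. Accepted iterations never increase the
objective. Missing observations (NaN triplets) are excluded per frame.

Termination: gradient ∞-norm < 1e-10, or accepted step norm < 1e-12, or
100 iterations (the result is then flagged unconverged, never silently
wrong). Optional per-coordinate bounds are enforced by projecting each
trial step (soft bounds; the solvers here never enforce joint limits as
hard constraints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import UnderdeterminedError
from .fileio import MarkerFrameSeries
from .kinematics import _fk_core

GRAD_TOL = 1e-10
STEP_TOL = 1e-12
MAX_ITER = 100


@dataclass
class IKProblem:
    """One frame of the weighted least-squares marker-tracking problem.

    ``targets`` maps marker names to observed world positions (meters); a
    NaN component marks the marker as missing for this frame. ``weights``
    defaults to 1.0 for every marker. ``free_coords`` optionally restricts
    the optimization to a subset of coordinates (the rest stay at the
    initial guess) — used e.g. to solve the root pose with joint angles
    frozen at encoder values.
    """

    model: object
    targets: Dict[str, np.ndarray]
    weights: Optional[Dict[str, float]] = None
    initial_guess: Optional[np.ndarray] = None
    bounds: Optional[tuple] = None
    free_coords: Optional[Sequence[str]] = None


@dataclass
class IKResult:
    q: np.ndarray
    residuals: Dict[str, float]
    objective: float
    converged: bool
    iterations: int
    marker_rms: float = 0.0


def _problem_arrays(problem: IKProblem):
    names, targets, weights = [], [], []
    for name, pos in problem.targets.items():
        pos = np.asarray(pos, dtype=float).reshape(3)
        if np.any(np.isnan(pos)):
            continue
        w = 1.0 if problem.weights is None else float(problem.weights.get(name, 1.0))
        if w < 0:
            raise ValueError(f"marker '{name}': weight must be nonnegative")
        if w == 0.0:
            continue
        names.append(name)
        targets.append(pos)
        weights.append(w)
    if len(names) < 3:
        raise UnderdeterminedError(
            f"only {len(names)} usable marker targets; at least 3 required"
        )
    t = np.asarray(targets)
    # collinearity check: rank of centered target cloud
    centered = t - t.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise UnderdeterminedError("usable targets are collinear; pose unobservable")
    return names, t, np.asarray(weights)


class _Tracker:
    """Vectorized residual/Jacobian evaluator for a fixed marker subset.

    Groups targets by segment so marker world positions are computed by one
    matrix product per segment, and precomputes, per coordinate, which
    marker rows it influences (the tree structure). Built once per marker
    subset and reused across frames of a trajectory.
    """

    def __init__(self, model, names: Sequence[str]):
        self.model = model
        self.names = list(names)
        row_of = {n: i for i, n in enumerate(self.names)}
        by_seg: Dict[str, list] = {}
        for n in self.names:
            by_seg.setdefault(model.marker_segment(n), []).append(n)
        self.groups = []  # (segment, row indices, offsets (k,3))
        for seg, ms in by_seg.items():
            rows = np.array([row_of[n] for n in ms], dtype=int)
            offs = np.array([model.marker_offset(n) for n in ms])
            self.groups.append((seg, rows, offs))
        path = model.path_coordinates()
        self.coord_rows: List[np.ndarray] = []
        for i in range(model.n_coordinates):
            rows = [
                rows_g
                for seg, rows_g, _ in self.groups
                if i in set(path[seg].tolist())
            ]
            self.coord_rows.append(
                np.concatenate(rows) if rows else np.empty(0, dtype=int)
            )

    def positions(self, q: np.ndarray):
        pre = _fk_core(self.model, q)
        poses = pre[0]
        xs = np.empty((len(self.names), 3))
        for seg, rows, offs in self.groups:
            r, p = poses[seg]
            xs[rows] = offs @ r.T + p
        return xs, pre

    def jacobian(self, xs: np.ndarray, info) -> np.ndarray:
        m = len(self.names)
        jm = np.zeros((m, 3, self.model.n_coordinates))
        for i, rows in enumerate(self.coord_rows):
            if rows.size == 0:
                continue
            ci = info[i]
            if ci.kind == "rotation":
                jm[rows, :, i] = np.cross(ci.axis, xs[rows] - ci.point)
            else:
                jm[rows, :, i] = ci.axis
        return jm.reshape(3 * m, self.model.n_coordinates)


def solve_frame(problem: IKProblem, _tracker: Optional[_Tracker] = None) -> IKResult:
    """Solve one frame of weighted least-squares marker tracking."""
    model = problem.model
    names, targets, weights = _problem_arrays(problem)
    sw = np.repeat(np.sqrt(weights), 3)
    tracker = (
        _tracker
        if _tracker is not None and _tracker.names == names
        else _Tracker(model, names)
    )

    q = (
        np.zeros(model.n_coordinates)
        if problem.initial_guess is None
        else np.asarray(problem.initial_guess, dtype=float).copy()
    )
    if q.shape != (model.n_coordinates,):
        raise ValueError("initial guess length does not match model coordinates")

    if problem.free_coords is None:
        free = np.ones(model.n_coordinates, dtype=bool)
    else:
        free = np.zeros(model.n_coordinates, dtype=bool)
        for cname in problem.free_coords:
            free[model.coordinate_index(cname)] = True

    lo = hi = None
    if problem.bounds is not None:
        lo = np.asarray(problem.bounds[0], dtype=float)
        hi = np.asarray(problem.bounds[1], dtype=float)
        q = np.clip(q, lo, hi)

    def evaluate(qv):
        xs, pre = tracker.positions(qv)
        res = ((xs - targets).ravel()) * sw
        return res, pre, xs

    res, pre, xs = evaluate(q)
    obj = float(res @ res)
    lam = 1e-3
    iters = 0
    converged = False
    while iters < MAX_ITER:
        iters += 1
        jac = tracker.jacobian(xs, pre[1])[:, free] * sw[:, None]
        grad = jac.T @ res
        if np.max(np.abs(grad), initial=0.0) < GRAD_TOL:
            converged = True
            break
        jtj = jac.T @ jac
        accepted = False
        for _ in range(25):
            try:
                step = np.linalg.solve(jtj + lam * np.eye(jtj.shape[0]), -grad)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            q_try = q.copy()
            q_try[free] = q[free] + step
            if lo is not None:
                q_try = np.clip(q_try, lo, hi)
            res_try, pre_try, xs_try = evaluate(q_try)
            obj_try = float(res_try @ res_try)
            if obj_try <= obj:
                step_norm = float(np.linalg.norm(q_try - q))
                q, res, pre, xs, obj = q_try, res_try, pre_try, xs_try, obj_try
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True  # no descent direction left: local minimum
            break
        if step_norm < STEP_TOL:
            converged = True
            break

    dists = np.linalg.norm(xs - targets, axis=1)
    return IKResult(
        q=q,
        residuals=dict(zip(names, dists.tolist())),
        objective=obj,
        converged=converged,
        iterations=iters,
        marker_rms=float(np.sqrt(np.mean(dists**2))),
    )


@dataclass
class TrajectoryResult:
    """Coordinate trajectory plus per-frame solver diagnostics."""

    trajectory: "object"  # dynamics.CoordinateTrajectory
    marker_rms: np.ndarray
    objective: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray


def solve_trajectory(
    model,
    marker_series: MarkerFrameSeries,
    weights: Optional[Dict[str, float]] = None,
    q0: Optional[np.ndarray] = None,
    bounds: Optional[tuple] = None,
) -> TrajectoryResult:
    """Frame-by-frame IK over a marker series, warm-started frame to frame.

    The first frame starts from ``q0`` (typically the registration static
    pose); each later frame starts from the previous solution, which also
    re-anchors the root-rotation parameterization away from gimbal lock.
    Per-frame failures are re-raised with the frame index attached.
    """
    from .dynamics import CoordinateTrajectory

    n = marker_series.n_frames
    qs = np.zeros((n, model.n_coordinates))
    rms = np.zeros(n)
    objs = np.zeros(n)
    conv = np.zeros(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    guess = q0 if q0 is not None else np.zeros(model.n_coordinates)
    known = set(model.marker_names)
    trackers: Dict[tuple, _Tracker] = {}
    for i in range(n):
        targets = {k: v for k, v in marker_series.frame(i).items() if k in known}
        key = tuple(targets)
        if key not in trackers:
            trackers[key] = _Tracker(model, list(key))
        try:
            result = solve_frame(
                IKProblem(
                    model=model,
                    targets=targets,
                    weights=weights,
                    initial_guess=guess,
                    bounds=bounds,
                ),
                _tracker=trackers[key],
            )
        except Exception as exc:
            raise type(exc)(f"frame {i} (t={marker_series.time[i]:.4f} s): {exc}")
        qs[i] = result.q
        rms[i] = result.marker_rms
        objs[i] = result.objective
        conv[i] = result.converged
        iters[i] = result.iterations
        guess = result.q
    traj = CoordinateTrajectory(
        time=marker_series.time.copy(),
        values=qs,
        names=model.coordinate_names,
        rate=marker_series.rate,
    )
    return TrajectoryResult(traj, rms, objs, conv, iters)
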