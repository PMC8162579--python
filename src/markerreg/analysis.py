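"""Signal processing and the evaluation protocol.

Filtering (zero-phase low-pass Butterworth, default fourth order / 8 Hz
cutoff, the standard treatment for optical marker and force-plate data),
gait-event detection by vertical-force thresholding, normalization to
percent gait cycle (101 points), and the RMSE-based comparison of
registered models against ground-truth encoder kinematics and reference
moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .dynamics import (
    CoordinateTrajectory,
    GroundReaction,
    MomentTrajectory,
    inverse_dynamics,
)
from .fileio import MarkerFrameSeries
from .ik import solve_trajectory
from .model import RIGHT_LEG_COORDS

DEFAULT_CUTOFF_HZ = 8.0
DEFAULT_ORDER = 4
EVENT_THRESHOLD_FRACTION = 0.05
MIN_PHASE_DURATION_S = 0.050
CYCLE_POINTS = 101


def butterworth_lowpass(
    x: np.ndarray, rate: float, cutoff: float = DEFAULT_CUTOFF_HZ, order: int = DEFAULT_ORDER
) -> np.ndarray:
    """Zero-phase (forward–backward) low-pass Butterworth along axis 0.

    Two-pass filtering doubles the effective order and cancels phase lag,
    so filtered events keep their timing. Length is preserved.
    """
    if not 0.0 < cutoff < rate / 2.0:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist) = (0, {rate / 2:g}) Hz, got {cutoff:g}"
        )
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def filter_marker_series(
    series: MarkerFrameSeries, cutoff: float = DEFAULT_CUTOFF_HZ, order: int = DEFAULT_ORDER
) -> MarkerFrameSeries:
    """Low-pass each marker trajectory; fully missing channels pass through."""
    pos = series.positions.copy()
    flat = pos.reshape(series.n_frames, -1)
    good = ~np.any(np.isnan(flat), axis=0)
    flat[:, good] = butterworth_lowpass(flat[:, good], series.rate, cutoff, order)
    return MarkerFrameSeries(
        list(series.names), series.time.copy(), flat.reshape(pos.shape), series.rate
    )


@dataclass
class GaitEvents:
    """Foot strikes and foot offs for one side, strictly alternating."""

    strikes: np.ndarray
    offs: np.ndarray
    side: str = ""

    def cycles(self) -> List[tuple]:
        """(t_strike, t_next_strike) pairs — the gait cycles of this side."""
        return [
            (self.strikes[i], self.strikes[i + 1])
            for i in range(len(self.strikes) - 1)
        ]


def detect_gait_events(
    grf: GroundReaction,
    body_weight: float,
    threshold_fraction: float = EVENT_THRESHOLD_FRACTION,
    min_phase_duration: float = MIN_PHASE_DURATION_S,
) -> GaitEvents:
    """Threshold-crossing gait events from one plate's vertical force.

    Foot strike when the vertical force rises through
    ``threshold_fraction × body_weight``; foot off when it falls through.
    Contact or flight phases shorter than ``min_phase_duration`` are
    discarded as bounce.
    """
    if threshold_fraction <= 0:
        raise ValueError("threshold_fraction must be positive")
    fy = grf.vertical_force
    thr = threshold_fraction * body_weight
    above = fy >= thr
    changes = np.flatnonzero(np.diff(above.astype(int)))
    events = [(grf.time[i + 1], above[i + 1]) for i in changes]
    # debounce: drop phase pairs shorter than the minimum duration
    cleaned: List[tuple] = []
    for t, rising in events:
        if cleaned and (t - cleaned[-1][0]) < min_phase_duration:
            cleaned.pop()
        else:
            cleaned.append((t, rising))
    strikes = np.array([t for t, rising in cleaned if rising])
    offs = np.array([t for t, rising in cleaned if not rising])
    return GaitEvents(strikes=strikes, offs=offs, side=grf.applied_body)


def normalize_gait_cycle(
    time: np.ndarray, values: np.ndarray, cycle: tuple
) -> np.ndarray:
    """Linearly resample onto 101 equally spaced percentages of one cycle."""
    t0, t1 = cycle
    if t0 < time[0] - 1e-9 or t1 > time[-1] + 1e-9 or t1 <= t0:
        raise ValueError(
            f"cycle [{t0:g}, {t1:g}] outside data range "
            f"[{time[0]:g}, {time[-1]:g}]"
        )
    grid = np.linspace(t0, t1, CYCLE_POINTS)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return np.interp(grid, time, values)
    return np.column_stack(
        [np.interp(grid, time, values[:, j]) for j in range(values.shape[1])]
    )


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """√(mean((a − b)²)); symmetric, nonnegative, zero iff equal."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------- #
#  Evaluation protocol
# ---------------------------------------------------------------------- #


@dataclass
class EvaluationReport:
    """Per-DOF angle RMSE (deg), per-DOF moment RMSE (N·m, single-leg
    stance), and pooled marker RMSE (mm, mean ± SD over time points)."""

    method: str
    angle_rmse_deg: Dict[str, float]
    moment_rmse_nm: Optional[Dict[str, float]]
    marker_rmse_mm_mean: float
    marker_rmse_mm_sd: float
    cycle: tuple = ()
    stance_window: tuple = ()

    @property
    def mean_angle_rmse_deg(self) -> float:
        return float(np.mean(list(self.angle_rmse_deg.values())))

    @property
    def mean_moment_rmse_nm(self) -> Optional[float]:
        if not self.moment_rmse_nm:
            return None
        return float(np.mean(list(self.moment_rmse_nm.values())))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "angle_rmse_deg": self.angle_rmse_deg,
            "mean_angle_rmse_deg": self.mean_angle_rmse_deg,
            "moment_rmse_nm": self.moment_rmse_nm,
            "mean_moment_rmse_nm": self.mean_moment_rmse_nm,
            "marker_rmse_mm": {
                "mean": self.marker_rmse_mm_mean,
                "sd": self.marker_rmse_mm_sd,
            },
        }


def single_support_window(
    stance_grf: GroundReaction,
    other_grf: GroundReaction,
    body_weight: float,
    cycle: tuple,
    threshold_fraction: float = EVENT_THRESHOLD_FRACTION,
) -> tuple:
    """Time window inside ``cycle`` where only the stance foot bears load:
    from the other foot's foot-off to its next foot-strike."""
    other = detect_gait_events(other_grf, body_weight, threshold_fraction)
    t0, t1 = cycle
    offs = other.offs[(other.offs > t0) & (other.offs < t1)]
    if offs.size == 0:
        raise ValueError("no contralateral foot-off inside the gait cycle")
    start = float(offs[0])
    strikes = other.strikes[(other.strikes > start) & (other.strikes <= t1)]
    end = float(strikes[0]) if strikes.size else t1
    return (start, end)


def marker_error_series(
    model, traj: CoordinateTrajectory, observed: MarkerFrameSeries
) -> np.ndarray:
    """Per-frame RMS distance (m) between model markers posed at the IK
    solution and the observed markers, pooled over all markers."""
    from .ik import _Tracker

    names = [n for n in observed.names if n in set(model.marker_names)]
    cols = [observed.names.index(n) for n in names]
    tracker = _Tracker(model, names)
    out = np.zeros(traj.n_frames)
    for i in range(traj.n_frames):
        xs, _ = tracker.positions(traj.values[i])
        d2 = np.sum((xs - observed.positions[i, cols]) ** 2, axis=1)
        out[i] = np.sqrt(np.nanmean(d2))
    return out


def evaluate_registration(
    registered_model,
    walking_markers: MarkerFrameSeries,
    grfs: Sequence[GroundReaction],
    truth_angles: CoordinateTrajectory,
    reference_moments: Optional[MomentTrajectory] = None,
    static_pose: Optional[np.ndarray] = None,
    method: str = "",
    dofs: Sequence[str] = tuple(RIGHT_LEG_COORDS),
    stance_body: str = "foot_r",
) -> EvaluationReport:
    """Run constrained IK (and inverse dynamics) with a registered model over
    one gait cycle and score it against ground truth.

    Angle RMSE is computed in degrees per right-leg DOF on the 101-point
    normalized cycle against the encoder ground truth; moment RMSE is
    computed at native sampling inside the single-support window against
    ``reference_moments`` (conventionally those of the encoder-registered
    model); marker RMSE is pooled over all markers, reported per time point
    as mean ± SD in millimeters.
    """
    ikres = solve_trajectory(
        registered_model, walking_markers, q0=static_pose
    )
    traj = ikres.trajectory
    body_weight = registered_model.total_mass * 9.80665

    stance = next(g for g in grfs if g.applied_body == stance_body)
    other = next(g for g in grfs if g.applied_body != stance_body)
    events = detect_gait_events(stance, body_weight)
    if len(events.strikes) < 2:
        raise ValueError("need at least two ipsilateral foot strikes")
    cycle = (float(events.strikes[0]), float(events.strikes[1]))

    angle_rmse: Dict[str, float] = {}
    for dof in dofs:
        est = normalize_gait_cycle(traj.time, np.rad2deg(traj.column(dof)), cycle)
        tru = normalize_gait_cycle(
            truth_angles.time, np.rad2deg(truth_angles.column(dof)), cycle
        )
        angle_rmse[dof] = rmse(est, tru)

    moment_rmse: Optional[Dict[str, float]] = None
    window = ()
    if reference_moments is not None:
        window = single_support_window(stance, other, body_weight, cycle)
        moments = inverse_dynamics(registered_model, traj, grfs)
        sel = (moments.time >= window[0]) & (moments.time <= window[1])
        moment_rmse = {
            dof: rmse(
                moments.column(dof)[sel], reference_moments.column(dof)[sel]
            )
            for dof in dofs
        }

    err = marker_error_series(registered_model, traj, walking_markers) * 1000.0
    insel = (traj.time >= cycle[0]) & (traj.time <= cycle[1])
    err = err[insel]
    return EvaluationReport(
        method=method,
        angle_rmse_deg=angle_rmse,
        moment_rmse_nm=moment_rmse,
        marker_rmse_mm_mean=float(err.mean()),
        marker_rmse_mm_sd=float(err.std(ddof=0)),
        cycle=cycle,
        stance_window=window,
    )


def aggregate_reports(reports: Sequence[EvaluationReport]) -> dict:
    """Mean ± SD across users/seeds, mirroring the per-method table layout."""
    dofs = list(reports[0].angle_rmse_deg)
    out: dict = {"n": len(reports), "angle_rmse_deg": {}, "moment_rmse_nm": {}}
    for dof in dofs:
        vals = np.array([r.angle_rmse_deg[dof] for r in reports])
        out["angle_rmse_deg"][dof] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)),
        }
    if all(r.moment_rmse_nm for r in reports):
        for dof in dofs:
            vals = np.array([r.moment_rmse_nm[dof] for r in reports])
            out["moment_rmse_nm"][dof] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
            }
    marker = np.array([r.marker_rmse_mm_mean for r in reports])
    out["marker_rmse_mm"] = {
        "mean": float(marker.mean()),
        "sd": float(np.mean([r.marker_rmse_mm_sd for r in reports])),
    }
    return out
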