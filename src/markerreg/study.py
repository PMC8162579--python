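"""End-to-end study pipelines composing the toolkit modules.

The full protocol mirrors a robot gait experiment: synthesize a dataset
(static + walking trials, encoders, ground reactions), register the model
by each method (encoder, orientation, and several simulated users), run
constrained inverse kinematics and inverse dynamics with each registered
model, and score everything against the encoder ground truth. Joint-moment
accuracy is referenced to the encoder-registered model's moments, since no
moment ground truth exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .analysis import (
    EvaluationReport,
    aggregate_reports,
    evaluate_registration,
    filter_marker_series,
)
from .dynamics import MomentTrajectory, inverse_dynamics
from .frames import default_frame_definitions
from .ik import solve_trajectory
from .model import RIGHT_LEG_COORDS, KinematicModel
from .registration import (
    RegistrationResult,
    encoder_register,
    orientation_register,
    simulate_user_placement,
    user_register,
)
from .synthetic import GaitSpec, SyntheticTrial, make_dataset


@dataclass
class StudyResult:
    trial: SyntheticTrial
    registrations: Dict[str, object]
    encoder_report: EvaluationReport
    orientation_report: EvaluationReport
    user_reports: List[EvaluationReport]
    user_aggregate: dict

    def to_dict(self) -> dict:
        return {
            "seed": self.trial.seed,
            "encoder": self.encoder_report.to_dict() if self.encoder_report else None,
            "orientation": self.orientation_report.to_dict(),
            "user": self.user_aggregate,
            "n_users": len(self.user_reports),
        }


def _user_seeds(seed: int, n_users: int) -> List[int]:
    ss = np.random.SeedSequence([seed, 0xC0FFEE])
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_users)]


def run_study(
    seed: int = 1,
    n_users: int = 5,
    sigma_user: float = 0.010,
    noise_sigma: float = 0.0005,
    spec: Optional[GaitSpec] = None,
    lowpass_hz: Optional[float] = 8.0,
    with_moments: bool = True,
    include_encoder: bool = True,
    model: Optional[KinematicModel] = None,
    trial: Optional[SyntheticTrial] = None,
) -> StudyResult:
    """One full replication: synthesize, register three ways, evaluate.

    ``sigma_user`` is the simulated manual-placement error (m) and
    ``noise_sigma`` the marker measurement noise (m). Marker trajectories
    are low-pass filtered before IK unless ``lowpass_hz`` is None.
    """
    spec = spec if spec is not None else GaitSpec()
    if trial is None:
        trial = make_dataset(spec, noise_sigma=noise_sigma, seed=seed, model=model)
    nominal = trial.model
    static_avg = trial.static_markers.mean_positions()
    walking = (
        filter_marker_series(trial.markers, lowpass_hz)
        if lowpass_hz
        else trial.markers
    )

    enc = (
        encoder_register(nominal, static_avg, trial.static_encoders)
        if (include_encoder or with_moments)
        else None
    )
    orient = orientation_register(nominal, static_avg, default_frame_definitions())
    users: List[RegistrationResult] = []
    for useed in _user_seeds(seed, n_users):
        manual = simulate_user_placement(nominal, sigma=sigma_user, seed=useed)
        users.append(user_register(manual, static_avg))

    reference: Optional[MomentTrajectory] = None
    if with_moments:
        enc_ik = solve_trajectory(
            enc.registered_model, walking, q0=enc.static_pose
        ).trajectory
        reference = inverse_dynamics(enc.registered_model, enc_ik, trial.grf)

    def score(reg, method):
        return evaluate_registration(
            reg.registered_model,
            walking,
            trial.grf,
            trial.truth,
            reference_moments=reference if method != "encoder" else None,
            static_pose=reg.static_pose,
            method=method,
        )

    enc_report = score(enc, "encoder") if include_encoder else None
    orient_report = score(orient, "orientation")
    user_reports = [score(u, "user") for u in users]

    return StudyResult(
        trial=trial,
        registrations={"encoder": enc, "orientation": orient, "user": users},
        encoder_report=enc_report,
        orientation_report=orient_report,
        user_reports=user_reports,
        user_aggregate=aggregate_reports(user_reports),
    )


@dataclass
class EnsembleResult:
    """Directional comparison of orientation vs. user registration over
    repeated synthetic experiments."""

    per_rep_wins: List[int]  # DOFs (of 6) where orientation beat the user mean
    orientation_mean_rmse: np.ndarray  # (reps, dofs) deg
    user_mean_rmse: np.ndarray  # (reps, dofs) deg
    dofs: List[str] = field(default_factory=lambda: list(RIGHT_LEG_COORDS))

    @property
    def reps_with_majority(self) -> int:
        """Repetitions where orientation won at least 5 of the 6 DOFs."""
        return int(sum(w >= 5 for w in self.per_rep_wins))


def run_ensemble(
    seed: int = 1,
    n_reps: int = 10,
    n_users: int = 5,
    sigma_user: float = 0.010,
    noise_sigma: float = 0.0005,
    spec: Optional[GaitSpec] = None,
    lowpass_hz: Optional[float] = 8.0,
) -> EnsembleResult:
    """Repeat the angle-RMSE comparison over ``n_reps`` independent synthetic
    experiments (fresh marker noise and fresh simulated users each time)."""
    spec = spec if spec is not None else GaitSpec()
    rep_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence([seed, 0xE15EB1E]).spawn(n_reps)
    ]
    wins, orients, users = [], [], []
    for rseed in rep_seeds:
        res = run_study(
            seed=rseed,
            n_users=n_users,
            sigma_user=sigma_user,
            noise_sigma=noise_sigma,
            spec=spec,
            lowpass_hz=lowpass_hz,
            with_moments=False,
            include_encoder=False,
        )
        o = np.array(
            [res.orientation_report.angle_rmse_deg[d] for d in RIGHT_LEG_COORDS]
        )
        u = np.array(
            [
                res.user_aggregate["angle_rmse_deg"][d]["mean"]
                for d in RIGHT_LEG_COORDS
            ]
        )
        wins.append(int(np.sum(o < u)))
        orients.append(o)
        users.append(u)
    return EnsembleResult(
        per_rep_wins=wins,
        orientation_mean_rmse=np.asarray(orients),
        user_mean_rmse=np.asarray(users),
    )
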