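# markerreg

A rigid-body motion-capture toolkit for studying **marker registration** —
the step where a biomechanical model's markers are positioned to coincide
with the experimental markers on the subject — and its downstream effect on
joint angles and moments computed by **constrained inverse kinematics**.

## Who this is for

Movement scientists and biomechanists who use optical motion capture with
jointed rigid-body models. Constrained IK estimates generalized coordinates
`q` (6-DOF pelvis root + joint angles) by minimizing

```
q* = argmin_q  Σᵢ wᵢ ‖xᵢ_obs − xᵢ(q)‖²
```

over model markers `xᵢ(q)`. Its accuracy hinges on marker registration, and
registration has a trap: after placing each model marker at its observed
static-trial position, the static marker residual is **zero by
construction, whatever pose was used** — so a small residual can never
certify a good registration. This package implements and compares three
registration strategies on a synthetic humanoid robot whose true joint
angles are known:

- **encoder registration** — pose from ground-truth joint encoders
  (idealized reference; the root is solved from the pelvis markers);
- **orientation registration** — pose from anatomical reference frames
  built out of the static markers (pelvis ASIS/PSIS, knee/ankle flexion-axis
  pairs, foot heel–toe), tracked in the least-squares sense; systematic, no
  user input;
- **user registration** — a stochastic surrogate for manual GUI placement
  (isotropic Gaussian offsets, seeded "users"), followed by marker-fit
  posing.

Around this core the package provides forward kinematics with analytic
Jacobians, a damped Gauss–Newton IK solver, anatomical frame construction,
recursive Newton–Euler inverse dynamics, zero-phase Butterworth filtering,
gait-event detection and percent-gait-cycle analysis, TRC/MOT file I/O, a
12-DOF 35-marker robot model, and a synthetic gait generator whose ground
reactions are dynamically consistent with its kinematics. Conventions:
right-handed, Y up, X forward; meters and radians internally; degrees and
millimeters at file boundaries. See `docs/methods.md` for the science.

## Worked example

Run the whole study design — synthesize a gait dataset (0.4 m/s, 0.33 m
steps, 35 markers at 200 Hz, 0.5 mm marker noise), register the model by
all three methods (five simulated users at σ = 10 mm), run constrained IK
and inverse dynamics, and score everything against the encoder truth:

```sh
markerreg replicate --seed 1 --out report.json
```

which prints (about a minute on one CPU):

```
dof                 encoder angle (deg)  orientation angle (deg)  user angle (deg)
hip_flexion_r       0.02                 0.02                     0.99 ± 0.67
hip_adduction_r     0.02                 0.03                     1.68 ± 0.75
hip_rotation_r      0.04                 0.05                     3.58 ± 2.35
knee_flexion_r      0.03                 0.03                     1.72 ± 0.66
ankle_flexion_r     0.06                 0.06                     4.46 ± 2.66
ankle_inversion_r   0.10                 0.10                     7.85 ± 3.92
marker error (mm)   0.2 ± 0.0            0.2 ± 0.0                1.0 ± 0.4
```

Reading it: each row is the RMSE of one right-leg joint angle over the
normalized gait cycle against the robot's encoders. Orientation
registration is indistinguishable from the encoder reference on this
synthetic robot, while simulated manual placement inflates every DOF —
worst in ankle inversion, where the lever arms are shortest — and the
errors appear as near-constant offsets in otherwise similar trajectories.
Meanwhile the *marker* error stays around a millimeter for every method:
marker residuals do not diagnose registration error. The JSON twin of the
table (plus single-support joint-moment RMSE against the encoder-registered
model) lands in `report.json`.

The same pieces are scriptable:

```python
import markerreg as mr

study = mr.run_study(seed=1, n_users=5, sigma_user=0.010, noise_sigma=0.0005)
print(study.orientation_report.mean_angle_rmse_deg)   # 0.049
print(study.user_aggregate["angle_rmse_deg"]["ankle_inversion_r"])
```

Individual stages are exposed as CLI subcommands too: `synth`, `register`,
`ik`, `id`, `evaluate`.

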