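# Methods

## Problem

Constrained inverse kinematics (IK) estimates the generalized coordinates
`q` of a jointed rigid-body model by minimizing the weighted squared
distance between model-fixed markers and their measured counterparts:

    q* = argmin_q Σᵢ wᵢ ‖xᵢ_obs − xᵢ(q)‖².

Before IK can run, the model markers must be *registered*: moved so that at
a static calibration pose they coincide with the experimental markers. The
catch this package demonstrates is that **registration is exactly
consistent with the static trial no matter how wrong the pose was** —
placing each marker at the observed position renders the static residual
zero by construction — so a small marker residual can never certify an
accurate registration. What differs between methods is the *pose* used for
placement, and that difference propagates into joint angles and moments as
near-constant offsets.

Three registration strategies are implemented:

- **Encoder registration** (idealized reference): the twelve joint angles
  are taken from joint encoders (ground truth on a robot); only the
  six-DOF pelvis-to-ground root is solved, by least-squares fit of the
  pelvis markers with the joint angles frozen. The root completion is this
  package's choice — encoders cannot observe the root.
- **Orientation registration** (the systematic method): anatomical
  reference frames for pelvis, thighs, shanks and feet are built from the
  static markers (Gram–Schmidt on marker-pair directions; the thigh and
  shank mediolateral axes come from the knee- and ankle-flexion-axis marker
  pairs), and the model is posed by least-squares tracking of those frames.
  The orientation objective is realized through *virtual frame points*:
  each frame contributes its origin plus three points 0.1 m along its axes
  as unit-weight targets to the ordinary marker solver. This mirrors
  tracking orientations with a position-residual solver and is a swappable
  strategy; 0.1 m makes 1 rad of orientation error commensurate with 0.1 m
  of origin error.
- **User registration** (simulated): manual GUI placement is modeled as an
  isotropic Gaussian perturbation of every marker's segment-fixed offset
  (default σ = 10 mm, five independent seeded "users"). The pose is then
  solved by ordinary marker IK with those wrong offsets. The Gaussian
  surrogate is an assumption: real users produce structured, correlated
  errors; only aggregate error magnitudes are emulated.

## Model and conventions

World frame: right-handed, **Y up, X forward**, Z to the subject's right.
Lengths in meters, angles in radians, masses in kg; degrees appear only at
file and report boundaries. Joints compose intrinsic successive rotations
about declared unit axes between fixed parent/child frames; the root is a
6-DOF free joint (translations, then Z-X-Y intrinsic rotations). Trunk and
head are welded to the pelvis chain (0-axis joints); arms are absent.

The bundled robot fixture (`robot.model.json`) is a child-sized biped:
twelve lower-extremity DOFs (hip flexion/adduction/rotation, knee flexion,
ankle flexion/inversion per side), thigh 0.26 m, shank 0.25 m, hips
±0.082 m off the midline, ankle 0.06 m above the sole, total mass 15.5 kg.
Its 35 markers follow the classic gait set: 3 per foot/shank/thigh, 2 per
knee and ankle flexion axis, 4 pelvis, 2 trunk, 3 head. Link lengths and
inertias (cylinder/box approximations) are documented stand-ins at child
proportions — no published robot geometry is reproduced — chosen so a
0.33 m step is comfortable.

## Solvers

**IK** is a damped Gauss–Newton (Levenberg) iteration with the analytic
geometric Jacobian (rotational column `s × (x − p)`, translational column
`s`). Termination: gradient ∞-norm < 1e-10, accepted step < 1e-12, or 100
iterations (then flagged unconverged). Steps that would increase the
objective are rejected and the damping raised, so the objective is
monotone over accepted iterations. Missing markers (NaN) are excluded per
frame; weights default to 1. Trajectories are solved frame by frame,
warm-started from the previous solution, which also re-anchors the root
Euler parameterization away from gimbal lock (gait never approaches ±90°
root pitch). Optional per-coordinate bounds are soft (projected steps);
joint limits are never hard constraints.

**Inverse dynamics** propagates angular velocity/acceleration and linear
acceleration outward through the tree (Newton–Euler), then projects each
segment's required wrench, `m(a_com − g)` and `Iα + ω×Iω`, onto every
coordinate's instantaneous spatial axis (Jacobian-transpose form —
algebraically the inward recursion). Measured ground reactions enter as a
force at the center of pressure plus a free moment on the stance foot.
Rotational coordinates yield joint moments in N·m about the joint axes
(generalized forces); the six root coordinates yield residual force and
moment, which vanish when kinematics and ground reactions are mutually
consistent. Coordinates are differentiated with 4th-order central stencils
(2nd-order one-sided at the ends); the higher order keeps the acceleration
error of 1 Hz motion sampled at 200 Hz below 1e-3 s⁻², which 2nd-order
stencils cannot achieve.

## Signal processing and evaluation

Marker (and force) series are low-pass filtered with a zero-phase
forward–backward Butterworth filter, default 4th order with an 8 Hz
cutoff — the common treatment for gait data; two-pass application doubles
the effective order and cancels phase lag, so event timing is preserved.
Gait events come from vertical-force threshold crossings (default 5% of
body weight, 50 ms debounce). Kinematics are compared on a 101-point
percent-gait-cycle grid (linear interpolation between successive
ipsilateral foot strikes); angle RMSE is reported in degrees per right-leg
DOF. Joint-moment RMSE is computed at native sampling inside the
single-support window (contralateral foot-off to foot-strike) against the
encoder-registered model's moments, since no moment ground truth exists.
Marker RMSE pools all markers, per time point, reported as mean ± SD in mm
over the cycle. User results aggregate as mean ± SD across seeds.

## Synthetic experiment

The generator produces everything a capture session would: a 1 s static
trial, walking-trial markers (TRC, mm), encoder angles (MOT, deg), and
per-foot ground reactions (MOT), all at 200 Hz, deterministic under one
seed. Defaults are the study conditions: 0.4 m/s walking speed, 0.33 m
steps (stride 0.66 m, cycle 1.65 s), two cycles.

Gait kinematics are authored in task space, not simulated from a
controller: each ankle is stationary at its strike position during stance
(60% of the cycle) and advances one stride during swing along a quintic
smoothstep with a C² clearance bump (4 cm); the pelvis advances at exactly
the nominal speed plus zero-mean bob/sway; hip and knee flexion follow
from closed-form planar two-link IK, the ankle flexion keeps the foot
level, and small sinusoids (1.5–2°) animate hip adduction/rotation and
ankle inversion. Feet strike half a stance-excursion ahead of the pelvis,
centering the leg's reach so the knee stays well off its straight-leg
singularity (knee flexion ranges ≈ 33–75°; the robot walks crouched, as
small humanoids do). Measurement noise is independent isotropic Gaussian
per marker per frame (default 0.5 mm in studies).

Ground reactions are synthesized from the dynamics of the truth
kinematics: the whole-body Newton–Euler wrench is assigned to the stance
foot, split by a smooth cubic hand-over weight during double support (10%
of the cycle per side), with the COP solved on the ground plane from the
moment balance and a vertical free moment carrying the remainder. Where
the vertical force share is too small to define a COP, the share is
carried as a full free moment about the ankle's ground projection. By
construction, inverse dynamics on (truth, synthesized GRF) closes with
root residuals at numerical precision — the closure is asserted at < 1% of
body weight.

**What the generator does not emulate:** soft-tissue artifact (absent on a
robot by design), geometric model–subject mismatch, camera-dependent noise
structure, marker occlusion patterns, and a physically controlled gait.
Passing tests therefore demonstrate the *method logic* — that registration
pose error, and nothing else, drives the angle/moment errors — not
magnitudes transferable to human data. Because the synthetic model matches
the synthetic robot exactly, orientation registration is nearly exact here
and its advantage over simulated users is larger than would be observed
with real hardware; comparisons are asserted directionally, never against
any published magnitude.

## Numerical choices and limitations

- Registration placement is exact (static residual ~1e-16 m); tests assert
  < 1e-9 m.
- Frame construction requires the two defining directions to subtend ≥ 1°;
  closer is a degenerate-frame error.
- COP fallback radius 0.35 m from the ankle projection; hand-over weight is
  a cubic smoothstep; event debounce 50 ms.
- The evaluation trial is two gait cycles (661 frames at 200 Hz); the
  directional ensemble uses 10 repetitions × 5 users, sized so the whole
  comparison runs in minutes on one CPU.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds give byte-identical files.
- Known limitations: no double-support force attribution fidelity, no
  muscle or contact modeling, no marker-weight tuning, no global/multistart
  IK, Euler-angle root (re-anchored, but still a chart), and the Gaussian
  user model above.
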