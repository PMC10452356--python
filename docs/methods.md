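# Methods

This note documents the models, algorithms and numerical choices behind
`armclone`, in the order the pipeline runs.

## Task geometry and timing

The center-out-center reaching task uses eight targets evenly spaced on
a horizontal circle of diameter 0.5 m. The grid center defaults to
(0.35, 0.0, −0.25) m relative to the shoulder — a comfortable
desk-height plane in front of the body; the circle's position relative
to the body is a modelling choice, as is the target numbering (target 1
farthest from the body, numbering clockwise from above).

Each trial has four phases: reach (2.0 s, matching the cue interval of
the experimental protocol the task emulates), touch hold (0.5 s),
return (2.0 s) and center wait (1.0 s), sampled at 50 Hz (dt = 0.02 s).
The 5 s return-plus-wait interval of the human protocol is split 2.0 s
return + 0.5 s hold + 1.0 s wait as a design choice; all components are
configurable. The moving reference point travels in straight lines at
constant speed during reach and return.

## Arm model

The arm is a 7-DOF serial chain: 3-DOF shoulder (abduction about +z,
flexion about +y, internal rotation about the humerus axis), 2-DOF
elbow (flexion, pronation) and 2-DOF wrist (flexion, abduction), with
segment lengths 0.30 / 0.25 / 0.18 m (upper arm / forearm / hand) —
typical adult anthropometry, configurable. The frame is right-handed
with x forward, y left, z up; the zero pose is the arm extended along
+x with the palm down.

Positive **elbow flexion rotates about the local −y axis** (raising the
forearm of the palm-down zero pose). This is the anatomically correct
direction for a pronated arm — with the arm extended palm-down,
flexing the elbow brings the hand up — and it is also geometrically
necessary: with the opposite sign, holding the palm down during
desk-plane reaching would require ~180° of elbow pronation, outside any
anatomical range. With this convention, pronation stays within ±40°
for the whole task workspace.

Joint limits (degrees): shoulder abduction [−30, 180], flexion
[−60, 180], rotation ±165, elbow flexion [0, 150], pronation ±90,
wrist ±70. The ±165° rotation limit is set by the task itself: the
smallest default swivel style (12°) needs ~155° of internal rotation at
the far-diagonal targets.

**Inverse kinematics.** With the wrist neutral the fingertip lies on
the forearm axis, so the arm reduces to a two-link chain (upper arm,
forearm+hand) whose elbow position has one redundant degree of freedom:
the swivel angle, i.e. the rotation of the elbow about the
shoulder–fingertip axis away from the vertical reference plane
(positive = elbow swings outward, toward −y for a right arm). Given a
target and swivel, the elbow circle follows from the law of cosines,
the shoulder rotation matrix is reconstructed column-wise from the
upper-arm and forearm directions, and shoulder Euler angles are
extracted in z-y-x order, choosing between the two Euler branches by
joint-limit feasibility (small-abduction preference on ties). Elbow
pronation is then set so the palm normal is as close to straight down
as the forearm axis permits. The forward/inverse roundtrip closes to
< 1e-9 m in practice (tested at 1e-6 m).

## Reaching environment and reward

The default dynamics backend is a velocity-controlled kinematic
integrator: actions are normalized joint-velocity commands in [−1, 1]
per joint, scaled by a 180 deg/s speed cap and integrated at dt with
clipping at the joint limits. There is no contact or torque-level
dynamics; the backend sits behind a single transition function so a
physics engine could be slotted in. The default environment holds the
two wrist joints neutral (wrist commands are masked): the recorded
five channels then positionally determine the fingertip — the same
convention the surrogate subjects' inverse kinematics uses — and the
palm-down orientation is met through elbow pronation. With a free
wrist the policy satisfies the task with a bent wrist, and the
five-channel dataset no longer explains the fingertip position under
wrist-neutral replay (observed as an ~8 cm apparent endpoint offset).

The reward is

    r(s, a) = −b·error_p − c·‖a‖² − d·error_o

with error_p the fingertip-to-reference distance (m), ‖a‖² the squared
norm of the normalized action (an energy proxy), and
error_o = 1 − palm_normal·(0,0,−1) ∈ [0, 2] the palm-down orientation
error. Defaults b = 2.0, c = 0.05, d = 0.5 make the position term
dominate at typical tracking errors (~0.1 m → 0.2 penalty) while the
action term discourages bang-bang control; the coefficients are
configurable and were chosen once by this reasoning, not fitted.

The observation is the minimal sufficient set: 7 joint angles scaled to
[−1, 1] by their limits, fingertip position, moving-point position and
their difference (16 numbers). An episode is one trial (275 steps);
the target cycles 1..8 across episodes; every reset returns the arm to
a neutral pose solving the grid center at 27° swivel (the middle of the
surrogate range). Episodes end purely by time limit, so Bellman
targets always bootstrap.

## Soft actor–critic

No reinforcement-learning framework is part of the dependency set, so
the package carries a compact SAC implementation on its own NumPy
layers: a tanh-squashed Gaussian actor, twin Q critics with
Polyak-averaged targets (τ = 0.005), automatic entropy-weight tuning
towards a target entropy of −dim(A) = −7, Adam throughout (lr 3e-4),
batch 256, replay buffer 2e5, 1000 uniform-random warm-up steps, one
gradient update every 2 environment steps. Networks are two hidden
layers of 64 ReLU units — ample for a 16-dimensional servoing task and
fast on a single CPU core. All gradient assemblies (including the
reparameterized actor path through the tanh Jacobian) are verified
against central finite differences in the test suite.

Reference training length is 200k steps, which the acceptance script
runs in full; a 100k-step run already tracks the moving point to
~0.03 m mean error and is the reduced budget the test suite uses.
Position tracking converges much faster than the palm-orientation
term, which keeps improving late in training — the main reason the
full budget matters for the quality of the cloned data. Training is
reproducible for a fixed seed in single-threaded execution.

## Synthetic dataset extraction (cloning)

After training, the policy is rolled out in deterministic mode (tanh of
the Gaussian mean) over the full trial schedule; the five recorded
channels (shoulder rotation/flexion/abduction, elbow
pronation/flexion, degrees) are taken from the rolled-out joint
vectors at 50 Hz. Deterministic rollouts make repetitions of the same
target bit-identical, and cloning the same policy twice reproduces the
dataset exactly. The result carries subject id "DRL".

## Surrogate subjects

The six human participants of the emulated experiment are replaced by
six generative surrogate profiles. Each surrogate reaches with:

- a straight fingertip path center→target→center under minimum-jerk
  time scaling s(τ) = 10τ³ − 15τ⁴ + 6τ⁵ (zero end velocity and
  acceleration, peak speed 15/8);
- a subject-specific constant swivel angle — their redundancy
  -resolution "style" — of 12°, 18°, 24°, 30°, 36°, 42° across the six
  defaults, spreading styles over a plausible human range so that
  cross-subject transfer is nontrivial but learnable;
- stationary Ornstein–Uhlenbeck angle noise per recorded channel
  (sd 2°, correlation time 0.3 s), tapered to zero over 0.25 s at the
  trial boundaries because subjects rest on the center point there
  (this also keeps the forward-kinematic start/end positions within
  5 cm of the grid center, which is enforced as a dataset invariant);
- per-phase timing jitter of ±10% (uniform), rounded to whole samples.

Trials are deterministic given (profile seed, target, repetition,
session). The default structure mirrors the emulated study: 4
repetitions × 8 targets × 2 sessions per subject, session 1 for
training and session 2 for testing.

What the surrogates deliberately do **not** model: trunk/shoulder
compensatory displacement, target-dependent swivel modulation, fatigue
or learning effects across repetitions, and sensor soft-tissue
artefacts. Consequently, passing tests show that the pipeline recovers
the coupling structure the generator encodes — a single smooth
shoulder→elbow map per subject plus noise — not that it would reach the
same accuracy on real motion-capture data.

Cross-subject averaging (the "Human-Avg" training input) linearly
resamples each trial phase to the nominal per-phase sample count
(100/25/100/50 at the default timing) and takes the pointwise mean of
each angle across subjects. Phase boundaries are taken from the
generator's per-phase sample counts; for datasets re-read from CSV
(which stores no phase information) the nominal phase proportions are
assumed, which misplaces boundaries by at most the ±10% jitter.

## Decoder

The decoder maps a sliding window of the three shoulder channels to the
two elbow channels at the window's last sample (causal, suited to
online prosthesis control): one 1-D convolution (valid padding, ReLU),
two stacked LSTM layers, and a dense head read at the final time step,
trained by Adam on mean-squared error in z-normalized units (per-channel
statistics fitted on the training set only). Early stopping monitors a
validation split made of whole held-out trials (10%), never of windows,
to avoid leakage; with a single training trial the training loss is
monitored instead.

The reference architecture is 2 × 256 LSTM units with a 1 s (50-sample)
window at stride 1. For CPU-scale runs the pipeline uses a compact
setting — 32 conv filters, 2 × 48 LSTM units, 0.5 s window at stride 2,
≤ 60 epochs — which recovers the noise-free shoulder→elbow mapping to
well under 1° held-out RMSE; the reaching synergy is low-dimensional
and does not require the full reference capacity. Both are plain
configurations of the same implementation.

## Evaluation

- **Pearson r** per (subject, target, elbow channel), concatenating
  repetitions; constant series raise rather than returning 0.
  Qualitative interpretation bands: |r| ≥ 0.7 strong, ≥ 0.3 distinct,
  ≥ 0.1 weak, otherwise no linear relationship; boundary values belong
  to the stronger band.
- **RMSE** (degrees) per Eq. rmse = sqrt(mean((x̂ − x)²)). The
  "overall" RMSE of a model on a subject concatenates all test samples
  across targets, repetitions and both elbow channels before applying
  the formula (sample-weighted, rather than a mean of per-target
  values).
- **Target-reaching error** (cm): both the measured trial and a
  replica with predicted elbow angles (shoulder shared, wrist neutral)
  are replayed through the forward kinematics; the error is the
  fingertip discrepancy at the apex sample — the measured trial's
  sample of maximum fingertip distance from the grid center. The apex
  definition makes the metric independent of what happens elsewhere in
  the trial; angle noise occasionally pushes the apex slightly past the
  touch phase, which is warned about and accepted.
- **Correlation matrices** between datasets compare time-normalized
  mean trials (per target, per channel), the same per-phase
  normalization as averaging.

## Scenarios

**Sufficient data.** For each surrogate subject: a decoder trained on
the five other subjects' averaged session-1 data (Human-Avg-Model) and
a decoder trained on the cloned synthetic dataset only (DRL-Model) are
both tested on the held-out subject's session 2. One policy and one
DRL-Model are shared across the six evaluations.

**Limited data.** For each subject: a Human-Sparse-Model trained on
one session-1 repetition towards targets 1, 3, 5, 7 only, and a
Hybrid-Model trained on those four trials plus one cloned repetition
towards targets 2, 4, 6, 8 (eight trials total), both evaluated on all
eight targets of every other subject's session 2. The percentage
improvement per training subject is
(sparse − hybrid) / sparse × 100 on the cross-subject mean RMSE.

Trial-key intersections between any training and test set are asserted
empty. Reports serialize to JSON plus flat CSVs.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) runs the full pipeline
at surrogate scale: the complete 200k-step policy budget, six default
surrogates (4 × 8 × 2 trials each), the compact decoder configuration,
and both scenarios, all seeded from `--seed`; the test suite uses a
reduced 100k-step policy and three seed replicates for the
limited-data scenario. All
randomness flows through seeded NumPy generators, so single-threaded
runs are bit-reproducible.

## Known limitations

- The surrogate population is by construction more heterogeneous in
  redundancy style (swivel 12°–42°) than a typical homogeneous human
  cohort performing a constrained task. Decoders trained on averaged
  or synthetic data therefore face genuine extrapolation at the style
  extremes, and absolute cross-subject errors are dominated by that
  spread (mostly in the pronation channel) rather than by decoder
  capacity. Relative comparisons between training regimes — the
  pipeline's purpose — are unaffected.
- The DRL arm resolves redundancy by energy/orientation optimality,
  not by imitation, so its style can differ from any particular
  surrogate; the DRL-Model's errors combine that style gap with its
  input distribution shift (it never saw surrogate shoulder
  trajectories in training).
- The kinematic backend has no dynamics; cloned velocities are bounded
  by the speed cap rather than by muscle mechanics.
- With zero noise and a shared swivel, all surrogates are identical;
  that degenerate limit is used in tests to verify that the decoder
  and averaging pipeline are exact.
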