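# Methods

`camimu` studies a markerless alternative to wrist-worn inertial sensing for
upper-limb rehabilitation: a single time-of-flight (ToF) camera watches a
seated subject performing repeated arm-reaching, and a recurrent network
regresses the tri-axial wrist acceleration that an IMU strapped to the wrist
would report.  Everything runs on synthetic data at desk scale; this note
records the models, the choices behind them, and what the synthetic
conditions do and do not demonstrate.

## Motion model

One reaching cycle is: a stationary hold with the hand at rest on the table,
a transport of the wrist to a cup, a raise of the cup to mouth height, a
short hold, and the mirror-image return.  Each transport follows a
minimum-jerk (quintic) profile

    s(τ) = 10τ³ − 15τ⁴ + 6τ⁵,   τ = t/T ∈ [0, 1],

the standard kinematic model of point-to-point human reaching; its velocity
and acceleration vanish at both ends, and its peak acceleration is
(10/√3)·A/T² ≈ 5.77·A/T² for amplitude A and duration T.  With the default
geometry (rest→cup 0.40 m in 1.2 s; cup→mouth 0.56 m in 0.84 s) peak wrist
accelerations are ≈ 4.5 m/s², the natural scale for this task.

Four joints are tracked: right shoulder (RS), left shoulder (LS), left elbow
(LE), left wrist (LW).  Shoulders are quasi-static; the elbow comes from
exact two-segment inverse kinematics (upper arm 0.30 m, forearm 0.26 m,
elbow-down branch), so segment lengths are conserved to machine precision —
a property the tests assert on every seed.  Physiological tremor is modelled
as Gaussian-filtered white noise added to the wrist path and shoulders
(default 1 mm positional SD, 0.1 s correlation time), contributing
≈ 0.085 m/s² of acceleration — the scale of postural tremor.

The regression target G = (Accx, Accy, Accz) is the second central
difference of the wrist position at 50 fps (one-sided second-order stencils
at the ends, so frame counts stay aligned; exact for cubic trajectories),
plus i.i.d. Gaussian sensor noise (default SD 0.05 m/s²).  Gravity is not
included: the emulated IMU is flat-calibrated with world-aligned axes, so G
is pure kinematic acceleration — this makes the ground truth well defined
without modelling sensor orientation.

## Camera model

A pinhole ToF camera (224×172 px, f = 210 px — typical ToF optics) sits on a
circle of radius 2 m around the subject at azimuth 0°, 15° or 30°, looking
at the torso centre.  Two sensor products are emulated per frame:

* **2D joint estimates** — noisy pinhole projections of the true joints
  (Gaussian pixel noise, default SD 2 px).  This stands in for an
  off-the-shelf 2D pose estimator run on the amplitude image; the method
  under study begins *after* that stage, so the estimator itself is not
  reproduced.
* **Point cloud** — per-pixel ray casting against a capsule proxy of the
  body (radius 5 cm for the limbs, 12 cm torso), with Gaussian depth noise
  (SD 1 cm) and 5 % random pixel dropout.  Depth is stored as z along the
  optical axis; back-projecting (u, v, depth) reproduces the stored point
  exactly on noise-free frames.

Rendering a motion at azimuth θ is identical to rendering the world-rotated
motion at 0° (view equivariance), which the tests exploit as an oracle.

## Features and lifting

Both feature families use LS as the reference joint: the relative vectors
RS−LS, LE−LS, LW−LS plus their three Euclidean norms — 9 values per frame in
pixels (2D) or 12 in camera-frame meters (3D).  The 3D joints come from a
"3D generator": each joint takes the **median** depth of the valid
point-cloud pixels in a (2k+1)² window around its pixel estimate
(default k = 3) and is back-projected through the intrinsics.  The median is
robust to background bleed-through at silhouette edges; frames with no valid
depth around a joint are filled by linear temporal interpolation.  On
noise-free clouds the lift error is the surface-versus-bone offset — about
one capsule radius, slightly more when the forearm lies oblique to the view
so that depth varies across the median window.

The geometric heart of the study is testable without any learning: the
distances in the 3D features are invariant to camera rotation (isometry),
while every component of the 2D features changes with the view.  The
relative vectors rotate by exactly the relative camera extrinsics — also
asserted in the tests.  One caveat the emulation makes explicit: the camera
stations differ by rotation about the *vertical* axis, so the vertical pixel
displacement of a roughly centered subject is nearly azimuth-invariant —
purely geometric 2D features therefore keep tracking the vertical
acceleration axis at unseen views, and the 2D system's viewpoint weakness
shows on the two horizontal axes.  A full cross-view 2D collapse requires
appearance-level pose-estimator failures, which the isotropic pixel-noise
stand-in deliberately does not model.

Features are z-scored per dimension with statistics from training frames
only; pixel and metre scales differ by orders of magnitude otherwise.

## Regressors

Windows of 25 frames (0.5 s, stride 1) around each target frame feed three
architectures; the regression target is the acceleration of the window's
*centre* frame, so bidirectional context is meaningful:

* **DNN** — dense 36-324-324-324-36, dropout (–, 0.3, 0.2, –, –);
* **CNN** — 3×3 convolutions with filters (32, 64, 128, 256), dropout
  (–, 0.3, 0.2, –), full time×feature resolution retained (no pooling: the
  layer table lists none, and pooling blurs the temporal localization the
  centre-frame target needs);
* **DBLSTM** — bidirectional LSTM(128) → LSTM(256), dropout (0.3, 0.2),
  final state to the head.

Each hidden layer is batch-normalized and a 3-unit linear head closes every
network.  Training minimizes MSE with Nadam (learning rate 5e-4, desk batch
size 256), early-stops on a contiguous validation block (patience 10) and
returns the best-validation weights.  Targets are
standardized per axis inside the trainer and un-standardized at prediction,
so low-amplitude axes are not drowned out of the loss.  The networks and
their gradients are implemented directly in NumPy (layers, BPTT, Nadam);
gradient correctness is established against central finite differences.

Two width profiles exist.  `full` uses the layer sizes above (the DBLSTM
lands at ≈ 6.7×10⁵ parameters; exact published totals are not reproducible
because input dimensionality, head and batch-norm placement are
underdetermined, so the package logs its own counts).  `desk` divides all
widths by 4 (≈ 4.5×10⁴ parameters for the DBLSTM) so the full pipeline
trains in minutes on one CPU; it is the default everywhere.

## Splits and leakage control

Within each view's frame series the first 90 % feeds training and the final
10 % is the known-view test block; one window length of frames is dropped at
every boundary so no overlapping window straddles a split.  The validation
block for early stopping is carved from the training windows the same way.
The 15° view contributes nothing to training or normalization statistics.
A master seed derives per-stage sub-seeds through a fixed stage table, so
any stage can be re-run in isolation and whole runs are reproducible.

## Evaluation

Per axis: RMSE (m/s²); PRMSE = 100·RMSE/RMS(G) — normalizing by the target's
RMS rather than its signed mean, which is near zero over a closed reach
cycle and would make the percentage meaningless; and the coefficient of
multiple correlation CMC = sqrt(max(0, 1 − SSE/SST)), clamped to [0, 1],
with the usual interpretive bands (≤ 0.16 poor, < 0.5 moderate, < 0.99 good,
≥ 0.99 excellent).  Both normalization choices are isolated in the metrics
module so they can be swapped; brute-force loop implementations serve as
oracles in the tests at 1e-12.

## Benchmark conditions and problem sizes

The headline benchmark trains the desk DBLSTM on 3D features from 50 reach
cycles per known view (0° and 30°; ≈ 30 000 frames, ≈ 27 000 windows,
≤ 50 epochs) and evaluates on the held-out known-view split and on 10 cycles
at the unseen 15° view.  The cycle cadence uses a 1 s inter-cycle hold
(the 5 s hold of the recording protocol is a session-start event; cadence is
configurable).  Ordering experiments (model ranking, 2D-vs-3D) run at
reduced scale (6 cycles/view, 12 epochs) and are asserted as orderings, not
absolute values.

## What the synthetic conditions do not show

The simulator emulates the geometry and noise of the recording chain, not
its content: a single idealized subject, perfectly repeated cycles, a
capsule body, no occlusion by cup or table, no pose-estimator failure modes
beyond isotropic pixel noise, no ToF multipath or phase-wrap artifacts, no
accelerometer drift.  Passing bounds here demonstrate that the pipeline —
lifting, features, windowing, training, evaluation — recovers wrist
acceleration under controlled conditions and that 3D features generalize
across viewpoints where 2D features do not; they are not evidence about
recorded human data.

## Known limitations

* The wrist-mounted IMU is reduced to its accelerometer in world axes.
* The 2D pose stage is a noise model, not a learned estimator; its error is
  white, whereas real estimators fail structurally (left/right swaps,
  occlusion).
* Lifted joints sit on the body surface, one capsule radius in front of the
  bone; the regressor absorbs this constant bias, but the lifted coordinates
  themselves are surface coordinates.
* Training determinism is bit-exact only for a fixed BLAS backend and
  thread count.
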