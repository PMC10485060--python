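# Methods

## The walking model

The simulator implements the powered *simplest walking model*: two massless,
rigid legs of length `l` hinged at a point-mass hip `M`, a point mass `m` at
each foot, and a trunk that stays vertical. A torsional spring of stiffness
`k` between the trunk and the swing leg stands in for the burst-like hip
muscle activity of human walking — flexion torque in early swing, extension
torque in terminal swing. Everything is nondimensionalized by `M`, `l`, and
the pendulum time `sqrt(l/g)`, leaving three physical parameters:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `beta`  | foot/hip mass ratio `m/M` | 0.074 | lower-limb inertia matched to anthropometric tables |
| `k`     | hip spring constant (torque/rad) | 0 – 0.30 swept | spans the quasi-stiffness range observed on a treadmill |
| `mu`    | double-support constant in `dt_ds = mu / theta_dot⁻` | 0.142 | mean value estimated from treadmill walking |

The configuration is `(theta, phi)` — stance angle from vertical (positive
clockwise) and swing angle from the trunk (positive counterclockwise) — with
travel along +x. During single support the dynamics are conservative; the
accelerations come from a closed-form inversion of the 2×2 mass matrix, whose
determinant `beta(1+beta) − beta² cos²(theta+phi)` is positive for any
`beta > 0`. The full nonlinear equations are integrated for all trajectory
and fixed-point work; the small-angle form is kept for the swing-tuning
analysis (`omega = sqrt(1 + k/beta)`) and as a consistency check.

Heel strike occurs at `theta − phi = 0`. The event function also vanishes at
the start of every step and at mid-swing foot-scuffing, so detection is armed
only after the state leaves a dead-band around the section, and a crossing is
accepted only when it is *rising* (`d(theta−phi)/dt > 0`) with `theta > 0`;
everything else is recorded as a scuff and ignored. The rising/falling
distinction matters in practice: near-periodic trajectories exhibit scuffing
crossings with `theta` slightly positive, so a sign test on `theta` alone
would accept the wrong event.

The step-to-step transition applies, just before a perfectly inelastic
collision, a push-off impulse along the trailing leg and a vertical
gravitational impulse `i_gravity = dt_ds = mu / theta_dot⁻` on the hip mass
(gravity integrated over the double-support period). Under the optimal
push-off hypothesis the push-off exactly restores the collision energy loss,
`theta_dot⁺ = theta_dot⁻`; the map solves the jump equation for that impulse
in closed form.

## Periodic gaits

A periodic gait is a fixed point of the post-collision Poincaré map
`q = (theta, theta_dot)`. The solver uses a shooting formulation that avoids
event-branch discontinuities: integrate from the reconstructed section state
until the stance leg reaches the mirrored landing angle `−theta⁺` (a unique,
monotone passage) and demand the swing leg arrive simultaneously. The scalar
landing residual is solved by damped Newton–Raphson (forward finite
differences, step 1e−6 rad) or bracketed scanning plus Brent polish.

Two facts discovered during development shape the root selection:

1. The landing residual has *asymmetric* roots at which the landing angle
   repeats but the landing speed does not. The physical gait family is the
   time-reversal-symmetric branch, on which the landing-speed defect
   `theta_dot⁻ − theta_dot⁺` vanishes together with the landing residual
   (verified numerically to ~1e−12 at converged gaits). Every candidate root
   is vetted against that defect (threshold 1e−6).
2. Several symmetric roots can coexist: secondary branches land after extra
   swing oscillations. The primary family is the branch that lands at the
   first opportunity, so among vetted roots the shortest-period one is kept.

Every returned gait is re-checked through the actual event-detecting map;
the reported `residual` is the full two-component fixed-point defect
(typically 1e−13…1e−11, always required < 1e−8).

Gait observables are: step length `s = −2 sin theta⁺`, walking speed
`v = theta_dot⁺ cos theta⁺` (both restricted to (0, 1)), step period `tau`,
margin of stability `b = s/2 − v` (anterior base-of-support boundary minus
the extrapolated centre of mass, evaluated at heel strike), peak hip flexion
torque `T = max(−k phi) = k phi_max` (2000 trajectory samples plus 3-point
quadratic refinement), push-off impulse (closed form
`i_push = s v (s² beta − 4 beta − 2)/(s² − 4) + mu/(2v)`, equal to the
trajectory-level solve at fixed points), and propulsive force
`F = s v /(mu sqrt(4 − s²)) · i_push`.

Stiffness sweeps hold `v` fixed, walk an increasing `k` grid with
continuation, and record non-converging grid points (typically where the
implied step length leaves (0, 1)). The six studied speeds are the nominal
belt speeds 0.50…1.75 m/s nondimensionalized as `v = speed/sqrt(9.81)`,
reproducing the convention of the original protocol (which implies a 1 m
length scale); the default grid `k ∈ [0, 0.30]` in steps of 0.005 covers the
empirically observed quasi-stiffness range.

### A note on the period approximation

The swing-tuning analysis confirms `omega ∝ 1/tau` (origin-constrained fit,
R² ≈ 0.999 over the six-speed sweeps). The companion approximation
`tau ≈ s/v` is qualitatively right but quantitatively poor for this model:
`v` is the CoM speed *at heel strike*, which is the per-step maximum of the
inverted-pendulum speed profile, so `s/v` systematically underestimates the
period — by ≈32% at the worked-example gait (`s = 0.6`, `v = 0.39`,
`tau = 2.2598`) and by 20–40% across the studied range (median ≈31%). The
package reports the deviation distribution rather than asserting a small
bound; treat `s/v` as an order-of-magnitude cadence proxy only.

## The gait-analysis pipeline

The pipeline mirrors a standard instrumented-treadmill analysis:

* **Filtering.** Fourth-order zero-lag Butterworth (a second-order filter run
  forward and backward): 6 Hz for kinematics, 18 Hz for forces.
* **Events.** Heel strike = the last sample at/below 0 N before a 10 N
  up-crossing of the vertical GRF; toe-off = the first sample at/below 0 N
  after a 10 N down-crossing. The 10 N threshold provides hysteresis. Events
  are detected on the *raw* vertical GRF by default: a zero-lag filter is
  non-causal, so it smears contact onsets symmetrically and rings around
  zero, which makes the 0 N rule ill-posed on filtered data and biases the
  double-support period by tens of milliseconds.
* **Velocities.** The at-heel-strike CoM and marker velocities are
  least-squares slopes over the last 50 ms of *unfiltered* samples strictly
  before the event. Both choices (pre-event window, raw channel) exist for
  the same reason: the CoM vertical velocity reverses at heel strike, and
  any estimator that mixes post-event samples — including a zero-lag filter —
  contaminates the pre-collision value.
* **Per-step geometry.** The posture at heel strike is reduced to the
  compass model by assuming the CoM bisects the step; the effective leg
  length then follows from Pythagoras, and step length, speeds, the
  pre-collision stance angle and angular speed, the step period, and the
  double-support period are nondimensionalized by the standard scales
  (`l_expt`, `sqrt(g l_expt)`, `sqrt(l_expt/g)`, `M g l_expt`, `M g`). All
  periods are divided by `sqrt(l_expt/g)`; the margin of stability uses the
  CoM-to-leading-heel distance instead of `l_expt` and is computed as
  `b = u − xi` with `xi = x + x_dot` (the extrapolated centre of mass).
* **Quasi-stiffness.** Over the window from maximum hip extension during
  pre-swing to the end of swing, `k_expt` is the magnitude of the OLS slope
  of the (flexion-positive, nondimensionalized) hip torque on the
  (extension-positive) hip angle; with these conventions a restoring spring
  has positive slope. `R²` is `1 − SS_res/SS_tot` throughout the package.
* **Double-support law.** A no-intercept least-squares fit of
  `theta_dot⁻ = mu_expt / dt_ds` across steps.
* **Correlations.** Per belt speed, `k_expt` against peak flexion torque,
  propulsive force, margin of stability, and step length; Pearson when both
  samples pass Shapiro–Wilk normality at 0.05, Spearman otherwise. With four
  tests per speed the Bonferroni-adjusted level is
  `alpha' = 1 − 0.95^(1/4) ≈ 0.0127`, applied at its rounded 0.01 reporting
  level. One pooled `k_expt` vs `1/tau_expt` correlation spans all speeds.
  Steps from both sides are pooled, with the side recorded per step.

## The synthetic-trial generator

Real treadmill recordings for this protocol are not publicly archived, so the
generator synthesizes trials *from the model's own periodic gaits*, giving
every pipeline stage exact ground truth. Defaults define the emulated study:
six belt speeds 0.50–1.75 m/s (scaled by `sqrt(leg length)`, mirroring the
protocol's stature adjustment and making the dimensionless speed
stature-independent), 200 Hz kinematics / 1000 Hz force plates, 35 strides
per trial with the last 30 steps analyzed, subject mass 58.8 ± 9.1 kg and leg
length 0.96 ± 0.05 m, `mu = 0.142`, and a cohort stiffness progression
0.08 → 0.16 from the slowest to the fastest belt (between-subject sd 0.03).

What the generator emulates, and why:

* **Stride-to-stride variability on the gait family.** Each step takes a
  small AR(1)-correlated excursion (lag-one correlation 0.85 between steps)
  along the constant-speed stiffness direction (relative sd 0.12) and the
  speed direction (relative sd 0.01) of the periodic-gait family; the
  family's sensitivities come from finite differences between neighbouring
  fixed points. All per-step observables — step length, period, landing
  speed, double-support duration, torque scale, propulsion peak — move
  coherently, the way the underlying dynamics says they should. This is what
  gives the per-speed correlation battery a within-trial signal instead of
  pure estimation noise.
* **Finite double support in the kinematics.** The hybrid model changes the
  CoM velocity instantaneously at heel strike; humans take the whole
  double-support phase. Each single-support arc is straightened onto its
  collision-point tangent over the final stretch of the step and crossfaded
  from the previous tangent after heel strike (delayed, so the CoM keeps
  descending into early double support). The trailing foot dwells on the
  ground until its toe-off and swings with zero marker velocity at lift-off
  and landing.
* **Force plates.** M-shaped vertical GRF per stance with double-support
  overlap (`dt_ds = mu / theta_dot⁻` per step) and clean 0 N/10 N crossings;
  contact intervals are shrunk by half a force-plate sample on each side so
  threshold detection is unbiased against the stored event times. The
  anterior GRF is biphasic with the propulsion peak scaled to the model's
  propulsive force.
* **Hip channels.** The extension-positive hip angle follows the stance and
  swing angles of the model; the torque channel is the spring law
  `torque = k · angle · M g l` using the previous step's stiffness draw (so
  the quasi-stiffness window of each analyzed step sees the same draw as the
  step's geometric outcomes).
* **Measurement noise.** White noise on markers (0.3 mm, typical optical
  capture residual), forces (2 N), and angles (3 mrad); an AR(1)-colored
  disturbance on the hip torque with stationary sd 0.85 × the trial's peak
  spring torque. The torque disturbance is deliberately large: it is not
  instrument noise but the non-spring-like share of human hip torque, sized
  so the torque-angle fit quality lands in the R² range reported for real
  treadmill data (~0.68–0.79) at every speed.

What the generator does **not** emulate: soft-tissue artifact, force-plate
crosstalk, marker occlusion, asymmetry between legs, fatigue or speed drift,
and any hip torque structure beyond spring + colored disturbance. Passing
pipeline tests on these trials therefore demonstrates the *analysis chain* is
correct and internally consistent — not that real human hips behave like the
model.

## Numerical choices

* Integrator: DOP853 at rtol 1e−10 / atol 1e−12; events located to 1e−10;
  swing capped at 50 time units; walker-fall (|theta| ≥ π/2) terminates with
  a no-collision error.
* Newton–Raphson: forward finite differences (1e−6 rad), half-step damping
  (max 8), convergence at |residual| < 1e−10, 50 iterations.
* Symmetric-branch vetting threshold 1e−6 on the landing-speed defect;
  shortest-period candidate wins.
* `phi_max` is reported as 0 when `k = 0` (the torque is identically zero).
* Degenerate inputs raise typed errors (`GaitRangeError`, `NoGaitError`,
  `RegressionError`, `SchemaError`, …) rather than returning sentinels; a
  negative push-off solution is returned with a warning, not an error.
* Problem sizes: sweeps use the 61-point default stiffness grid per speed;
  synthetic cohorts use 11 subjects × 6 speeds × 35 strides, matching the
  emulated protocol.

## Known limitations

* 2-D sagittal dynamics only; no knees, ankles, or frontal-plane margin of
  stability; double support is instantaneous in the *model* (finite only in
  the synthesized kinematics).
* The map's orbital (Floquet) stability is out of scope; stability is
  discussed only through the margin-of-stability observable.
* `F` is an observable of the fixed point (it uses the closed-form push-off);
  transient propulsion is not defined.
* The pipeline consumes hip torque as a provided channel; no inverse
  dynamics is performed.
* Real-cohort numbers from the motivating experiments are not reproducible
  here (the raw data is not public); the pipeline is validated by
  property-level recovery on synthetic trials instead.
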