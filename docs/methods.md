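# Methods

This note documents the models, conventions, numerical choices and
limitations of `stridetraj` at the level of detail a user extending or
auditing the package needs.

## Conventions

Quaternions are scalar-first `(q0, q1, q2, q3)`, Hamilton product, and encode
**sensor-to-world** rotations; `R(q)` maps sensor-frame vectors into a world
frame whose `-y` axis is gravity (`g_w = (0, -1, 0)`).  An accelerometer at
rest therefore measures a specific force of `(0, 1, 0)` in units of g.  `q`
and `-q` are the same rotation; canonicalisation (`q0 ≥ 0`) is applied only
when comparing.  Axes follow the foot-mounted convention: `x`
anterior-posterior (walking direction), `y` longitudinal (up), `z`
transversal (lateral).  The vertical world axis is `y` throughout; clearance
is `s_y(t)`.

### Sign of the gravity-alignment error

The Madgwick correction descends the objective `½‖ε‖²` with
`ε(q) = R(q)ᵀ g_w + a_s`: predicted gravity direction plus measured specific
force, which vanishes exactly when the tracked orientation matches the
sensor's true attitude (the accelerometer measures the *negative* of
gravity).  Writing the error as predicted-gravity-minus-accelerometer
instead would be ≈ `2 g_w` at perfect alignment and drive the filter toward
the upside-down attitude.  The gradient is `Jᵀε` with the analytic Jacobian
`J = ∂(R(q)ᵀ g_w)/∂q`; a joint sign flip of `(ε, J)` leaves `Jᵀε` invariant,
so the choice of writing the error with `+a_s` or `-a_s` (with the gravity
direction negated accordingly) does not change the dynamics.  The Jacobian
is verified against central finite differences in the tests.

### Initial inclination

Only inclination is observable without a magnetometer.  The two tilt angles
are extracted as `α_z = atan2(-a_x, a_y)` and
`α_x = atan2(a_z, √(a_x² + a_y²))` — atan2 rather than a tangent ratio so
every quadrant and the `a_y → 0` limit are well defined — and the initial
quaternion is `q_x(-α_x) ⊗ q_z(-α_z)`, the exact inverse of the
world-to-sensor factorisation `R_z(α_z) R_x(α_x)`.  Applying it to the
measured accelerometer direction yields world `+y` exactly (unit tested at
1e-12).  The construction invents no heading: its world-y swing-twist
component is exactly zero for single-axis tilts and second order
(`|q_y| = |sin(α_x/2) sin(α_z/2)|`) for combined tilts.

## Orientation trackers

All three estimators share the first-order update
`q(t) = normalize(q(t-Δt) + q̇ Δt)`.  Deliberately no exponential-map
integrator is used: the benchmarked methods are defined with the Euler
update, and for the (dominantly fixed-axis) rotations of a stride the
normalised Euler step is third-order accurate per step.  A drift guard
raises if the incoming state leaves the unit sphere by more than 1e-6.

Accelerometer gating: corrections require (a) stance phase and (b)
`|‖a_s‖ − 1| ≤ γ`.  The stance/swing segmentation is not part of the
estimators' definition, so a simple, configurable rule is used: swing =
samples with `‖ω‖ > 1.5 rad/s`, morphologically closed over 50 ms so brief
dips inside the swing burst do not re-enable updates; stance is the
complement.  Both the threshold and the closing width are exposed.

The Euston integral term `∫e dt` is accumulated by the trapezoidal rule in a
single 3-vector state (carrying the running sum `Σ e_k Δt`; the trapezoidal
value at step k is that sum minus `e_k Δt/2`), and is reset at every stride
start — the pipeline re-initialises per stride, so integral wind-up cannot
leak across strides.

Default parameters (all exposed): `β = 0.046 rad/s`, `γ_madgwick = 0.24`,
`k_P = 0.0046 rad/s`, `k_I = 0 rad/s`, `γ_euston = 2.50`.  These are the
grid-search optima reported for a 735-stride motion-capture-referenced
benchmark of healthy over-ground walking; they are defaults, not claims
about other datasets.  The gain relation `β = √(3/4)·ω̃_max` links β to the
maximal gyroscope measurement error (0.046 rad/s ↔ 3.04 °/s); the
alternative `ω̃_max = 4/3·β` relation is also provided
(`max_gyro_error(..., relation="four_thirds")`).

## Trajectory integration

Gravity removal converts to m/s² (`g = 9.81` by default, configurable, e.g.
9.80665) and enforces `a(t_ms) = a(t_ms+1) = 0` with a piecewise-linear
drift estimate: one segment from the start residual to zero at the sample of
maximal acceleration norm, one from zero to the end residual.  The rationale
is that boundary residuals come from accumulated orientation error while the
mid-swing movement peak is comparatively drift-free; a single
endpoint-to-endpoint line is available via `piecewise=False`.  The split
rule (maximal `‖a‖`) is a documented package choice.

**Exact boundary conditions.**  All three integrators produce *bit-exact*
zeros for velocity at both stride endpoints and for vertical position at
both endpoints.  Three numerical devices make this exact rather than
approximate: drift lines are evaluated as `y0·(1-τ) + y1·τ` (endpoint
subtraction cancels exactly in floating point); the sigmoid fusion weight is
normalised so `w[0] = 0` and `w[n-1] = 1` exactly, and the reversed integral
contributes its exactly-zero anchor there; Fourier basis phases are reduced
modulo the period with integer arithmetic (`2π·((k·i) mod (n-1))/(n-1)`), so
sin/cos are bit-exact 0/1 at both endpoints.

**Direct & reverse fusion.**  Discrete time reversal is index mirroring
(`a←[i] = -a[n-1-i]`); the continuous re-indexing `v←(t) = v←*(t_ms+1 - t)`
maps to mirroring the cumulative integral.  Fusion weights are evaluated on
normalised stride time with defaults `t0 = 0.6`, `η = 0.08`.  Ground-plane
position is obtained by direct integration of the fused velocity without
further correction: only axes with à-priori-known boundary values are
corrected.

**Analytic integration.**  Fourier coefficients are obtained by least
squares on the exact stride duration `T = (i_ms+1 − i_ms)·Δt` (strides are
short and non-power-of-two, so no FFT grid is imposed), with the DC term
forced to zero and the fit restricted to the first `n-1` samples — the last
sample duplicates `τ = 0` of the periodic extension, and including it would
break the harmonics' orthogonality to constants.  The default order
`N = 60` keeps the reconstruction error of unfiltered ~100 Hz gait
acceleration below ~5%; no low-pass prefilter is applied by default (a
Butterworth prefilter would allow a much smaller order but changes the
benchmarked pipeline).  The order is capped at `(n-2)//2` for short strides
and an explicit error is raised for over-parameterised decompositions.  The
vertical double integral retains a linear term (`Σ c2(k)·t/ω_k`) and is
linearly dedrifted against the level-floor condition.  Ground-plane position
uses degree-3 B-splines (`scipy.interpolate.splrep`/`splantider`) with
smoothing 0 (interpolating) by default; the smoothing factor is exposed.

## Synthetic gait simulator

The simulator stands in for a motion-capture-referenced dataset and defines
the study conditions for all stochastic tests.  Defaults: stride length
1.25 m, duration 1.1 s, peak sensor clearance 0.12 m, 2.5 cm lateral sway,
stance dwell 40% of the stride (split between both ends), sampling
102.4 Hz, accelerometer noise 0.01 g, gyroscope noise 0.009 rad/s, residual
gyroscope bias ~0.3 °/s per axis, mounting tilt (5°, -3°).  Dataset
generation samples stride length 0.5–1.8 m and duration 0.9–1.4 s uniformly,
emulating a protocol with low/normal/high stride-length and velocity
conditions.

Closed forms (swing time τ ∈ [0, 1]): minimum-jerk horizontal progression
`L(10τ³ - 15τ⁴ + 6τ⁵)`; two-lobe clearance `∝ sin⁴(πτ)(1 + d·cos 2πτ)`
(exactly two maxima for `d > ½`, default `d = 0.8`); lateral sway
`∝ sin(2πτ) sin²(πτ)`; sagittal pitch `-A·sin(2πτ) sin²(πτ)`
(plantarflexion after toe-off, dorsiflexion before heel strike, `A = 20°`),
optionally a small frontal wobble.  Every profile has vanishing value,
velocity and acceleration at the swing boundaries, so the IMU signals are
continuous and the dwell is exactly static.  The gyroscope signal is the
*closed-form* body rate of the quaternion composition
(`ω_s = R_baseᵀ (R_x(φ)ᵀ (0,0,θ̇) + (φ̇,0,0))`) rather than a
finite-difference of sampled quaternions — the ground truth carries no
discretisation error, so estimator error measurements are not confounded by
simulator error.  One seeded generator drives all noise; identical seeds
give identical recordings.

What the simulator does *not* emulate: soft-tissue/mounting vibration,
non-Gaussian and temperature-dependent sensor error, turning gait, stairs,
non-level floors, pathological patterns (shuffling, freezing) beyond its
parameter ranges, and heading-varying strides.  Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
assumptions, not clinical accuracy on real data.

### Drift-robustness conditions

A truly constant acceleration offset integrates to a *linear* velocity
drift, which linear dedrifting removes exactly — under such drift direct
integration trivially matches or beats any fusion scheme (verified
numerically).  The drift regime in which the direct & reverse scheme earns
its precision advantage is constant-*rate* sensor drift: a constant
gyroscope bias (set to 3 °/s per axis, the maximal gyroscope error implied
by the reported optimal β for a gyroscope not calibrated on a turntable)
produces a growing orientation error that leaks gravity into `a(t)` as a
nonlinearly drifting acceleration error.  The paired comparison uses the
plain gyroscope-integration tracker so the integrators' drift handling is
isolated from the complementary filters' partial bias correction.

## Evaluation harness

Errors are pooled per sample over all strides of a dataset, per variable and
axis; accuracy is the pooled mean, precision the pooled sample SD (ddof 1).
Angle errors are wrapped to [-180°, 180°).  Per-plane angles use the
intrinsic Z-X-Y Euler decomposition of the sensor-to-world rotation:
rotation about `z` (transversal axis) is sagittal-plane motion, about `x`
frontal-plane, about `y` transversal-plane motion; the convention is
recorded in outputs.  The grid-search objective is
`J(θ) = (1/m) Σ rmse(ε_i)/ρ_i` with `ρ_i` the range the reference course of
axis `i` attains over the dataset; the search is exhaustive with ties broken
by grid order, hence fully deterministic.  The η grid is
`10^(κ - i·δ)`, `κ = log10(½)`, `δ = (log10(½) + 2)/9`, `i = 0..9`, mapping
onto [0.01, 0.5].  Method ranking uses the composite score
mean-over-endpoints of `(|accuracy| + precision)/2`, stated in the output
metadata.  Execution times per stride are reported for information only —
they are hardware-dependent and never asserted.

## Problem sizes

Simulated checks use 100 strides for the boundary-condition sweep, 50 for
the noisy recovery, drift-ordering and grid-search determinism experiments,
20 for the filter-reduction identities and 20 seeds for the noise
monotonicity property; these sizes give stable orderings (the drift
comparison holds across independent dataset seeds with ~10% margin) while
keeping the whole suite fast on one CPU.

## Known limitations

* Heading is unobservable and set to zero per stride; estimated trajectories
  are expressed in a per-stride frame aligned at the initial mid-stance.
  Stride length is invariant to this, full 3-D paths across strides are not
  reconstructed.
* The first-order quaternion update is the benchmarked method; for very fast
  rotations with strongly varying axis an exponential-map integrator would
  be more accurate.
* The piecewise-linear dedrift split at maximal `‖a‖` is a reproducible
  default, not a uniquely determined rule.
* Reported default parameters are optima of one laboratory dataset;
  generalisation to other sensors, mounting positions or populations is not
  implied.
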