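# stridetraj

Stride-wise foot trajectory estimation from shoe-mounted inertial sensors.

Mobile gait analysis systems attach an IMU (3-axis gyroscope + 3-axis
accelerometer) to the shoe and reconstruct, stride by stride, where the foot
went: stride length, foot clearance, velocity profiles and orientation
courses.  These quantities cannot be measured directly in a wearable setting
— they have to be inferred by tracking the sensor orientation and
double-integrating the gravity-free acceleration, which is numerically
fragile because any orientation or bias error integrates into unbounded
position drift.  `stridetraj` implements the complete per-stride processing
pipeline for this task, aimed at researchers in clinical movement analysis
who need a transparent, testable reference implementation.

## The model

A stride is the segment between two consecutive mid-stances `t_ms`,
`t_ms+1` — the quasi-stationary instants of stance at which the foot
velocity is assumed zero (the zero-velocity assumption, ZUPT) and the foot
is on the floor (level-floor assumption).  Within a stride, with a
sensor-to-world unit quaternion `q(t)` (Hamilton convention, scalar first,
gravity along world `-y`):

1. **Initial inclination** from the static accelerometer sample `a_s(t_ms)`:
   `α_z = atan2(-a_x, a_y)`, `α_x = atan2(a_z, √(a_x² + a_y²))`,
   `q(t_ms) = q_x(-α_x) ⊗ q_z(-α_z)` (heading is unobservable and set to
   zero).
2. **Orientation tracking** by one of three estimators, all built on the
   first-order update `q(t) = normalize(q(t-Δt) + q̇(t)·Δt)` with
   `q̇_ω = ½ q ⊗ (0, ω)`:
   * plain gyroscope integration;
   * the Madgwick complementary filter, `q̇ = q̇_ω − β ∇ε/‖∇ε‖`, a
     normalised gradient step on the gravity-alignment error
     `ε(q) = R(q)ᵀ g_w + a_s` with analytic Jacobian;
   * the Euston (explicit PI) complementary filter,
     `ω* = ω + k_P e + k_I ∫e dt`, `e = ĝ_s × â_s`.
   Accelerometer corrections are gated: only during stance and only when
   `|‖a_s‖ − 1| ≤ γ` (in g).
3. **World transform and gravity removal**: `a(t) = (R(q) a_s − ŷ)·g`,
   then piecewise-linear dedrifting so `a(t_ms) = a(t_ms+1) = 0` exactly.
4. **Double integration** by one of three schemes, each honouring
   `v(t_ms) = v(t_ms+1) = 0` and `s_y(t_ms) = s_y(t_ms+1) = 0` to machine
   precision:
   * direct trapezoidal integration with linear velocity (and vertical
     position) dedrifting;
   * direct & time-reversed integration, fusing a forward integral (exact
     initial value) with a reversed one (exact final value) through a
     normalised sigmoid weight `w(t)` with mid-point `t0` and steepness `η`;
   * analytic integration: least-squares decomposition in a zero-DC Fourier
     basis (cyclic axes) and a B-spline basis (non-cyclic ground-plane
     position), integrated term by term in closed form.

Any of the 3 × 3 estimator/integrator combinations can be run.  A synthetic
gait simulator with closed-form ground truth (minimum-jerk progression,
two-lobe clearance, sagittal pitch cycle, configurable sensor noise and
bias) provides reference data, and an evaluation harness pools per-sample
signed errors into accuracy (mean) / precision (SD) tables, grid-searches
filter parameters with a range-normalised RMSE objective, and ranks methods.

## Worked example

```python
from stridetraj import SyntheticStrideSpec, simulate_stride, run_pipeline

spec = SyntheticStrideSpec(stride_length=1.25, stride_duration=1.1, seed=0)
rec, truth = simulate_stride(spec)          # noisy IMU data + exact truth
track, traj = run_pipeline(rec, orient_method="madgwick",
                           integ_method="direct_reverse")
print(f"stride length : {traj.stride_length:.3f} m")
print(f"peak clearance: {traj.max_clearance*100:.1f} cm")
```

prints

```
stride length : 1.230 m
peak clearance: 12.0 cm
```

i.e. the pipeline recovers the simulated 1.25 m stride to within 2 cm under
realistic sensor noise (0.01 g accelerometer, 0.009 rad/s gyroscope, ~0.3 °/s
residual bias) and the 12 cm peak clearance almost exactly; the velocity at
both stride endpoints is exactly zero by construction.

The estimators are sklearn-style transformers and compose in pipelines:

```python
from sklearn.pipeline import Pipeline
from stridetraj import MadgwickTracker, DirectReverseIntegrator

pipe = Pipeline([("orientation", MadgwickTracker(beta=0.046, gamma=0.24)),
                 ("integration", DirectReverseIntegrator(t0=0.6, eta=0.08))])
trajectories = pipe.fit_transform(list_of_stride_recordings)
```

A CLI mirrors the library (`stridetraj simulate / run / gridsearch /
benchmark`); see `stridetraj --help`.

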