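"""Double integration: dedrifting, reverse fusion, analytic bases."""

from dataclasses import replace

import numpy as np
import pytest

from stridetraj import quat
from stridetraj.orientation import OrientationTrack, gyro_integrate
from stridetraj.simulate import SyntheticStrideSpec, simulate_stride
from stridetraj.stride import WorldFrame
from stridetraj.trajectory import (
    AnalyticBasisParams,
    SigmoidFusionParams,
    WorldAccelTrack,
    bspline_analytic_integrate,
    fourier_analytic_integrate,
    fourier_decompose,
    fourier_evaluate,
    integrate_analytic,
    integrate_direct,
    integrate_direct_reverse,
    linear_dedrift,
    remove_gravity_and_dedrift,
    reverse_accel,
    run_pipeline,
    sigmoid_weight,
    to_world,
    trapezoid_cumint,
)

ALL_INTEGRATORS = {
    "direct": lambda a: integrate_direct(a),
    "direct_reverse": lambda a: integrate_direct_reverse(a),
    "analytic": lambda a: integrate_analytic(a),
}


def accel_track(a, dt):
    """WorldAccelTrack from an (n, 3) m/s² array."""
    a = np.asarray(a, dtype=float)
    return WorldAccelTrack(a, np.arange(len(a)) * dt)


def bandlimited_track(n=1100, dt=1e-3, amp=1.0):
    """Drift-free, band-limited stride-like acceleration.

    All axes integrate to zero velocity at both ends (zero-DC harmonics);
    the vertical axis additionally has a vanishing double integral
    (Σ c2(k)/k = 0), so the true trajectory itself satisfies the level-floor
    condition and every integration scheme targets the same curve.
    """
    t = np.arange(n) * dt
    T = t[-1]
    a = np.zeros((n, 3))
    a[:, 0] = amp * np.sin(2 * np.pi * t / T)
    a[:, 1] = amp * (np.sin(2 * np.pi * t / T) - 2.0 * np.sin(4 * np.pi * t / T))
    a[:, 2] = 0.3 * amp * np.sin(6 * np.pi * t / T)
    return accel_track(a, dt)


class TestToWorld:
    def test_identity_track_is_noop(self, rng):
        accel = rng.normal(size=(20, 3))
        track = OrientationTrack(np.tile(quat.IDENTITY, (20, 1)))
        np.testing.assert_allclose(to_world(track, accel), accel, atol=1e-15)

    def test_static_tilt_recovers_vertical(self, rng):
        """Exact orientation of a resting tilted sensor maps the measured
        specific force to (0, 1, 0) per sample."""
        q = quat.from_axis_angle(rng.normal(size=3), 0.4)
        a_sensor = np.tile(quat.rotate(quat.conjugate(q), (0.0, 1.0, 0.0)), (15, 1))
        track = OrientationTrack(np.tile(q, (15, 1)))
        aw = to_world(track, a_sensor)
        np.testing.assert_allclose(aw, np.tile([0, 1, 0], (15, 1)), atol=1e-12)

    def test_norm_preserved(self, rng):
        quats = rng.normal(size=(10, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        accel = rng.normal(size=(10, 3))
        aw = to_world(OrientationTrack(quats), accel)
        np.testing.assert_allclose(
            np.linalg.norm(aw, axis=1), np.linalg.norm(accel, axis=1), atol=1e-9
        )


class TestGravityRemoval:
    def test_perfect_static_gives_zero(self):
        aw = np.tile([0.0, 1.0, 0.0], (50, 1))
        out = remove_gravity_and_dedrift(aw)
        np.testing.assert_array_equal(out.accel_world, np.zeros((50, 3)))

    def test_constant_offset_zeroed_at_endpoints(self):
        aw = np.tile([0.0, 1.0, 0.0], (50, 1))
        aw[:, 0] += 0.02  # constant orientation-error leak on one axis
        out = remove_gravity_and_dedrift(aw)
        assert out.accel_world[0, 0] == 0.0
        assert out.accel_world[-1, 0] == 0.0
        # interior shifted by the interpolated two-segment correction
        assert np.all(np.abs(out.accel_world[1:-1, 0]) <= 0.02 * 9.81 + 1e-12)

    def test_endpoints_exact_zero_with_orientation_error(self, noisy_stride):
        rec, _ = noisy_stride
        track = gyro_integrate(rec)
        aw = to_world(track, rec.segment(rec.accel))
        out = remove_gravity_and_dedrift(aw)
        np.testing.assert_array_equal(out.accel_world[0], np.zeros(3))
        np.testing.assert_array_equal(out.accel_world[-1], np.zeros(3))

    def test_single_line_fallback(self):
        aw = np.tile([0.05, 1.0, 0.0], (30, 1))
        out = remove_gravity_and_dedrift(aw, piecewise=False)
        # a constant offset is a line: removed identically
        np.testing.assert_allclose(out.accel_world, 0.0, atol=1e-12)


class TestTrapezoidCumint:
    def test_constant_exact(self):
        y = trapezoid_cumint(np.full(11, 3.0), 0.5)
        assert y[0] == 0.0
        assert y[-1] == pytest.approx(3.0 * 10 * 0.5, abs=1e-12)

    def test_linear_ramp_exact_quadratic(self):
        """Trapezoid is exact for polynomials of degree <= 1."""
        dt = 0.1
        t = np.arange(21) * dt
        y = trapezoid_cumint(2.0 * t + 1.0, dt)
        np.testing.assert_allclose(y, t**2 + t, atol=1e-12)

    def test_zero_is_zero(self):
        np.testing.assert_array_equal(trapezoid_cumint(np.zeros(5), 0.1), np.zeros(5))


class TestLinearDedrift:
    def test_already_anchored_unchanged(self):
        y = np.array([0.0, 0.3, -0.2, 0.1, 0.0])
        np.testing.assert_allclose(linear_dedrift(y), y, atol=1e-15)

    def test_pure_line_becomes_zero(self):
        t = np.linspace(0, 1, 30)
        np.testing.assert_allclose(linear_dedrift(2.0 * t - 0.5), 0.0, atol=1e-12)

    def test_sine_plus_ramp(self):
        """y = sin(πt/T) + 0.3 t/T keeps only the sine after dedrifting."""
        t = np.linspace(0.0, 1.0, 101)
        y = np.sin(np.pi * t) + 0.3 * t
        out = linear_dedrift(y)
        np.testing.assert_allclose(out, np.sin(np.pi * t), atol=1e-12)
        assert out[0] == 0.0 and out[-1] == 0.0


class TestReverseAccel:
    def test_involution(self, rng):
        a = rng.normal(size=(31, 3))
        np.testing.assert_array_equal(reverse_accel(reverse_accel(a)), a)

    def test_even_signal_negates(self):
        a = np.cos(np.linspace(-1, 1, 41))[:, None] * np.ones(3)
        np.testing.assert_allclose(reverse_accel(a), -a, atol=1e-15)

    def test_full_span_integral_identity(self, rng):
        """∫₀ᵀ a← dt = -∫₀ᵀ a dt: substituting u = T - t flips the limits
        back while the direction flip keeps the minus sign."""
        a = rng.normal(size=101)
        dt = 0.01
        lhs = trapezoid_cumint(reverse_accel(a), dt)[-1]
        rhs = trapezoid_cumint(a, dt)[-1]
        assert lhs == pytest.approx(-rhs, abs=1e-12)


class TestSigmoidWeight:
    @pytest.mark.parametrize("t0,eta", [(0.6, 0.08), (0.0, 0.5), (1.0, 0.01)])
    def test_endpoints_exact(self, t0, eta):
        w = sigmoid_weight(57, SigmoidFusionParams(t0, eta))
        assert w[0] == 0.0 and w[-1] == 1.0
        assert np.all(np.diff(w) >= 0.0)

    def test_midpoint_half_before_normalisation(self):
        """h(t0) = 0.5 by construction of the logistic function."""
        t0, eta = 0.6, 0.08
        h = 1.0 / (1.0 + np.exp(-(np.array([t0]) - t0) / eta))
        assert h[0] == 0.5

    def test_large_eta_approaches_linear_ramp(self):
        """η → ∞: the normalised sigmoid tends to the linear ramp."""
        n = 101
        w = sigmoid_weight(n, SigmoidFusionParams(0.6, 1e4))
        np.testing.assert_allclose(w, np.arange(n) / (n - 1), atol=1e-6)


class TestDirectIntegration:
    def test_zero_accel_zero_trajectory(self):
        out = integrate_direct(accel_track(np.zeros((40, 3)), 0.01))
        np.testing.assert_array_equal(out.velocity, np.zeros((40, 3)))
        np.testing.assert_array_equal(out.position, np.zeros((40, 3)))

    def test_constant_bias_still_anchored(self):
        """Injected constant acceleration bias: dedrifting guarantees zero
        endpoint velocities regardless."""
        a = np.zeros((60, 3))
        a[:, 0] = 0.7
        out = integrate_direct(accel_track(a, 0.01))
        np.testing.assert_array_equal(out.velocity[0], np.zeros(3))
        np.testing.assert_array_equal(out.velocity[-1], np.zeros(3))
        # constant accel integrates to a line: dedrifting removes it entirely
        np.testing.assert_allclose(out.velocity, 0.0, atol=1e-12)

    def test_simulator_round_trip(self, clean_stride, clean_spec):
        rec, _ = clean_stride
        _, traj = run_pipeline(rec, orient_method="gyro", integ_method="direct")
        assert traj.stride_length == pytest.approx(clean_spec.stride_length, rel=0.01)


class TestDirectReverse:
    def test_drift_free_fusion_equals_direct(self):
        """When both integrals agree, any weighting returns the same curve."""
        track = bandlimited_track(n=301, dt=0.005)
        direct = integrate_direct(track)
        fused = integrate_direct_reverse(track)
        np.testing.assert_allclose(fused.velocity, direct.velocity, atol=2e-5)

    def test_bias_anchored_without_dedrifting(self):
        """A constant bias leaves both velocity endpoints exactly zero purely
        through the reverse-integral anchoring."""
        a = np.zeros((80, 3))
        a[:, 1] = 0.4
        out = integrate_direct_reverse(accel_track(a, 0.01))
        np.testing.assert_array_equal(out.velocity[0], np.zeros(3))
        np.testing.assert_array_equal(out.velocity[-1], np.zeros(3))

    def test_clearance_beats_direct_under_gyro_drift(self):
        """Paired comparison under constant-rate sensor drift: the fused
        scheme's clearance error is no worse than direct integration's."""
        from stridetraj.simulate import make_dataset

        base = SyntheticStrideSpec(gyro_bias=(0.052, -0.052, 0.052))
        errs = {"direct": [], "direct_reverse": []}
        for _, rec, truth in make_dataset(30, seed=0, base_spec=base):
            for name in errs:
                _, traj = run_pipeline(rec, orient_method="gyro", integ_method=name)
                errs[name].append(traj.clearance - truth.position[:, 1])
        prec = {k: np.std(np.concatenate(v)) for k, v in errs.items()}
        assert prec["direct_reverse"] <= prec["direct"]


class TestFourier:
    def test_pure_cosine_recovers_coefficient(self):
        n = 200
        t = np.arange(n) / (n - 1)
        x = np.cos(2 * np.pi * t)
        c = fourier_decompose(x, 10)
        assert c.cos[0] == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(c.cos[1:])) < 1e-9
        assert np.max(np.abs(c.sin)) < 1e-9

    def test_constant_reconstructs_to_zero(self):
        """DC is forced to zero: a constant signal reconstructs to ~0."""
        x = np.full(150, 2.5)
        c = fourier_decompose(x, 8)
        np.testing.assert_allclose(fourier_evaluate(c), 0.0, atol=1e-9)

    def test_bandlimited_reconstruction_error(self, clean_stride):
        """Movement acceleration of a simulated stride: < 5% RMS residual at
        the default expansion order."""
        rec, truth = clean_stride
        c = fourier_decompose(truth.accel_world[:, 1], 55)
        assert c.reconstruction_error < 0.05

    def test_overparameterised_rejected(self):
        with pytest.raises(ValueError):
            fourier_decompose(np.zeros(20), 10)

    def test_single_sine_closed_form(self):
        """a = sin(2πt/T) → v = (T/2π)(1 - cos(2πt/T)), exactly zero at T."""
        n, T = 400, 1.25
        t = np.arange(n) / (n - 1) * T
        c = fourier_decompose(np.sin(2 * np.pi * t / T), 5)
        v = fourier_analytic_integrate(c, T, order=1)
        want = T / (2 * np.pi) * (1.0 - np.cos(2 * np.pi * t / T))
        np.testing.assert_allclose(v, want, atol=1e-9)
        assert v[-1] == 0.0

    def test_zero_coefficients_zero_output(self):
        c = fourier_decompose(np.zeros(100), 4)
        assert np.all(fourier_analytic_integrate(c, 1.0, 1) == 0.0)
        assert np.all(fourier_analytic_integrate(c, 1.0, 2) == 0.0)

    @pytest.mark.parametrize("order", [1, 2])
    def test_agrees_with_trapezoid(self, order):
        """Analytic vs numeric integration agree to O(Δt²) on smooth input."""
        n, T = 1001, 1.0
        t = np.arange(n) / (n - 1) * T
        x = np.sin(2 * np.pi * t / T) + 0.4 * np.cos(6 * np.pi * t / T) - 0.4
        c = fourier_decompose(x, 20)
        xa = fourier_evaluate(c)
        dt = T / (n - 1)
        num = trapezoid_cumint(xa, dt)
        if order == 2:
            num = trapezoid_cumint(num, dt)
        ana = fourier_analytic_integrate(c, T, order=order)
        np.testing.assert_allclose(ana, num, atol=5e-5)


class TestBsplineIntegrate:
    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_polynomial_exact(self, degree):
        """Interpolating spline of order k integrates degree <= k exactly."""
        dt = 0.01
        t = np.arange(80) * dt
        x = np.polyval(np.arange(degree + 1) + 1.0, t)
        want = np.polyval(np.polyint(np.arange(degree + 1) + 1.0), t)
        got = bspline_analytic_integrate(
            x, AnalyticBasisParams(spline_order=degree), order=1, delta_t=dt
        )
        np.testing.assert_allclose(got, want - want[0], atol=1e-9)

    def test_zero_in_zero_out(self):
        out = bspline_analytic_integrate(np.zeros(50), order=2, delta_t=0.01)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_agrees_with_trapezoid_on_smooth(self):
        dt = 1e-3
        t = np.arange(1001) * dt
        x = np.sin(2 * np.pi * t)
        num = trapezoid_cumint(x, dt)
        ana = bspline_analytic_integrate(x, order=1, delta_t=dt)
        # the difference is the trapezoid rule's own O(Δt²) error:
        # |e| <= Δt²/12 · max|x'| · 2
        np.testing.assert_allclose(ana, num, atol=2 * np.pi * dt**2 / 6)


class TestBoundaryConditions:
    """Zero-velocity and level-floor conditions hold exactly for every scheme."""

    @pytest.mark.parametrize("name", list(ALL_INTEGRATORS))
    def test_machine_exact_endpoints(self, name, noisy_stride):
        rec, _ = noisy_stride
        _, traj = run_pipeline(rec, orient_method="madgwick", integ_method=name)
        assert np.all(traj.velocity[0] == 0.0)
        assert np.all(traj.velocity[-1] == 0.0)
        assert traj.position[0, 1] == 0.0
        assert traj.position[-1, 1] == 0.0
        assert np.all(traj.position[0] == 0.0)  # starts at the origin


class TestSchemeConsistency:
    def test_all_integrators_agree_in_ideal_limit(self):
        """Drift-free band-limited input at 1 kHz: all three schemes agree to
        within 1e-6 m."""
        track = bandlimited_track(n=1100, dt=1e-3, amp=1.0)
        results = {k: f(track) for k, f in ALL_INTEGRATORS.items()}
        names = list(results)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = np.max(
                    np.abs(results[names[i]].position - results[names[j]].position)
                )
                assert diff < 1e-6, (names[i], names[j], diff)

    @pytest.mark.parametrize("name", list(ALL_INTEGRATORS))
    def test_stride_length_heading_invariant(self, name, noisy_stride):
        """Rotating the world frame about vertical leaves stride length
        unchanged (all steps are linear and the dedrift split uses norms)."""
        rec, _ = noisy_stride
        track = gyro_integrate(rec)
        aw = to_world(track, rec.segment(rec.accel))
        ang = 0.7
        R = np.array(
            [
                [np.cos(ang), 0, np.sin(ang)],
                [0, 1, 0],
                [-np.sin(ang), 0, np.cos(ang)],
            ]
        )
        base = remove_gravity_and_dedrift(aw)
        rot = remove_gravity_and_dedrift(aw @ R.T)
        l0 = ALL_INTEGRATORS[name](base).stride_length
        l1 = ALL_INTEGRATORS[name](rot).stride_length
        assert l1 == pytest.approx(l0, abs=1e-9)


class TestParameterRecovery:
    @pytest.mark.parametrize("length", [0.5, 1.0, 1.5])
    def test_median_error_under_noise(self, length):
        """Realistic sensor noise: median stride-length error < 5% of L for
        the best pipeline."""
        errs = []
        for seed in range(9):
            spec = SyntheticStrideSpec(stride_length=length, seed=seed)
            rec, _ = simulate_stride(spec)
            _, traj = run_pipeline(
                rec, orient_method="madgwick", integ_method="direct_reverse"
            )
            errs.append(abs(traj.stride_length - length))
        assert np.median(errs) < 0.05 * length


class TestRunPipeline:
    def test_unknown_method_rejected(self, noisy_stride):
        rec, _ = noisy_stride
        with pytest.raises(ValueError):
            run_pipeline(rec, integ_method="simpson")

    def test_all_nine_combinations_run(self, noisy_stride):
        rec, _ = noisy_stride
        for om in ("gyro", "madgwick", "euston"):
            for im in ("direct", "direct_reverse", "analytic"):
                track, traj = run_pipeline(rec, orient_method=om, integ_method=im)
                assert np.isfinite(traj.position).all()
                assert len(track) == len(traj.position)

    def test_deterministic(self, noisy_stride):
        rec, _ = noisy_stride
        _, a = run_pipeline(rec)
        _, b = run_pipeline(rec)
        np.testing.assert_array_equal(a.position, b.position)
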