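"""World-frame transformation, gravity removal and the three double-integration
schemes (direct, direct & reverse, analytic).

All schemes enforce the two per-stride boundary conditions exactly:

* zero-velocity: ``v = 0`` at both mid-stances (the foot is stationary),
* level floor: vertical position ``sy = 0`` at both mid-stances.

Exactness matters: the corrections are constructed so the endpoint samples are
bit-exact zeros (e.g. drift lines are evaluated as ``y0·(1-τ) + y1·τ`` so the
endpoint subtraction cancels exactly in floating point, and Fourier basis
phases are reduced modulo the period with integer arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import splantider, splev, splrep
from sklearn.base import BaseEstimator, TransformerMixin

from . import quat
from .orientation import OrientationTrack
from .stride import StrideRecording, WorldFrame

__all__ = [
    "WorldAccelTrack",
    "TrajectoryEstimate",
    "SigmoidFusionParams",
    "AnalyticBasisParams",
    "FourierCoefficients",
    "to_world",
    "remove_gravity_and_dedrift",
    "trapezoid_cumint",
    "linear_dedrift",
    "integrate_direct",
    "reverse_accel",
    "sigmoid_weight",
    "integrate_direct_reverse",
    "fourier_decompose",
    "fourier_analytic_integrate",
    "bspline_analytic_integrate",
    "integrate_analytic",
    "run_pipeline",
    "DirectIntegrator",
    "DirectReverseIntegrator",
    "AnalyticIntegrator",
]

#: Vertical axis index (world y): clearance is the y component of position.
VERTICAL = 1
GROUND_PLANE = (0, 2)


@dataclass
class WorldAccelTrack:
    """Gravity-free movement acceleration in the world frame (m/s²)."""

    accel_world: np.ndarray  # (n, 3)
    timestamps: np.ndarray  # (n,)

    @property
    def delta_t(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class TrajectoryEstimate:
    """World-frame velocity (m/s) and position (m) over one stride.

    Position starts at the origin; velocity is zero and the vertical position
    is zero at both stride endpoints.
    """

    velocity: np.ndarray  # (n, 3)
    position: np.ndarray  # (n, 3)

    @property
    def stride_length(self) -> float:
        """Horizontal displacement norm between the two mid-stances (m)."""
        d = self.position[-1, list(GROUND_PLANE)] - self.position[0, list(GROUND_PLANE)]
        return float(np.linalg.norm(d))

    @property
    def clearance(self) -> np.ndarray:
        """Vertical (world-y) position course, m."""
        return self.position[:, VERTICAL]

    @property
    def max_clearance(self) -> float:
        return float(np.max(self.clearance))


@dataclass
class SigmoidFusionParams:
    """Sigmoid weighting for direct & reverse fusion.

    t0 : sigmoid mid-point as a fraction of the stride duration, in [0, 1].
    eta : steepness; the limit ``eta → ∞`` is a linear ramp.
    """

    t0: float = 0.6
    eta: float = 0.08

    def __post_init__(self) -> None:
        if not 0.0 <= self.t0 <= 1.0:
            raise ValueError("t0 must lie in [0, 1]")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass
class AnalyticBasisParams:
    """Bases for the analytic integration scheme.

    n_fourier : Fourier expansion order for axes with cyclic boundary
        conditions.  The default of 60 keeps the average reconstruction error
        of unfiltered ~100 Hz gait acceleration below ~5%; it is capped
        automatically when a stride has too few samples.
    spline_order, spline_smoothing : B-spline degree and smoothing factor
        (Dierckx ``s``) for the non-cyclic ground-plane position integrals;
        ``smoothing=0`` interpolates.
    """

    basis: str = "fourier"
    n_fourier: int = 60
    spline_order: int = 3
    spline_smoothing: float = 0.0

    def __post_init__(self) -> None:
        if self.basis not in ("fourier", "bspline"):
            raise ValueError("basis must be 'fourier' or 'bspline'")
        if self.n_fourier < 1:
            raise ValueError("n_fourier must be >= 1")
        if self.spline_order < 1:
            raise ValueError("spline_order must be >= 1")


@dataclass
class FourierCoefficients:
    """Zero-DC Fourier expansion of one scalar stride signal."""

    cos: np.ndarray  # c1(k), k = 1..N
    sin: np.ndarray  # c2(k)
    n_samples: int
    reconstruction_error: float  # relative RMS residual

    @property
    def n_terms(self) -> int:
        return len(self.cos)


def to_world(track: OrientationTrack, accel_sensor: np.ndarray) -> np.ndarray:
    """Rotate sensor-frame accelerations into the world frame, per sample."""
    accel_sensor = np.asarray(accel_sensor, dtype=float)
    if len(accel_sensor) != len(track):
        raise ValueError("orientation track and acceleration must align per sample")
    out = np.empty_like(accel_sensor)
    for i, q in enumerate(track.quaternions):
        out[i] = quat.rotate(q, accel_sensor[i])
    return out


def _endpoint_line(y: np.ndarray) -> np.ndarray:
    """Line through the endpoint values, exact at both endpoints."""
    n = len(y)
    tau = np.arange(n) / (n - 1)
    return y[0] * (1.0 - tau) + y[-1] * tau


def remove_gravity_and_dedrift(
    aw: np.ndarray,
    frame: WorldFrame | None = None,
    timestamps: np.ndarray | None = None,
    piecewise: bool = True,
) -> WorldAccelTrack:
    """Subtract gravity and enforce ``a = 0`` at both stride endpoints.

    ``aw`` is the world-frame acceleration in units of g (specific force, so
    a perfectly tracked static stride reads ``(0, 1, 0)``).  Gravity removal
    leaves the movement component, converted to m/s².  Because orientation
    errors corrupt the boundary condition ``a(tms) = a(tms+1) = 0``, a
    piecewise-linear drift estimate is subtracted per axis: one segment from
    the start residual down to zero at the sample of maximal acceleration
    magnitude, one from zero up to the end residual.  The movement peak is
    assumed drift-free; set ``piecewise=False`` for a single endpoint-to-
    endpoint line instead.
    """
    aw = np.asarray(aw, dtype=float)
    n = len(aw)
    if n < 3:
        raise ValueError("need at least 3 samples")
    frame = frame or WorldFrame()
    a = (aw - (-frame.gravity_world)) * frame.g_mag
    split = int(np.argmax(np.linalg.norm(a, axis=1)))
    drift = np.empty_like(a)
    if piecewise and 0 < split < n - 1:
        tau1 = np.arange(split + 1) / split
        tau2 = np.arange(n - split) / (n - 1 - split)
        for ax in range(3):
            drift[: split + 1, ax] = a[0, ax] * (1.0 - tau1)
            drift[split:, ax] = a[-1, ax] * tau2
    else:
        for ax in range(3):
            drift[:, ax] = _endpoint_line(a[:, ax])
    a = a - drift
    if timestamps is None:
        timestamps = np.arange(n, dtype=float)
    return WorldAccelTrack(a, np.asarray(timestamps, dtype=float))


def trapezoid_cumint(x: np.ndarray, delta_t: float) -> np.ndarray:
    """Cumulative trapezoidal integral starting at 0."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return cumulative_trapezoid(x, dx=delta_t, initial=0.0)


def linear_dedrift(y: np.ndarray) -> np.ndarray:
    """Subtract the endpoint-to-endpoint line; both endpoints become exactly 0."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    return y - _endpoint_line(y)


def integrate_direct(a: WorldAccelTrack) -> TrajectoryEstimate:
    """Direct integration with linear velocity dedrifting.

    Velocity: trapezoidal integral of each acceleration axis, linearly
    dedrifted to honour the zero-velocity boundary condition.  Position:
    trapezoidal integral of the velocity; the vertical axis is additionally
    linearly dedrifted to honour the level-floor condition.
    """
    dt = a.delta_t
    v = np.column_stack(
        [linear_dedrift(trapezoid_cumint(a.accel_world[:, ax], dt)) for ax in range(3)]
    )
    s = np.column_stack([trapezoid_cumint(v[:, ax], dt) for ax in range(3)])
    s[:, VERTICAL] = linear_dedrift(s[:, VERTICAL])
    return TrajectoryEstimate(v, s)


def reverse_accel(a: np.ndarray) -> np.ndarray:
    """Flip a signal in time and direction: ``a←[i] = -a[n-1-i]``."""
    return -np.asarray(a, dtype=float)[::-1]


def sigmoid_weight(n: int, params: SigmoidFusionParams | None = None) -> np.ndarray:
    """Endpoint-normalised sigmoid fusion weights on normalised stride time.

    ``h(τ) = (1 + exp(-(τ - t0)/η))⁻¹`` evaluated on ``τ = i/(n-1)`` and
    normalised so ``w[0] = 0`` and ``w[n-1] = 1`` exactly; monotone
    non-decreasing.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    params = params or SigmoidFusionParams()
    tau = np.arange(n) / (n - 1)
    h = 1.0 / (1.0 + np.exp(-(tau - params.t0) / params.eta))
    return (h - h[0]) / (h[-1] - h[0])


def _fuse_direct_reverse(x: np.ndarray, dt: float, w: np.ndarray) -> np.ndarray:
    """Fused forward and time-reversed trapezoidal integral of one axis.

    The forward integral anchors the known zero initial value, the reversed
    integral anchors the known zero final value; the sigmoid weight blends
    them so both boundary values hold exactly without explicit dedrifting.
    """
    forward = trapezoid_cumint(x, dt)
    backward = trapezoid_cumint(reverse_accel(x), dt)[::-1]
    return (1.0 - w) * forward + w * backward


def integrate_direct_reverse(
    a: WorldAccelTrack, params: SigmoidFusionParams | None = None
) -> TrajectoryEstimate:
    """Direct & time-reversed integration with sigmoid fusion.

    Velocity on every axis and the vertical position both satisfy cyclic
    boundary conditions (zero velocity, level floor) and are computed as
    sigmoid-weighted fusions of a forward and a reversed integral.  The
    ground-plane position has no known final value and is obtained by direct
    integration of the fused velocity, without further correction.
    """
    params = params or SigmoidFusionParams()
    dt = a.delta_t
    n = len(a.accel_world)
    w = sigmoid_weight(n, params)
    v = np.column_stack(
        [_fuse_direct_reverse(a.accel_world[:, ax], dt, w) for ax in range(3)]
    )
    s = np.column_stack([trapezoid_cumint(v[:, ax], dt) for ax in range(3)])
    s[:, VERTICAL] = _fuse_direct_reverse(v[:, VERTICAL], dt, w)
    return TrajectoryEstimate(v, s)


def _fourier_phases(n: int, n_terms: int) -> np.ndarray:
    """Phases ``2π k i / (n-1)`` reduced mod 2π with integer arithmetic.

    Integer reduction makes the basis exactly periodic on the sample grid:
    sin is bit-exact 0 and cos bit-exact 1 at both stride endpoints, which is
    what guarantees machine-exact boundary conditions downstream.
    """
    i = np.arange(n)
    k = np.arange(1, n_terms + 1)[:, None]
    return 2.0 * np.pi * ((k * i) % (n - 1)) / (n - 1)


def fourier_decompose(x: np.ndarray, n_terms: int) -> FourierCoefficients:
    """Least-squares projection onto a zero-DC Fourier basis of period T.

    The DC component is forced to zero (zero acceleration at both stride
    endpoints), so a constant signal reconstructs to ~0.  Raises
    ``ValueError`` when ``n_terms >= n/2`` (over-parameterised).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if n_terms >= n / 2:
        raise ValueError("n_terms must be < n/2 to stay over-determined")
    phases = _fourier_phases(n, n_terms)
    design = np.concatenate([np.cos(phases), np.sin(phases)]).T  # (n, 2N)
    # fit on one exact period (the last sample duplicates τ = 0 in the
    # periodic extension); this keeps the harmonics orthogonal to constants
    coef, *_ = np.linalg.lstsq(design[:-1], x[:-1], rcond=None)
    resid = x - design @ coef
    scale = np.sqrt(np.mean(x**2))
    err = float(np.sqrt(np.mean(resid**2)) / scale) if scale > 0 else 0.0
    return FourierCoefficients(coef[:n_terms], coef[n_terms:], n, err)


def fourier_evaluate(coeffs: FourierCoefficients) -> np.ndarray:
    """Reconstructed signal on the original sample grid."""
    phases = _fourier_phases(coeffs.n_samples, coeffs.n_terms)
    return coeffs.cos @ np.cos(phases) + coeffs.sin @ np.sin(phases)


def fourier_analytic_integrate(
    coeffs: FourierCoefficients, T: float, order: int = 1
) -> np.ndarray:
    """Term-wise analytic integral of a zero-DC Fourier expansion.

    Integration constants are fixed by zero initial values.  ``order=1``
    returns the velocity-like single integral (exactly zero at both stride
    endpoints because every term is periodic); ``order=2`` the double
    integral, which retains a linear component ``c2(k)·t/ω_k`` and therefore
    generally needs dedrifting against the level-floor condition.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n = coeffs.n_samples
    k = np.arange(1, coeffs.n_terms + 1)
    omega = 2.0 * np.pi * k / T
    phases = _fourier_phases(n, coeffs.n_terms)
    sin_p, cos_p = np.sin(phases), np.cos(phases)
    if order == 1:
        return (coeffs.cos / omega) @ sin_p + (coeffs.sin / omega) @ (1.0 - cos_p)
    # ∫∫: s(t) = Σ c1k (1-cos ωk t)/ωk² + c2k (t/ωk - sin(ωk t)/ωk²)
    t = np.arange(n) / (n - 1) * T
    return (
        (coeffs.cos / omega**2) @ (1.0 - cos_p)
        + t * float(np.sum(coeffs.sin / omega))
        - (coeffs.sin / omega**2) @ sin_p
    )


def bspline_analytic_integrate(
    x: np.ndarray,
    params: AnalyticBasisParams | None = None,
    order: int = 1,
    delta_t: float = 1.0,
) -> np.ndarray:
    """Fit a smoothing B-spline to ``x`` and integrate it analytically.

    The antiderivative of a degree-k spline is the exactly computable
    degree-(k+1) spline; initial value 0.  With ``spline_smoothing=0`` the fit
    interpolates, so polynomials of degree <= ``spline_order`` integrate
    exactly.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    params = params or AnalyticBasisParams()
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) * delta_t
    tck = splrep(t, x, k=params.spline_order, s=params.spline_smoothing)
    anti = splantider(tck, order)
    y = np.asarray(splev(t, anti), dtype=float)
    return y - y[0]


def integrate_analytic(
    a: WorldAccelTrack, params: AnalyticBasisParams | None = None
) -> TrajectoryEstimate:
    """Analytic integration: Fourier basis for cyclic axes, B-splines otherwise.

    Velocities (all axes) and the vertical double integral are computed in the
    zero-DC Fourier basis, whose periodicity realises the cyclic boundary
    conditions; the vertical position is additionally linearly dedrifted to
    pin the level-floor condition exactly.  The non-cyclic ground-plane
    position is obtained by analytic integration of the velocity in a B-spline
    basis.  The Fourier order is capped at ``(n-2)//2`` for short strides.
    """
    params = params or AnalyticBasisParams()
    n = len(a.accel_world)
    dt = a.delta_t
    T = a.duration
    n_terms = min(params.n_fourier, max(1, (n - 2) // 2))
    coeffs = [fourier_decompose(a.accel_world[:, ax], n_terms) for ax in range(3)]
    v = np.column_stack([fourier_analytic_integrate(c, T, order=1) for c in coeffs])
    s = np.empty_like(v)
    for ax in GROUND_PLANE:
        s[:, ax] = bspline_analytic_integrate(v[:, ax], params, order=1, delta_t=dt)
    s[:, VERTICAL] = linear_dedrift(
        fourier_analytic_integrate(coeffs[VERTICAL], T, order=2)
    )
    return TrajectoryEstimate(v, s)


_INTEGRATORS = {
    "direct": lambda a, p: integrate_direct(a),
    "direct_reverse": integrate_direct_reverse,
    "analytic": integrate_analytic,
}


def run_pipeline(
    stride: StrideRecording,
    orient_method: str = "madgwick",
    orient_params=None,
    integ_method: str = "direct_reverse",
    integ_params=None,
    frame: WorldFrame | None = None,
    dedrift_piecewise: bool = True,
) -> tuple[OrientationTrack, TrajectoryEstimate]:
    """Full deterministic per-stride pipeline; any of the 3×3 combinations.

    Orientation estimation → world-frame transform → gravity removal with
    piecewise-linear dedrifting → double integration.
    """
    from .orientation import run_tracker  # local import avoids cycle at module load

    if integ_method not in _INTEGRATORS:
        raise ValueError(f"unknown integration method: {integ_method!r}")
    track = run_tracker(stride, orient_method, params=orient_params)
    aw = to_world(track, stride.segment(stride.accel))
    awt = remove_gravity_and_dedrift(
        aw,
        frame,
        timestamps=stride.segment(stride.timestamps),
        piecewise=dedrift_piecewise,
    )
    traj = _INTEGRATORS[integ_method](awt, integ_params)
    return track, traj


class _BaseIntegrator(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: ``(stride, track)`` pairs → trajectories."""

    def fit(self, X, y=None):
        self.n_strides_ = len(X)
        return self

    def _integrate(self, awt: WorldAccelTrack) -> TrajectoryEstimate:
        raise NotImplementedError

    def estimate(
        self, stride: StrideRecording, track: OrientationTrack
    ) -> TrajectoryEstimate:
        """Trajectory for a single stride given its orientation track."""
        frame = WorldFrame(g_mag=getattr(self, "g_mag", 9.81))
        aw = to_world(track, stride.segment(stride.accel))
        awt = remove_gravity_and_dedrift(
            aw,
            frame,
            timestamps=stride.segment(stride.timestamps),
            piecewise=getattr(self, "dedrift_piecewise", True),
        )
        return self._integrate(awt)

    def transform(self, X):
        return [self.estimate(stride, track) for stride, track in X]


class DirectIntegrator(_BaseIntegrator):
    """Parameter-free direct integration with linear dedrifting."""

    def __init__(self, g_mag: float = 9.81, dedrift_piecewise: bool = True):
        self.g_mag = g_mag
        self.dedrift_piecewise = dedrift_piecewise

    def _integrate(self, awt):
        return integrate_direct(awt)


class DirectReverseIntegrator(_BaseIntegrator):
    """Direct & time-reversed integration fused by a sigmoid weight."""

    def __init__(
        self,
        t0: float = 0.6,
        eta: float = 0.08,
        g_mag: float = 9.81,
        dedrift_piecewise: bool = True,
    ):
        self.t0 = t0
        self.eta = eta
        self.g_mag = g_mag
        self.dedrift_piecewise = dedrift_piecewise

    def _integrate(self, awt):
        return integrate_direct_reverse(awt, SigmoidFusionParams(self.t0, self.eta))


class AnalyticIntegrator(_BaseIntegrator):
    """Analytic integration in zero-DC Fourier and B-spline bases."""

    def __init__(
        self,
        n_fourier: int = 60,
        spline_order: int = 3,
        spline_smoothing: float = 0.0,
        g_mag: float = 9.81,
        dedrift_piecewise: bool = True,
    ):
        self.n_fourier = n_fourier
        self.spline_order = spline_order
        self.spline_smoothing = spline_smoothing
        self.g_mag = g_mag
        self.dedrift_piecewise = dedrift_piecewise

    def _integrate(self, awt):
        return integrate_analytic(
            awt,
            AnalyticBasisParams(
                n_fourier=self.n_fourier,
                spline_order=self.spline_order,
                spline_smoothing=self.spline_smoothing,
            ),
        )
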