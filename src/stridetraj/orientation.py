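"""Per-stride orientation tracking: gyroscope integration and two
complementary filters (Madgwick, Euston).

All three trackers propagate a sensor-to-world unit quaternion from the first
mid-stance to the next with the first-order update

    q(t) = normalize(q(t-Δt) + q̇(t)·Δt),

where q̇ is the pure gyroscope quaternion rate ``½ q ⊗ (0, ω)`` optionally
corrected by accelerometer gravity sensing.  Accelerometer corrections are
gated: they are applied only outside the swing phase and only when the
accelerometer magnitude is within ``γ`` of 1 g (quasi-static condition).

The magnetometer path of the original Madgwick filter and the airspeed path
of the original Euston filter are absent by design — neither signal exists in
the shoe-mounted setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from . import quat
from .stride import StrideRecording, initial_orientation

__all__ = [
    "MadgwickParams",
    "EustonParams",
    "OrientationTrack",
    "swing_mask",
    "accel_gate",
    "gravity_sensor_frame",
    "gravity_error_jacobian",
    "gyro_step",
    "madgwick_step",
    "euston_step",
    "gyro_integrate",
    "run_tracker",
    "stance_update_fraction",
    "max_gyro_error",
    "GyroTracker",
    "MadgwickTracker",
    "EustonTracker",
]

#: Default swing-phase gyro-norm threshold (rad/s) and closing width (s).
DEFAULT_SWING_THRESHOLD = 1.5
DEFAULT_SWING_CLOSING = 0.05


@dataclass
class MadgwickParams:
    """Madgwick filter parameters.

    beta : gradient-step magnitude in rad/s, proportional to the maximal
        gyroscope measurement error.  Default 0.046 rad/s (grid-search optimum
        reported for a 735-stride reference dataset).
    gamma : half-width of the accelerometer acceptance band around 1 g
        (dimensionless).  Default 0.24.
    """

    beta: float = 0.046
    gamma: float = 0.24

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError("beta must be finite and non-negative")
        if not self.gamma >= 0:  # inf allowed: an all-pass acceptance band
            raise ValueError("gamma must be non-negative")


@dataclass
class EustonParams:
    """Euston filter parameters (proportional / integral gains in rad/s)."""

    k_p: float = 0.0046
    k_i: float = 0.0
    gamma: float = 2.50

    def __post_init__(self) -> None:
        for name in ("k_p", "k_i"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if not self.gamma >= 0:  # inf allowed: an all-pass acceptance band
            raise ValueError("gamma must be non-negative")


@dataclass
class OrientationTrack:
    """Per-sample quaternion sequence over one stride.

    quaternions : (n, 4) array, one unit quaternion per sample of
        ``[i_ms_start, i_ms_end]``; the first row is the initial-inclination
        quaternion.
    accel_update_mask : (n,) bool, True where an accelerometer correction was
        actually applied.
    """

    quaternions: np.ndarray
    accel_update_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.accel_update_mask is None:
            self.accel_update_mask = np.zeros(len(self.quaternions), dtype=bool)
        self.accel_update_mask = np.asarray(self.accel_update_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.quaternions)


def swing_mask(
    gyro: np.ndarray,
    delta_t: float,
    threshold: float = DEFAULT_SWING_THRESHOLD,
    closing: float = DEFAULT_SWING_CLOSING,
) -> np.ndarray:
    """Boolean swing-phase mask from the gyro norm.

    Swing = samples where ``||ω||`` exceeds ``threshold`` (rad/s), smoothed
    by morphological closing over ``closing`` seconds so short dips below the
    threshold inside the swing phase do not re-enable accelerometer updates.
    Stance is the complement.
    """
    gyro = np.asarray(gyro, dtype=float)
    mask = np.linalg.norm(gyro, axis=1) > threshold
    width = max(1, int(round(closing / delta_t)))
    if width > 1 and mask.any():
        mask = ndimage.binary_closing(mask, structure=np.ones(width, dtype=bool))
    return mask


def accel_gate(accel, gamma: float, in_swing: bool) -> bool:
    """True iff an accelerometer orientation update is admissible.

    Requires stance phase and ``| ||a|| - 1 | <= γ`` (accelerometer magnitude
    within the gravity band, in units of g).
    """
    if in_swing:
        return False
    a = np.asarray(accel, dtype=float)
    return bool(abs(np.linalg.norm(a) - 1.0) <= gamma)


def gravity_sensor_frame(q: np.ndarray) -> np.ndarray:
    """Predicted gravity direction in the sensor frame, ``gs = R(q)ᵀ gw``.

    With ``gw = (0, -1, 0)`` this is minus the second row of ``R(q)``:
    ``(-2(q1 q2 + q0 q3), -q0² + q1² - q2² + q3², 2(q0 q1 - q2 q3))``.
    """
    w, x, y, z = q
    return np.array(
        [
            -2.0 * (x * y + w * z),
            -w * w + x * x - y * y + z * z,
            2.0 * (w * x - y * z),
        ]
    )


def gravity_error_jacobian(q: np.ndarray) -> np.ndarray:
    """Jacobian ``J = ∂ gs / ∂ (q0, q1, q2, q3)`` of :func:`gravity_sensor_frame`."""
    w, x, y, z = q
    return np.array(
        [
            [-2 * z, -2 * y, -2 * x, -2 * w],
            [-2 * w, 2 * x, -2 * y, 2 * z],
            [2 * x, 2 * w, -2 * z, -2 * y],
        ]
    )


def _check_unit(q: np.ndarray) -> None:
    if abs(quat.norm(q) - 1.0) > quat.UNIT_TOL:
        raise ValueError("tracker state drifted off the unit sphere")


def gyro_step(q_prev: np.ndarray, omega, delta_t: float) -> np.ndarray:
    """One first-order gyroscope-integration update (normalised)."""
    return quat.normalize(q_prev + quat.derivative(q_prev, omega) * delta_t)


def madgwick_step(
    q_prev: np.ndarray,
    omega,
    accel,
    params: MadgwickParams,
    use_accel: bool,
    delta_t: float,
) -> tuple[np.ndarray, bool]:
    """One Madgwick update; returns ``(q, corrected)``.

    When ``use_accel`` is set, the gyroscope quaternion rate is corrected by a
    normalised gradient step on the gravity-alignment error
    ``ε = gs(q_prev) + as`` (the accelerometer measures specific force, the
    negative of gravity, so ε vanishes at perfect alignment):

        q̇ = q̇ω - β · Jᵀε / ||Jᵀε||

    If the gradient vanishes (ε = 0 or orthogonal to the Jacobian range) the
    step degrades gracefully to pure gyroscope integration.
    """
    _check_unit(q_prev)
    if not use_accel or params.beta == 0.0:
        return gyro_step(q_prev, omega, delta_t), False
    eps = gravity_sensor_frame(q_prev) + np.asarray(accel, dtype=float)
    grad = gravity_error_jacobian(q_prev).T @ eps
    gn = np.linalg.norm(grad)
    if gn == 0.0:
        # perfect alignment (or degenerate gradient): the correction is zero;
        # the update path was active nonetheless, so it counts as applied
        return gyro_step(q_prev, omega, delta_t), True
    qdot = quat.derivative(q_prev, omega) - params.beta * grad / gn
    return quat.normalize(q_prev + qdot * delta_t), True


def euston_step(
    q_prev: np.ndarray,
    omega,
    accel,
    params: EustonParams,
    use_accel: bool,
    integ_state: np.ndarray,
    delta_t: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One Euston update; returns ``(q, integ_state, corrected)``.

    The angular mismatch between predicted and measured gravity direction,
    ``e = (gs/||gs||) × (as/||as||)``, feeds a PI correction of the angular
    rate: ``ω* = ω + kP e + kI ∫e dt``.  The integral is accumulated by the
    trapezoidal rule; ``integ_state`` carries it between samples and is reset
    at every stride start.  A zero-norm accelerometer sample disables the
    correction for that step.
    """
    _check_unit(q_prev)
    omega = np.asarray(omega, dtype=float)
    if use_accel:
        a = np.asarray(accel, dtype=float)
        an = np.linalg.norm(a)
        if an == 0.0:
            use_accel = False
    if not use_accel or (params.k_p == 0.0 and params.k_i == 0.0):
        return gyro_step(q_prev, omega, delta_t), integ_state, False
    gs = gravity_sensor_frame(q_prev)
    e = np.cross(gs / np.linalg.norm(gs), a / an)
    # integ_state holds J_k = sum(e_j * dt): the trapezoidal integral up to
    # the current sample is I_k = J_{k-1} + e_k * dt / 2 (e = 0 at stride start)
    integral = integ_state + e * (0.5 * delta_t)
    integ_state = integ_state + e * delta_t
    delta = params.k_p * e + params.k_i * integral
    return gyro_step(q_prev, omega + delta, delta_t), integ_state, True


def gyro_integrate(stride: StrideRecording, q0: np.ndarray | None = None) -> OrientationTrack:
    """Pure gyroscope-integration track over ``[i_ms_start, i_ms_end]``."""
    return run_tracker(stride, "gyro", q0=q0)


def run_tracker(
    stride: StrideRecording,
    method: str,
    params: MadgwickParams | EustonParams | None = None,
    q0: np.ndarray | None = None,
    swing_threshold: float = DEFAULT_SWING_THRESHOLD,
    swing_closing: float = DEFAULT_SWING_CLOSING,
) -> OrientationTrack:
    """Run one of the three orientation trackers over a stride.

    ``method`` is one of ``"gyro"``, ``"madgwick"``, ``"euston"``.  The
    initial quaternion defaults to the inclination estimated from the
    accelerometer sample at ``i_ms_start``.  Deterministic.
    """
    if method not in ("gyro", "madgwick", "euston"):
        raise ValueError(f"unknown orientation method: {method!r}")
    gyro = stride.segment(stride.gyro)
    accel = stride.segment(stride.accel)
    n = len(gyro)
    if q0 is None:
        q0 = initial_orientation(accel[0])
    if method == "gyro":
        in_swing = None
    else:
        if params is None:
            params = MadgwickParams() if method == "madgwick" else EustonParams()
        in_swing = swing_mask(gyro, stride.delta_t, swing_threshold, swing_closing)

    quats = np.empty((n, 4))
    mask = np.zeros(n, dtype=bool)
    quats[0] = q0
    q = np.asarray(q0, dtype=float)
    integ_state = np.zeros(3)
    dt = stride.delta_t
    for i in range(1, n):
        if method == "gyro":
            q = gyro_step(q, gyro[i], dt)
        elif method == "madgwick":
            use = accel_gate(accel[i], params.gamma, in_swing[i])
            q, corrected = madgwick_step(q, gyro[i], accel[i], params, use, dt)
            mask[i] = corrected
        else:
            use = accel_gate(accel[i], params.gamma, in_swing[i])
            q, integ_state, corrected = euston_step(
                q, gyro[i], accel[i], params, use, integ_state, dt
            )
            mask[i] = corrected
        quats[i] = q
    return OrientationTrack(quats, mask)


def stance_update_fraction(track: OrientationTrack, stance_mask: np.ndarray) -> float:
    """Fraction of stance-phase samples that received an accelerometer update."""
    stance_mask = np.asarray(stance_mask, dtype=bool)
    if len(stance_mask) != len(track):
        raise ValueError("stance mask and track must have equal length")
    n_stance = int(stance_mask.sum())
    if n_stance == 0:
        return 0.0
    return float(np.count_nonzero(track.accel_update_mask & stance_mask) / n_stance)


def max_gyro_error(beta: float, relation: str = "madgwick") -> float:
    """Maximal gyroscope measurement error (rad/s) implied by ``beta``.

    ``relation="madgwick"`` inverts the original gain definition
    ``β = sqrt(3/4)·ω̃max``, i.e. ``ω̃max = 2/sqrt(3)·β`` (β = 0.046 rad/s
    maps to 3.04 °/s).  ``relation="four_thirds"`` uses the alternative
    ``ω̃max = 4/3·β``.
    """
    if relation == "madgwick":
        return 2.0 / np.sqrt(3.0) * beta
    if relation == "four_thirds":
        return 4.0 / 3.0 * beta
    raise ValueError(f"unknown relation: {relation!r}")


class _BaseTracker(BaseEstimator, TransformerMixin):
    """sklearn-style transformer mapping stride recordings to orientation tracks.

    ``transform`` accepts a list of :class:`StrideRecording` and returns a list
    of ``(stride, OrientationTrack)`` pairs so that an integrator transformer
    can be chained behind it in a :class:`sklearn.pipeline.Pipeline`.
    """

    _method: str = ""

    def fit(self, X, y=None):  # noqa: D102 - stateless, records bookkeeping only
        self.n_strides_ = len(X)
        return self

    def _params(self):
        return None

    def track(self, stride: StrideRecording) -> OrientationTrack:
        """Orientation track for a single stride."""
        return run_tracker(
            stride,
            self._method,
            params=self._params(),
            swing_threshold=getattr(self, "swing_threshold", DEFAULT_SWING_THRESHOLD),
            swing_closing=getattr(self, "swing_closing", DEFAULT_SWING_CLOSING),
        )

    def transform(self, X):
        return [(stride, self.track(stride)) for stride in X]


class GyroTracker(_BaseTracker):
    """Parameter-free gyroscope-integration orientation tracker."""

    _method = "gyro"


class MadgwickTracker(_BaseTracker):
    """Madgwick complementary filter (magnetometer-free, gravity-gated)."""

    _method = "madgwick"

    def __init__(
        self,
        beta: float = 0.046,
        gamma: float = 0.24,
        swing_threshold: float = DEFAULT_SWING_THRESHOLD,
        swing_closing: float = DEFAULT_SWING_CLOSING,
    ):
        self.beta = beta
        self.gamma = gamma
        self.swing_threshold = swing_threshold
        self.swing_closing = swing_closing

    def _params(self) -> MadgwickParams:
        return MadgwickParams(beta=self.beta, gamma=self.gamma)


class EustonTracker(_BaseTracker):
    """Euston explicit complementary filter (airspeed path removed)."""

    _method = "euston"

    def __init__(
        self,
        k_p: float = 0.0046,
        k_i: float = 0.0,
        gamma: float = 2.50,
        swing_threshold: float = DEFAULT_SWING_THRESHOLD,
        swing_closing: float = DEFAULT_SWING_CLOSING,
    ):
        self.k_p = k_p
        self.k_i = k_i
        self.gamma = gamma
        self.swing_threshold = swing_threshold
        self.swing_closing = swing_closing

    def _params(self) -> EustonParams:
        return EustonParams(k_p=self.k_p, k_i=self.k_i, gamma=self.gamma)
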