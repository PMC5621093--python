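"""Synthetic gait strides with exact ground truth.

The simulator emulates the stride population of a marker-referenced gait
laboratory recording (healthy over-ground walking at low / normal / high
stride lengths and velocities) for a shoe-mounted IMU sampled at 102.4 Hz,
and produces both

* the exact ground truth (position, velocity, world acceleration and
  sensor-to-world orientation per sample), and
* the corresponding noisy sensor-frame IMU signals, by inverting the
  estimation pipeline's forward model analytically.

Every stride satisfies the boundary conditions the estimators assume: the
foot is stationary at both mid-stances (zero velocity and acceleration),
starts and ends on the floor (zero vertical position) and is quasi-static
during the stance dwell around the mid-stances.

Closed-form motion model (swing phase, normalised swing time τ ∈ [0, 1]):

* horizontal progression: minimum-jerk profile
  ``x(τ) = L (10τ³ - 15τ⁴ + 6τ⁵)``;
* clearance: two-lobe curve ``y(τ) ∝ sin⁴(πτ)(1 + d cos 2πτ)`` which for
  ``d > 1/2`` has exactly two maxima with a mid-swing dip — the
  heel-off / toe-off shape of a shoe-mounted sensor — scaled to the requested
  peak clearance;
* sagittal pitch: ``θ(τ) = -A sin(2πτ) sin²(πτ)`` (plantarflexion after
  toe-off, dorsiflexion before heel strike), optionally with a small frontal
  wobble, composed with a constant mounting-tilt rotation.

All profiles are C² in time with vanishing first and second derivatives at
the swing boundaries, so the IMU signals are continuous and the stance dwell
is exactly static.  The body angular rate is derived in closed form from the
quaternion composition, and the sensor acceleration from the analytic second
derivatives — the ground truth carries no discretisation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import quat
from .orientation import OrientationTrack
from .stride import DEFAULT_SAMPLING_RATE, StrideRecording, WorldFrame

__all__ = [
    "SyntheticStrideSpec",
    "GroundTruth",
    "make_ground_truth",
    "imu_from_ground_truth",
    "simulate_stride",
    "make_dataset",
    "DEFAULT_RANGES",
]


@dataclass
class SyntheticStrideSpec:
    """Parameters of one simulated stride.

    Defaults describe a healthy self-selected-pace stride recorded by a
    calibrated but imperfect shoe-mounted MEMS IMU: 1.25 m in 1.1 s, 12 cm
    peak sensor clearance, 40% of the stride spent in the stance dwell
    (split between both ends), white sensor noise of 0.01 g / 0.009 rad/s and
    a residual gyro bias of ~0.3 °/s per axis.
    """

    stride_length: float = 1.25  # m
    stride_duration: float = 1.1  # s
    max_clearance: float = 0.12  # m
    lateral_sway: float = 0.025  # m, peak medio-lateral excursion (zero net)
    stance_fraction: float = 0.4  # fraction of the stride in the dwell
    sampling_rate: float = DEFAULT_SAMPLING_RATE  # Hz
    accel_noise_sd: float = 0.01  # g
    gyro_noise_sd: float = 0.009  # rad/s
    gyro_bias: tuple = (0.005, -0.004, 0.006)  # rad/s, sensor frame
    accel_bias: tuple = (0.0, 0.0, 0.0)  # g, sensor frame (drift injection)
    initial_tilt: tuple = (5.0, -3.0)  # deg about x and z (mounting tilt)
    pitch_amplitude: float = 20.0  # deg, sagittal plantar/dorsiflexion
    wobble_amplitude: float = 0.0  # deg, optional frontal wobble
    clearance_dip: float = 0.8  # two-lobe shape parameter d in (1/2, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_duration <= 0:
            raise ValueError("stride_duration must be positive")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.5 < self.clearance_dip <= 1.0:
            raise ValueError("clearance_dip must lie in (1/2, 1]")


@dataclass
class GroundTruth:
    """Exact per-sample state of a simulated stride."""

    timestamps: np.ndarray  # (n,) s
    position: np.ndarray  # (n, 3) m, world frame, origin at first mid-stance
    velocity: np.ndarray  # (n, 3) m/s
    accel_world: np.ndarray  # (n, 3) m/s², gravity-free movement component
    orientation: OrientationTrack  # sensor-to-world quaternions
    stance_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def _minimum_jerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk position/velocity/acceleration profiles on τ ∈ [0, 1]."""
    p = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    v = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    a = 60 * tau - 180 * tau**2 + 120 * tau**3
    return p, v, a


def _clearance_profile(tau: np.ndarray, d: float) -> tuple[np.ndarray, ...]:
    """Two-lobe clearance shape f, f', f'' with unit-normalised peak.

    ``f(τ) = sin⁴(πτ)(1 + d cos 2πτ)``: for ``d > 1/2`` it has exactly two
    maxima (at ``sin²(πτ) = (1+d)/(3d)``) separated by a mid-swing dip, and
    f, f' and f'' all vanish at both swing boundaries, keeping the simulated
    acceleration continuous.
    """
    s, c = np.sin(np.pi * tau), np.cos(np.pi * tau)
    f = s**4 * (1.0 + d - 2.0 * d * s**2)
    fp = 4.0 * np.pi * s**3 * c * (1.0 + d - 3.0 * d * s**2)
    fpp = 4.0 * np.pi**2 * (
        (3.0 * s**2 * c**2 - s**4) * (1.0 + d - 3.0 * d * s**2)
        - 6.0 * d * s**4 * c**2
    )
    f_star = (1.0 + d) ** 3 / (27.0 * d**2)  # peak value
    return f / f_star, fp / f_star, fpp / f_star


def _pitch_profile(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal pitch shape u(τ) = -sin(2πτ) sin²(πτ) and its derivative."""
    s2, c2 = np.sin(2 * np.pi * tau), np.cos(2 * np.pi * tau)
    sp2 = np.sin(np.pi * tau) ** 2
    u = -s2 * sp2
    up = -(2.0 * np.pi * c2 * sp2 + np.pi * s2 * s2)
    return u, up


def _sway_profile(tau: np.ndarray) -> tuple[np.ndarray, ...]:
    """Medio-lateral sway w(τ) = sin(2πτ) sin²(πτ) with w', w''.

    Zero net displacement, zero value/velocity/acceleration at both ends.
    """
    s2, c2 = np.sin(2 * np.pi * tau), np.cos(2 * np.pi * tau)
    sp2 = np.sin(np.pi * tau) ** 2
    w = s2 * sp2
    wp = 2.0 * np.pi * c2 * sp2 + np.pi * s2 * s2
    wpp = 2.0 * np.pi**2 * s2 * (4.0 * c2 - 1.0)
    return w, wp, wpp


def make_ground_truth(spec: SyntheticStrideSpec) -> GroundTruth:
    """Exact trajectory and orientation of one simulated stride."""
    dt = 1.0 / spec.sampling_rate
    n = int(round(spec.stride_duration * spec.sampling_rate)) + 1
    t = np.arange(n) * dt
    T = t[-1]
    t1 = 0.5 * spec.stance_fraction * T  # swing start
    t2 = T - t1  # swing end
    t_sw = t2 - t1

    swing = (t > t1) & (t < t2)
    tau = np.zeros(n)
    tau[swing] = (t[swing] - t1) / t_sw
    tau[t >= t2] = 1.0

    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    acc = np.zeros((n, 3))

    p, v, a = _minimum_jerk(tau)
    pos[:, 0] = spec.stride_length * p
    vel[:, 0] = spec.stride_length * v / t_sw
    acc[:, 0] = spec.stride_length * a / t_sw**2

    f, fp, fpp = _clearance_profile(tau, spec.clearance_dip)
    pos[:, 1] = spec.max_clearance * f
    vel[:, 1] = spec.max_clearance * fp / t_sw
    acc[:, 1] = spec.max_clearance * fpp / t_sw**2

    w, wp, wpp = _sway_profile(tau)
    pos[:, 2] = spec.lateral_sway * w
    vel[:, 2] = spec.lateral_sway * wp / t_sw
    acc[:, 2] = spec.lateral_sway * wpp / t_sw**2
    # dwell samples keep the analytic zeros of the profiles
    pos[~swing & (t <= t1), :] = 0.0
    pos[t >= t2, 0] = spec.stride_length
    pos[t >= t2, 1] = 0.0
    pos[t >= t2, 2] = 0.0
    vel[~swing] = 0.0
    acc[~swing] = 0.0

    # orientation: q(t) = qz(θ(t)) ⊗ qx(φ(t)) ⊗ q_base
    tilt_x, tilt_z = np.radians(spec.initial_tilt)
    q_base = quat.multiply(
        quat.from_axis_angle((1.0, 0.0, 0.0), tilt_x),
        quat.from_axis_angle((0.0, 0.0, 1.0), tilt_z),
    )
    amp = np.radians(spec.pitch_amplitude)
    wob = np.radians(spec.wobble_amplitude)
    u, _ = _pitch_profile(tau)
    theta = amp * u
    phi = wob * np.sin(np.pi * tau) ** 3  # frontal wobble: C², zero-ended

    quats = np.empty((n, 4))
    for i in range(n):
        qz = quat.from_axis_angle((0.0, 0.0, 1.0), theta[i])
        qx = quat.from_axis_angle((1.0, 0.0, 0.0), phi[i])
        quats[i] = quat.multiply(quat.multiply(qz, qx), q_base)
    track = OrientationTrack(quats, np.zeros(n, dtype=bool))
    return GroundTruth(t, pos, vel, acc, track, stance_mask=~swing)


def imu_from_ground_truth(
    truth: GroundTruth, spec: SyntheticStrideSpec, frame: WorldFrame | None = None
) -> StrideRecording:
    """Sensor-frame IMU signals consistent with a ground-truth stride.

    The specific force in g is ``a_world/g_mag + (0, 1, 0)`` rotated into the
    sensor frame with the conjugate orientation; the body angular rate comes
    from the closed-form rate of the orientation composition.  Gaussian white
    noise and constant biases are then added from the spec's seed
    (deterministic per seed).
    """
    frame = frame or WorldFrame()
    n = len(truth.timestamps)
    t = truth.timestamps
    T = t[-1]
    t1 = 0.5 * spec.stance_fraction * T
    t2 = T - t1
    t_sw = t2 - t1
    swing = (t > t1) & (t < t2)
    tau = np.zeros(n)
    tau[swing] = (t[swing] - t1) / t_sw
    tau[t >= t2] = 1.0

    amp = np.radians(spec.pitch_amplitude)
    wob = np.radians(spec.wobble_amplitude)
    _, up = _pitch_profile(tau)
    theta_dot = np.where(swing, amp * up / t_sw, 0.0)
    phi = wob * np.sin(np.pi * tau) ** 3
    phi_dot = np.where(
        swing, wob * 3.0 * np.pi * np.sin(np.pi * tau) ** 2 * np.cos(np.pi * tau) / t_sw, 0.0
    )

    tilt_x, tilt_z = np.radians(spec.initial_tilt)
    q_base = quat.multiply(
        quat.from_axis_angle((1.0, 0.0, 0.0), tilt_x),
        quat.from_axis_angle((0.0, 0.0, 1.0), tilt_z),
    )
    Rb_T = quat.to_matrix(q_base).T

    gyro = np.empty((n, 3))
    accel = np.empty((n, 3))
    up_world = -frame.gravity_world  # unit specific force of gravity
    for i in range(n):
        # body rate of q = qz(θ) ⊗ qx(φ) ⊗ q_base:
        #   ω_s = R(q_base)ᵀ (R(qx(φ))ᵀ (0, 0, θ̇) + (φ̇, 0, 0))
        cx, sx = np.cos(phi[i]), np.sin(phi[i])
        w_mid = np.array(
            [phi_dot[i], sx * theta_dot[i], cx * theta_dot[i]]
        )  # Rx(φ)ᵀ(0,0,θ̇) + (φ̇,0,0)
        gyro[i] = Rb_T @ w_mid
        specific_g = truth.accel_world[i] / frame.g_mag + up_world
        accel[i] = quat.rotate(
            quat.conjugate(truth.orientation.quaternions[i]), specific_g
        )

    rng = np.random.default_rng(spec.seed)
    if spec.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, spec.gyro_noise_sd, (n, 3))
    if spec.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, spec.accel_noise_sd, (n, 3))
    gyro = gyro + np.asarray(spec.gyro_bias, dtype=float)
    accel = accel + np.asarray(spec.accel_bias, dtype=float)
    return StrideRecording(
        t, gyro, accel, delta_t=1.0 / spec.sampling_rate, i_ms_start=0, i_ms_end=n - 1
    )


def simulate_stride(spec: SyntheticStrideSpec) -> tuple[StrideRecording, GroundTruth]:
    """Convenience: ground truth plus matching IMU recording."""
    truth = make_ground_truth(spec)
    return imu_from_ground_truth(truth, spec), truth


#: Sampled ranges emulating the low / normal / high stride-length and
#: velocity conditions of the reference protocol.
DEFAULT_RANGES = {
    "stride_length": (0.5, 1.8),
    "stride_duration": (0.9, 1.4),
    "max_clearance": (0.08, 0.16),
    "lateral_sway": (0.01, 0.04),
    "initial_tilt_x": (-8.0, 8.0),
    "initial_tilt_z": (-8.0, 8.0),
}


def make_dataset(
    n_strides: int,
    ranges: dict | None = None,
    seed: int = 0,
    base_spec: SyntheticStrideSpec | None = None,
) -> list[tuple[SyntheticStrideSpec, StrideRecording, GroundTruth]]:
    """Reproducible stride collection spanning the requested parameter ranges.

    Stride length, duration, peak clearance and mounting tilt are drawn
    uniformly from ``ranges`` (defaults: :data:`DEFAULT_RANGES`); every other
    parameter comes from ``base_spec``.  Per-stride seeds are derived from
    ``seed``, so the collection is deterministic.
    """
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    base = base_spec or SyntheticStrideSpec()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_strides):
        spec = replace(
            base,
            stride_length=rng.uniform(*ranges["stride_length"]),
            stride_duration=rng.uniform(*ranges["stride_duration"]),
            max_clearance=rng.uniform(*ranges["max_clearance"]),
            lateral_sway=rng.uniform(*ranges["lateral_sway"]),
            initial_tilt=(
                rng.uniform(*ranges["initial_tilt_x"]),
                rng.uniform(*ranges["initial_tilt_z"]),
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = simulate_stride(spec)
        out.append((spec, rec, truth))
    return out
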