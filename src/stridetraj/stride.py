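"""Per-stride data model, mid-stance detection and initial inclination.

A stride is the segment between two consecutive mid-stance (MS) instants: the
quasi-stationary moments of the stance phase at which the foot velocity is
assumed to be zero (ZUPT).  All downstream estimators operate on the sample
range ``[i_ms_start, i_ms_end]`` of a :class:`StrideRecording` and are
re-initialised at every stride.

Units: gyroscope in rad/s, accelerometer in units of g (so a resting sensor
measures a specific force of magnitude 1 pointing to world ``+y``), time in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quat

__all__ = [
    "DEFAULT_SAMPLING_RATE",
    "StrideRecording",
    "WorldFrame",
    "detect_midstance",
    "initial_orientation",
]

#: Sampling rate of the Shimmer2R-class IMU the pipeline targets (Hz).
DEFAULT_SAMPLING_RATE = 102.4


@dataclass
class WorldFrame:
    """World coordinate frame: gravity points along ``-y``."""

    gravity_world: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.0, 0.0])
    )
    g_mag: float = 9.81  # m/s² per unit of g

    def __post_init__(self) -> None:
        self.gravity_world = np.asarray(self.gravity_world, dtype=float)
        if abs(np.linalg.norm(self.gravity_world) - 1.0) > 1e-9:
            raise ValueError("gravity_world must be a unit direction")


@dataclass
class StrideRecording:
    """Synchronised gyro/accel time series with mid-stance anchors.

    Parameters
    ----------
    timestamps : (n,) array, seconds, strictly increasing, uniform.
    gyro : (n, 3) array, rad/s, sensor frame.
    accel : (n, 3) array, units of g, sensor frame.
    delta_t : sampling interval in s (must match the timestamps).
    i_ms_start, i_ms_end : indices of two consecutive mid-stances; the stride
        used for integration spans ``[i_ms_start, i_ms_end]`` inclusive.
    """

    timestamps: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    delta_t: float = 1.0 / DEFAULT_SAMPLING_RATE
    i_ms_start: int = 0
    i_ms_end: int = -1

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        n = len(self.timestamps)
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError("gyro/accel must have shape (n, 3) matching timestamps")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        dt = np.diff(self.timestamps)
        if n > 1 and (np.any(dt <= 0) or np.max(np.abs(dt - self.delta_t)) > 1e-6):
            raise ValueError("timestamps must increase uniformly by delta_t")
        if self.i_ms_end < 0:
            self.i_ms_end += n
        if not 0 <= self.i_ms_start < self.i_ms_end <= n - 1:
            raise ValueError("mid-stance indices out of order or out of range")
        if self.i_ms_end - self.i_ms_start < 4:
            raise ValueError("need at least 3 samples between the mid-stances")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Stride duration T = t(ms+1) - t(ms) in seconds."""
        return (self.i_ms_end - self.i_ms_start) * self.delta_t

    def segment(self, arr: np.ndarray) -> np.ndarray:
        """View of a per-sample array restricted to ``[i_ms_start, i_ms_end]``."""
        return arr[self.i_ms_start : self.i_ms_end + 1]


def detect_midstance(gyro: np.ndarray, window: int = 10) -> int:
    """Index of minimal gyroscope energy: the mid-stance candidate.

    The energy of a window is the sum of squared gyro norms over ``window``
    consecutive samples; the returned index is the centre
    ``i + (window - 1) // 2`` of the minimising window, ties broken by the
    earliest window.  ``window=1`` degenerates to the global argmin of the
    per-sample squared norm.

    The default window of 10 samples ≈ 0.1 s at 102.4 Hz.
    """
    gyro = np.asarray(gyro, dtype=float)
    if gyro.ndim != 2 or gyro.shape[1] != 3:
        raise ValueError("gyro must have shape (n, 3)")
    n = len(gyro)
    if n == 0:
        raise ValueError("empty gyroscope sequence")
    if not 1 <= window <= n:
        raise ValueError("window must satisfy 1 <= window <= len(gyro)")
    sq = np.einsum("ij,ij->i", gyro, gyro)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    energy = csum[window:] - csum[:-window]  # energy of window starting at i
    i0 = int(np.argmin(energy))  # argmin returns the first minimiser
    return i0 + (window - 1) // 2


def initial_orientation(accel_at_ms) -> np.ndarray:
    """Initial sensor-to-world quaternion from a quasi-static accel sample.

    At mid-stance the accelerometer is assumed to measure pure specific force
    (magnitude ``||a||`` pointing opposite gravity).  Only inclination is
    observable without a magnetometer, parameterised by two tilt angles

    * ``alpha_z = atan2(-ax, ay)``   (about the transversal axis z),
    * ``alpha_x = atan2(az, sqrt(ax² + ay²))``  (about the anterior-posterior
      axis x),

    and the returned rotation is the inverse of the tilt,
    ``q = qx(-alpha_x) ⊗ qz(-alpha_z)``, so that ``rotate(q, accel_at_ms)``
    is exactly aligned with world ``+y``.  atan2 is used throughout to stay
    well-defined in every quadrant and as ``ay → 0``.
    """
    a = np.asarray(accel_at_ms, dtype=float)
    if np.linalg.norm(a) == 0.0:
        raise ValueError("zero-norm accelerometer sample at mid-stance")
    ax, ay, az = a
    alpha_z = np.arctan2(-ax, ay)
    alpha_x = np.arctan2(az, np.hypot(ax, ay))
    qx = quat.from_axis_angle((1.0, 0.0, 0.0), -alpha_x)
    qz = quat.from_axis_angle((0.0, 0.0, 1.0), -alpha_z)
    return quat.multiply(qx, qz)
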