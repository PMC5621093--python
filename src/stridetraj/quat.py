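"""Quaternion algebra for sensor-to-world rotation tracking.

Conventions used throughout the package:

* scalar-first component order ``(q0, q1, q2, q3) = (w, x, y, z)``;
* Hamilton product;
* quaternions encode **sensor-to-world** rotations, i.e. ``rotate(q, v)``
  maps a sensor-frame vector ``v`` into the world frame whose ``-y`` axis is
  gravity;
* ``q`` and ``-q`` encode the same rotation.  Canonicalisation (``q0 >= 0``)
  is applied only when comparing rotations, never during tracking.

Quaternions are plain ``numpy`` arrays of shape ``(4,)`` (float64); there is
deliberately no wrapper class so that per-sample filter loops stay cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IDENTITY",
    "multiply",
    "conjugate",
    "norm",
    "normalize",
    "canonical",
    "from_axis_angle",
    "to_matrix",
    "rotate",
    "derivative",
    "angle_between",
]

#: The identity rotation.
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

#: Unit-norm drift tolerated before a tracking step (guard against silent
#: de-normalisation bugs; every update renormalises anyway).
UNIT_TOL = 1e-6


def multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b``.

    Composes rotations so that ``rotate(multiply(a, b), v) ==
    rotate(a, rotate(b, v))``.  The product norm equals the product of the
    factor norms.
    """
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate; the inverse rotation for unit ``q``."""
    return np.array([q[0], -q[1], -q[2], -q[3]])


def norm(q: np.ndarray) -> float:
    return float(np.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3]))


def normalize(q: np.ndarray) -> np.ndarray:
    """Return ``q / ||q||``.

    Raises
    ------
    ValueError
        If ``q`` has (near-)zero norm.
    """
    n = norm(q)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-norm quaternion")
    return q / n


def canonical(q: np.ndarray) -> np.ndarray:
    """Flip sign so the scalar part is non-negative (comparison helper)."""
    if q[0] < 0.0:
        return -q
    if q[0] == 0.0:
        # break the q0 == 0 tie on the first non-zero vector component
        for c in q[1:]:
            if c != 0.0:
                return q if c > 0.0 else -q
    return q


def from_axis_angle(axis, angle: float) -> np.ndarray:
    """Unit quaternion rotating by ``angle`` (rad) about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    half = 0.5 * angle
    s = np.sin(half) / n
    return np.array([np.cos(half), s * axis[0], s * axis[1], s * axis[2]])


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix ``R(q)`` mapping sensor-frame to world-frame vectors.

    Requires unit input: raises ``ValueError`` if ``| ||q|| - 1 | > 1e-6``.
    The world-to-sensor transform is the transpose ``R(q).T``.
    """
    if abs(norm(q) - 1.0) > UNIT_TOL:
        raise ValueError("to_matrix requires a unit quaternion")
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotate(q: np.ndarray, v) -> np.ndarray:
    """Rotate a 3-vector by the unit quaternion ``q`` (sensor → world)."""
    w, x, y, z = q
    vx, vy, vz = v
    # q ⊗ (0, v) ⊗ q*  expanded (avoids building the matrix)
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    return np.array(
        [
            vx + w * tx + (y * tz - z * ty),
            vy + w * ty + (z * tx - x * tz),
            vz + w * tz + (x * ty - y * tx),
        ]
    )


def derivative(q_prev: np.ndarray, omega) -> np.ndarray:
    """Quaternion rate ``q̇ = ½ q ⊗ (0, ω)`` for body angular rate ``ω`` (rad/s)."""
    w, x, y, z = q_prev
    ox, oy, oz = omega
    return 0.5 * np.array(
        [
            -x * ox - y * oy - z * oz,
            w * ox + y * oz - z * oy,
            w * oy - x * oz + z * ox,
            w * oz + x * oy - y * ox,
        ]
    )


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Geodesic rotation angle (rad) between two unit quaternions.

    Sign-insensitive: ``angle_between(q, -q) == 0``.
    """
    d = abs(float(np.dot(a, b)))
    return 2.0 * np.arccos(min(1.0, d))
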