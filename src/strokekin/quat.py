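"""Quaternion and Euler-angle algebra.

Conventions used throughout the package:

* Quaternions are scalar-first ``[w, x, y, z]`` Hamilton quaternions.
* An orientation quaternion ``q`` maps body-frame vectors into the parent
  (earth) frame via the sandwich product ``q ⊗ [0, v] ⊗ q*``.
* Euler angles follow the intrinsic Z–X–Y sequence: yaw about the vertical
  z axis, then pitch about the (new) x axis, then roll about the (new) y
  axis.  This is the factorization under which the standard
  accelerometer-tilt formulas ``pitch = asin(ay/|a|)`` and
  ``roll = atan2(-ax, az)`` are exact.

All functions accept and return plain :class:`numpy.ndarray` objects; the
leading dimensions broadcast, so ``(N, 4)`` stacks of quaternions work
wherever a single quaternion does.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "EulerAngles",
    "quat_identity",
    "quat_normalize",
    "quat_multiply",
    "quat_conjugate",
    "rotate_vector",
    "quat_to_matrix",
    "quat_from_axis_angle",
    "quat_from_euler",
    "euler_from_quat",
    "orientation_distance",
]


class EulerAngles(NamedTuple):
    """Orientation as intrinsic Z–X–Y angles, radians.

    pitch: rotation about x, in [-pi/2, pi/2]
    roll:  rotation about y, in (-pi, pi]
    yaw:   rotation about z (heading, 0 = magnetic north), in (-pi, pi]
    """

    pitch: float
    roll: float
    yaw: float


def _check_finite(q: np.ndarray, name: str = "quaternion") -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"{name} must have last dimension 4, got {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError(f"{name} contains non-finite values")
    return q


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = _check_finite(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b (broadcasts over leading dimensions)."""
    a = _check_finite(a, "left factor")
    b = _check_finite(b, "right factor")
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = _check_finite(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotate_vector(q: np.ndarray, v: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Rotate body-frame vector(s) ``v`` into the parent frame by unit ``q``.

    Equivalent to the sandwich product ``q ⊗ [0, v] ⊗ q*`` but computed with
    the expanded rotation formula (no intermediate quaternions).
    """
    q = _check_finite(q)
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError(f"vector must have last dimension 3, got {v.shape}")
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > tol):
        raise ValueError("rotate_vector requires unit quaternions "
                         f"(|norm - 1| > {tol})")
    w = q[..., :1]
    qv = q[..., 1:]
    t = 2.0 * np.cross(qv, v)
    return v + w * t + np.cross(qv, t)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix R with R @ v_body = v_parent."""
    q = quat_normalize(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    row0 = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1)
    row1 = np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1)
    row2 = np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / n
    half = 0.5 * np.asarray(angle, dtype=float)
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )


def quat_from_euler(e: EulerAngles) -> np.ndarray:
    """Unit quaternion for intrinsic Z–X–Y angles (yaw, pitch, roll)."""
    pitch, roll, yaw = (float(e.pitch), float(e.roll), float(e.yaw))
    qz = quat_from_axis_angle([0.0, 0.0, 1.0], yaw)
    qx = quat_from_axis_angle([1.0, 0.0, 0.0], pitch)
    qy = quat_from_axis_angle([0.0, 1.0, 0.0], roll)
    return quat_normalize(quat_multiply(quat_multiply(qz, qx), qy))


def euler_from_quat(q: np.ndarray) -> EulerAngles:
    """Invert :func:`quat_from_euler` (away from pitch = ±90° gimbal lock)."""
    R = quat_to_matrix(q)
    # R = Rz(yaw) Rx(pitch) Ry(roll); third row = (-cp*sr, sp, cp*cr),
    # second column = (-sy*cp, cy*cp, sp).
    sp = np.clip(R[..., 2, 1], -1.0, 1.0)
    pitch = np.arcsin(sp)
    roll = np.arctan2(-R[..., 2, 0], R[..., 2, 2])
    yaw = np.arctan2(-R[..., 0, 1], R[..., 1, 1])
    return EulerAngles(pitch=pitch, roll=roll, yaw=yaw)


def orientation_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Geodesic angle (radians) between two orientations, in [0, pi].

    Respects the double cover: distance(q, -q) = 0.
    """
    a = quat_normalize(a)
    b = quat_normalize(b)
    dot = np.abs(np.sum(a * b, axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))
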