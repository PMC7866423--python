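"""Quaternion extended Kalman filter for 9-axis IMU orientation fusion.

State: 7-vector ``x = [q0, q1, q2, q3, bx, by, bz]`` — the sensor-to-earth
orientation quaternion plus a slowly varying gyroscope bias (rad/s).

Dynamics: the quaternion kinematic equation ``q̇ = ½ q ⊗ [0, ω − b]`` with
gyroscope reading ``ω`` as the control input, integrated first order at the
sample period T and renormalized.  The bias is a random walk.

Observation: the body-frame projections of two known earth-frame vectors,
the geomagnetic reference ``h = [hx, 0, hz]`` (x = magnetic north, z = up;
hz < 0 in the northern hemisphere where the field dips below horizontal)
and the static specific force ``(0, 0, +g)`` (a resting accelerometer with
z up reads +1 g).  The measurement vector is stacked ``[mag; accel]``.

Frames: earth coordinates (ECS) are x = magnetic north, z = up, y
completing the right-handed triad.  ``q`` maps sensor-frame vectors to ECS.

Initialization: while the wearer stands still facing north, pitch and roll
come from the accelerometer tilt and yaw from the tilt-compensated
magnetometer; the EKF then tracks from that attitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .quat import (
    EulerAngles,
    quat_from_euler,
    quat_multiply,
    quat_normalize,
    quat_to_matrix,
)

__all__ = [
    "GRAVITY",
    "DEG",
    "EkfConfig",
    "EkfState",
    "SensorStream",
    "initial_euler",
    "initial_state",
    "ekf_predict",
    "predict_measurement",
    "measurement_jacobian",
    "ekf_update",
    "run_fusion",
]

GRAVITY = 9.81  # m/s^2
DEG = np.pi / 180.0

# Table-style dynamic ranges used for sanity checks at ingest.
MAX_ACCEL = 18 * GRAVITY          # m/s^2
MAX_GYRO = 1200 * DEG             # rad/s
MAX_MAG = 1.9                     # gauss


@dataclass
class EkfConfig:
    """Filter tuning.  Defaults reflect a consumer MEMS 9-axis node at 400 Hz."""

    T: float = 1.0 / 400.0                     # sample period, s
    sigma_omega: float = 0.04 * DEG            # gyro white noise SD, rad/s
    sigma_omega_bias: float = 0.002 * DEG      # bias random walk, rad/s/sqrt(s)
    accel_noise_var: float = (0.02 * GRAVITY) ** 2   # (m/s^2)^2
    mag_noise_var: float = 0.005 ** 2          # gauss^2
    gravity_g: float = GRAVITY
    mag_reference: np.ndarray = field(
        default_factory=lambda: np.array([0.30, 0.0, -0.45])
    )
    init_quat_var: float = 1e-4
    init_bias_var: float = 1e-3

    def __post_init__(self) -> None:
        self.mag_reference = np.asarray(self.mag_reference, dtype=float)
        if self.mag_reference[1] != 0.0:
            raise ValueError("mag_reference must have zero east component")
        for name in ("sigma_omega", "sigma_omega_bias", "accel_noise_var",
                     "mag_noise_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EkfState:
    x: np.ndarray  # (7,)
    P: np.ndarray  # (7,7)

    @property
    def quat(self) -> np.ndarray:
        return self.x[:4]

    @property
    def gyro_bias(self) -> np.ndarray:
        return self.x[4:]

    def validate(self, tol: float = 1e-9) -> None:
        if abs(np.linalg.norm(self.x[:4]) - 1.0) > 1e-6:
            raise ValueError("state quaternion is not unit norm")
        if np.max(np.abs(self.P - self.P.T)) > tol:
            raise ValueError("covariance is not symmetric")
        if np.min(np.linalg.eigvalsh(self.P)) < -tol:
            raise ValueError("covariance is not positive semidefinite")


@dataclass
class SensorStream:
    """Time-ordered 9-axis samples from one body-mounted node, SI units.

    accel in m/s^2, gyro in rad/s, mag in gauss (CSV files store g and
    deg/s; conversion happens at ingest).
    """

    node_id: str
    t: np.ndarray        # (N,) seconds, strictly increasing
    accel: np.ndarray    # (N, 3)
    gyro: np.ndarray     # (N, 3)
    mag: np.ndarray      # (N, 3)
    sample_rate_hz: float = 400.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        n = len(self.t)
        for name in ("accel", "gyro", "mag"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            nominal = 1.0 / self.sample_rate_hz
            if np.any(np.abs(dt - nominal) > 0.1 * nominal):
                raise ValueError("sample spacing deviates more than 10% from "
                                 "the nominal period")

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# initialization


def initial_euler(accel: np.ndarray, mag: np.ndarray) -> EulerAngles:
    """Static attitude from one (averaged) accelerometer + magnetometer pair.

    pitch = asin(ay/|a|), roll = atan2(-ax, az); yaw from the
    tilt-compensated magnetometer.  Exact when the device is at rest so the
    accelerometer reads the body projection of (0, 0, +g).
    """
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    norm_a = np.linalg.norm(a)
    if norm_a == 0:
        raise ValueError("zero accelerometer vector")
    if not (0.5 * GRAVITY <= norm_a <= 1.5 * GRAVITY):
        warnings.warn(
            f"|accel| = {norm_a:.2f} m/s^2 is far from 1 g; device may not "
            "be static during initialization", stacklevel=2)
    pitch = np.arcsin(np.clip(a[1] / norm_a, -1.0, 1.0))
    roll = np.arctan2(-a[0], a[2])
    # De-tilt the magnetometer: apply Rx(pitch) @ Ry(roll).
    mxa = m[0] * np.cos(roll) + m[2] * np.sin(roll)
    mya = (m[0] * np.sin(roll) * np.sin(pitch) + m[1] * np.cos(pitch)
           - m[2] * np.cos(roll) * np.sin(pitch))
    if mxa == 0 and mya == 0:
        raise ValueError("zero horizontal magnetic field; yaw is undefined")
    yaw = np.arctan2(-mya, mxa)
    return EulerAngles(pitch=float(pitch), roll=float(roll), yaw=float(yaw))


def initial_state(e: EulerAngles, config: EkfConfig) -> EkfState:
    x = np.zeros(7)
    x[:4] = quat_from_euler(e)
    P = np.diag(
        [config.init_quat_var] * 4 + [config.init_bias_var] * 3
    ).astype(float)
    return EkfState(x=x, P=P)


# ---------------------------------------------------------------------------
# prediction


def _xi_matrix(q: np.ndarray) -> np.ndarray:
    """4x3 matrix Xi(q) with q ⊗ [0, w] = Xi(q) @ w."""
    w, x, y, z = q
    return np.array(
        [[-x, -y, -z],
         [w, -z, y],
         [z, w, -x],
         [-y, x, w]]
    )


def _omega_matrix(w3: np.ndarray) -> np.ndarray:
    """4x4 matrix Omega(w) with q ⊗ [0, w] = Omega(w) @ q (right mult.)."""
    wx, wy, wz = w3
    return np.array(
        [[0.0, -wx, -wy, -wz],
         [wx, 0.0, wz, -wy],
         [wy, -wz, 0.0, wx],
         [wz, wy, -wx, 0.0]]
    )


def _predict(x: np.ndarray, P: np.ndarray, gyro: np.ndarray,
             cfg: EkfConfig) -> tuple[np.ndarray, np.ndarray]:
    T = cfg.T
    q = x[:4]
    bias = x[4:]
    w = gyro - bias
    Xi = _xi_matrix(q)
    qdot = 0.5 * (Xi @ w)
    q_new = q + T * qdot
    q_new /= np.linalg.norm(q_new)

    # F = d(xdot)/dx from qdot = 0.5 q ⊗ [0, w - b].
    F = np.zeros((7, 7))
    F[:4, :4] = 0.5 * _omega_matrix(w)
    F[:4, 4:] = -0.5 * Xi
    Phi = np.eye(7) + F * T

    Q = np.zeros((7, 7))
    Q[:4, :4] = (0.5 * T * cfg.sigma_omega) ** 2 * (Xi @ Xi.T)
    Q[4:, 4:] = (cfg.sigma_omega_bias ** 2 * T) * np.eye(3)

    P_new = Phi @ P @ Phi.T + Q
    P_new = 0.5 * (P_new + P_new.T)
    x_new = x.copy()
    x_new[:4] = q_new
    return x_new, P_new


def ekf_predict(state: EkfState, gyro: np.ndarray, config: EkfConfig) -> EkfState:
    """Time update: integrate the bias-corrected rate over one period."""
    gyro = np.asarray(gyro, dtype=float)
    if not np.all(np.isfinite(gyro)):
        raise ValueError("gyro reading contains non-finite values")
    x, P = _predict(state.x, state.P, gyro, config)
    return EkfState(x=x, P=P)


# ---------------------------------------------------------------------------
# observation model


def _body_projection(q: np.ndarray, v_earth: np.ndarray) -> np.ndarray:
    """R(q)^T v — an earth vector seen in the sensor frame.

    Written as the homogeneous quadratic form in q so that
    :func:`_body_projection_jacobian` is its exact derivative.
    """
    w, x, y, z = q
    v0, v1, v2 = v_earth
    s = w * w - x * x - y * y - z * z
    d = 2.0 * (x * v0 + y * v1 + z * v2)
    tw = 2.0 * w
    return np.array([
        s * v0 + d * x - tw * (y * v2 - z * v1),
        s * v1 + d * y - tw * (z * v0 - x * v2),
        s * v2 + d * z - tw * (x * v1 - y * v0),
    ])


def _body_projection_jacobian(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """3x4 Jacobian of R(q)^T v with respect to q (unnormalized)."""
    w, x, y, z = q
    v0, v1, v2 = v
    dot = x * v0 + y * v1 + z * v2
    # columns: d/dw = 2(w v - qv x v); d/dqv = -2 v qv' + 2 qv v' +
    # 2(qv.v) I + 2w [v]x
    return np.array([
        [2 * (w * v0 - (y * v2 - z * v1)),
         2 * dot, 2 * (x * v1 - v0 * y - w * v2), 2 * (x * v2 - v0 * z + w * v1)],
        [2 * (w * v1 - (z * v0 - x * v2)),
         2 * (y * v0 - v1 * x + w * v2), 2 * dot, 2 * (y * v2 - v1 * z - w * v0)],
        [2 * (w * v2 - (x * v1 - y * v0)),
         2 * (z * v0 - v2 * x - w * v1), 2 * (z * v1 - v2 * y + w * v0), 2 * dot],
    ])


def predict_measurement(q: np.ndarray, config: EkfConfig) -> np.ndarray:
    """Expected [mag(3); accel(3)] for orientation q: body-frame projections
    of the magnetic reference and of (0, 0, +g)."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-6:
        raise ValueError("predict_measurement requires a unit quaternion")
    g_vec = np.array([0.0, 0.0, config.gravity_g])
    return np.concatenate(
        [_body_projection(q, config.mag_reference), _body_projection(q, g_vec)]
    )


def measurement_jacobian(q: np.ndarray, config: EkfConfig) -> np.ndarray:
    """Analytic 6x7 Jacobian of the measurement; bias columns are zero."""
    q = np.asarray(q, dtype=float)
    H = np.zeros((6, 7))
    H[:3, :4] = _body_projection_jacobian(q, config.mag_reference)
    H[3:, :4] = _body_projection_jacobian(
        q, np.array([0.0, 0.0, config.gravity_g]))
    return H


def _update(x: np.ndarray, P: np.ndarray, z: np.ndarray,
            cfg: EkfConfig, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q = x[:4]
    g_vec = np.array([0.0, 0.0, cfg.gravity_g])
    h = np.concatenate(
        [_body_projection(q, cfg.mag_reference), _body_projection(q, g_vec)]
    )
    H = np.zeros((6, 7))
    H[:3, :4] = _body_projection_jacobian(q, cfg.mag_reference)
    H[3:, :4] = _body_projection_jacobian(q, g_vec)

    PHt = P @ H.T
    S = H @ PHt + R
    try:
        K = np.linalg.solve(S, PHt.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "innovation covariance is numerically singular") from exc
    if not np.all(np.isfinite(K)):
        raise np.linalg.LinAlgError(
            "innovation covariance is numerically singular")
    x_new = x + K @ (z - h)
    P_new = (np.eye(7) - K @ H) @ P
    P_new = 0.5 * (P_new + P_new.T)
    x_new[:4] /= np.linalg.norm(x_new[:4])
    return x_new, P_new


def ekf_update(state: EkfState, z: np.ndarray, config: EkfConfig) -> EkfState:
    """Measurement update with z = [mag (gauss); accel (m/s^2)]."""
    z = np.asarray(z, dtype=float)
    if z.shape != (6,) or not np.all(np.isfinite(z)):
        raise ValueError("measurement must be a finite 6-vector")
    R = np.diag([config.mag_noise_var] * 3 + [config.accel_noise_var] * 3)
    x, P = _update(state.x, state.P, z, config, R)
    return EkfState(x=x, P=P)


# ---------------------------------------------------------------------------
# whole-stream driver


def run_fusion(
    stream: SensorStream,
    config: EkfConfig | None = None,
    init_duration_s: float = 1.0,
    return_state: bool = False,
):
    """Fuse one node's stream into a per-sample orientation series seq(t).

    The first ``init_duration_s`` of data (assumed near-static: the wearer
    holds the calibration pose) is averaged to seed pitch/roll/yaw; the EKF
    then runs predict+update over every sample.  Returns an (N, 4) array of
    unit quaternions (sign-continuous), and optionally the final state.
    """
    if config is None:
        config = EkfConfig(T=1.0 / stream.sample_rate_hz)
    n = len(stream)
    if n == 0:
        raise ValueError("empty sensor stream")
    if np.all(stream.mag == 0):
        raise ValueError("all-zero magnetometer stream; yaw unobservable")

    n_init = max(1, min(n, int(round(init_duration_s * stream.sample_rate_hz))))
    e0 = initial_euler(stream.accel[:n_init].mean(axis=0),
                       stream.mag[:n_init].mean(axis=0))
    state = initial_state(e0, config)

    R = np.diag([config.mag_noise_var] * 3 + [config.accel_noise_var] * 3)
    x, P = state.x, state.P
    out = np.empty((n, 4))
    prev = x[:4].copy()
    z = np.empty(6)
    for i in range(n):
        if i > 0:
            # gyro[i-1] is the rate over [t_{i-1}, t_i]
            x, P = _predict(x, P, stream.gyro[i - 1], config)
        z[:3] = stream.mag[i]
        z[3:] = stream.accel[i]
        x, P = _update(x, P, z, config, R)
        q = x[:4]
        if q @ prev < 0:          # hemisphere continuity for readability
            q = -q
            x[:4] = q
        out[i] = q
        prev = q
    if return_state:
        return out, EkfState(x=x, P=P)
    return out
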