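"""Magnetometer ellipsoid calibration and low-pass filtering.

Hard-iron (additive offset) and soft-iron (linear) distortion make raw
magnetometer readings lie on a displaced, skewed ellipsoid instead of a
sphere of radius equal to the local field strength.  ``fit_ellipsoid``
recovers the correction ``corrected = A @ (raw - b)`` by algebraic
least-squares fitting of a general quadric, scaled so the mean field
magnitude is preserved.

Angular-velocity and acceleration channels are smoothed with a zero-phase
second-order Butterworth low-pass (default cutoff 100 Hz at 400 Hz
sampling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["MagCalibration", "FilterSpec", "fit_ellipsoid",
           "apply_mag_calibration", "lowpass"]


@dataclass
class MagCalibration:
    """Correction ``corrected = soft_iron_matrix @ (raw - hard_iron_offset)``."""

    hard_iron_offset: np.ndarray  # (3,) gauss
    soft_iron_matrix: np.ndarray  # (3,3) symmetric positive-definite
    mean_field_gauss: float = 1.0

    @classmethod
    def identity(cls) -> "MagCalibration":
        return cls(np.zeros(3), np.eye(3), 1.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "offset": self.hard_iron_offset.tolist(),
                "matrix": self.soft_iron_matrix.tolist(),
                "mean_field_gauss": self.mean_field_gauss,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MagCalibration":
        d = json.loads(text)
        return cls(
            np.asarray(d["offset"], dtype=float),
            np.asarray(d["matrix"], dtype=float),
            float(d["mean_field_gauss"]),
        )


@dataclass
class FilterSpec:
    order: int = 2
    cutoff_hz: float = 100.0
    sample_rate_hz: float = 400.0

    def __post_init__(self) -> None:
        if not self.cutoff_hz < self.sample_rate_hz / 2:
            raise ValueError("cutoff_hz must be below the Nyquist frequency")


def fit_ellipsoid(mag_samples: np.ndarray) -> MagCalibration:
    """Least-squares general-quadric ellipsoid fit of raw magnetometer samples.

    Parameters
    ----------
    mag_samples : (N, 3) array of raw readings, N >= 10, spanning at least
        three non-coplanar directions around the ellipsoid.

    Returns
    -------
    MagCalibration mapping the fitted ellipsoid onto a sphere whose radius
    equals the mean corrected field magnitude of the input samples.
    """
    m = np.asarray(mag_samples, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("mag_samples must be an (N, 3) array")
    if m.shape[0] < 10:
        raise ValueError("need at least 10 magnetometer samples")
    centered = m - m.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(m).max())) < 3:
        raise ValueError("degenerate sample cloud: directions are coplanar "
                         "(rank < 3); rotate the sensor about all axes")

    x, y, z = m.T
    # General quadric v' Q v + 2 b' v + c = 0 with 10 algebraic parameters
    # [A, B, C, D, E, F, G, H, I, J] multiplying
    # [x^2, y^2, z^2, 2xy, 2xz, 2yz, 2x, 2y, 2z, 1].
    D = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z,
         2 * x, 2 * y, 2 * z, np.ones_like(x)]
    )
    # Unit-norm constraint on the parameter vector: smallest singular vector.
    _, _, vt = np.linalg.svd(D, full_matrices=False)
    p = vt[-1]
    Q = np.array(
        [[p[0], p[3], p[4]],
         [p[3], p[1], p[5]],
         [p[4], p[5], p[2]]]
    )
    bvec = p[6:9]
    c = p[9]

    eigvals = np.linalg.eigvalsh(Q)
    if np.any(eigvals <= 0):
        if np.all(eigvals < 0):  # overall sign is arbitrary
            Q, bvec, c = -Q, -bvec, -c
            eigvals = -eigvals[::-1]
        else:
            raise ValueError("fitted quadric is not an ellipsoid "
                             "(indefinite quadratic form)")

    center = -np.linalg.solve(Q, bvec)
    # (v - center)' Q (v - center) = k  on the fitted surface.
    k = center @ Q @ center - c
    if k <= 0:
        raise ValueError("fitted quadric is not an ellipsoid (empty surface)")
    # Symmetric square root of Q/k maps the ellipsoid to the unit sphere.
    w, V = np.linalg.eigh(Q / k)
    A = V @ np.diag(np.sqrt(w)) @ V.T

    # Rescale so the mean corrected magnitude equals the raw mean magnitude,
    # i.e. the calibration does not invent a field strength.
    corrected = (m - center) @ A.T
    mean_field = float(np.mean(np.linalg.norm(m - center, axis=1)))
    unit_mean = float(np.mean(np.linalg.norm(corrected, axis=1)))
    A = A * (mean_field / unit_mean)
    return MagCalibration(center, A, mean_field)


def apply_mag_calibration(raw: np.ndarray, cal: MagCalibration) -> np.ndarray:
    """Apply ``A @ (raw - b)``; broadcasts over leading dimensions."""
    raw = np.asarray(raw, dtype=float)
    return (raw - cal.hard_iron_offset) @ cal.soft_iron_matrix.T


def lowpass(series: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase second-order Butterworth low-pass along axis 0.

    Forward-backward application (``filtfilt``) doubles the attenuation and
    cancels phase lag, so filtered joint-angle timing is unbiased.
    """
    if spec is None:
        spec = FilterSpec()
    series = np.asarray(series, dtype=float)
    if series.shape[0] <= 3 * spec.order:
        raise ValueError(
            f"series length {series.shape[0]} too short for order-{spec.order} "
            "zero-phase filtering (need > 3x order)"
        )
    sos = signal.butter(
        spec.order, spec.cutoff_hz, btype="low", fs=spec.sample_rate_hz,
        output="sos",
    )
    return signal.sosfiltfilt(sos, series, axis=0)
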