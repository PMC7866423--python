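"""1-D wavelet scattering transform for short joint-angle windows.

The transform cascades wavelet-modulus operations and finishes each path
with low-pass averaging:

    S0 x            = x * phi_J
    S1 x(j1)        = |x * psi_j1| * phi_J
    S2 x(j1, j2)    = ||x * psi_j1| * psi_j2| * phi_J ,  j2 > j1

with a dyadic Morlet filter bank psi_j centered at xi * 2^-j and a Gaussian
low-pass phi_J dilated by 2^J.  Only frequency-decreasing paths (j2 > j1)
carry energy and are kept.  The bank is normalized so its Littlewood–Paley
sum is at most 1, which makes the transform nonexpansive and keeps the
per-order energies bounded by the signal energy.

Coefficients are computed at full resolution (no subsampling — windows are
tiny); feature vectors average each scattering path over time, yielding the
translation-stable descriptors fed to the phase classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScatteringBank",
    "ScatteringCoeffs",
    "build_bank",
    "scatter",
    "sliding_windows",
    "feature_matrix",
    "feature_names",
]


@dataclass
class ScatteringBank:
    n: int                       # signal length the bank is built for
    J: int                       # number of dyadic scales
    xi: float                    # mother-wavelet center frequency, rad/sample
    slope: float                 # bandwidth ratio sigma/xi
    psi_hat: np.ndarray          # (J, n) one-sided Morlet responses
    phi_hat: np.ndarray          # (n,) Gaussian low-pass, DC gain 1

    @property
    def n_paths(self) -> int:
        return 1 + self.J + self.J * (self.J - 1) // 2


@dataclass
class ScatteringCoeffs:
    S0: np.ndarray                              # (n,)
    S1: dict[int, np.ndarray]                   # j1 -> (n,)
    S2: dict[tuple[int, int], np.ndarray]       # (j1, j2) -> (n,), j2 > j1

    def energy_per_order(self) -> tuple[float, float, float]:
        e0 = float(np.sum(self.S0 ** 2))
        e1 = float(sum(np.sum(v ** 2) for v in self.S1.values()))
        e2 = float(sum(np.sum(v ** 2) for v in self.S2.values()))
        return e0, e1, e2

    def feature_vector(self) -> np.ndarray:
        """Time-averaged coefficient per path, fixed order: S0, S1 by j1,
        S2 by (j1, j2) lexicographic."""
        feats = [self.S0.mean()]
        feats += [self.S1[j].mean() for j in sorted(self.S1)]
        feats += [self.S2[k].mean() for k in sorted(self.S2)]
        return np.array(feats)


def _morlet_hat(omega: np.ndarray, xi: float, sigma: float) -> np.ndarray:
    """Frequency response of a zero-mean (corrected) Morlet wavelet."""
    main = np.exp(-((omega - xi) ** 2) / (2 * sigma ** 2))
    corr = np.exp(-(xi ** 2) / (2 * sigma ** 2)) * np.exp(
        -(omega ** 2) / (2 * sigma ** 2))
    return main - corr


def build_bank(n: int, J: int = 3, xi: float = 2.356194490192345,
               slope: float = 0.4) -> ScatteringBank:
    """Dyadic Morlet bank on an n-point FFT grid.

    xi defaults to 3*pi/4 (the customary first-octave center); sigma_j =
    slope * xi_j gives roughly octave bandwidth.  The whole bank is scaled
    so that the Littlewood–Paley sum |phi|^2 + sum_j |psi_j|^2 <= 1.
    """
    if n < 2 ** J:
        raise ValueError(f"signal length {n} shorter than 2^J = {2 ** J}")
    omega = 2 * np.pi * np.fft.fftfreq(n)        # (-pi, pi]
    psi = np.zeros((J, n))
    for j in range(J):
        xi_j = xi * 2.0 ** (-j)
        sigma_j = slope * xi_j
        resp = _morlet_hat(omega, xi_j, sigma_j)
        resp[omega < 0] = 0.0                    # analytic (one-sided)
        psi[j] = resp
    sigma_phi = slope * xi * 2.0 ** (-J)
    phi = np.exp(-(omega ** 2) / (2 * sigma_phi ** 2))
    phi = phi / phi[0]                           # DC gain exactly 1

    lp = phi ** 2 + np.sum(psi ** 2, axis=0)
    peak = float(np.max(lp))
    if peak > 1.0:
        # scale the wavelets only; phi must keep unit DC gain
        excess = np.sqrt(np.maximum(lp - phi ** 2, 0.0))
        limit = np.sqrt(np.maximum(1.0 - phi ** 2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(excess > 0, limit / excess, 1.0)
        psi = psi * np.minimum(1.0, np.min(scale[excess > 1e-12]))
    return ScatteringBank(n=n, J=J, xi=xi, slope=slope,
                          psi_hat=psi, phi_hat=phi)


def _conv(x_hat: np.ndarray, filt_hat: np.ndarray) -> np.ndarray:
    return np.fft.ifft(x_hat * filt_hat)


def scatter(x: np.ndarray, bank: ScatteringBank, m: int = 2) -> ScatteringCoeffs:
    """Scattering coefficients of one window (length must equal bank.n)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (bank.n,):
        raise ValueError(f"window length {x.shape} != bank length {bank.n}")
    if not 0 <= m <= 2:
        raise ValueError("scattering order m must be 0, 1 or 2")
    x_hat = np.fft.fft(x)
    S0 = np.real(_conv(x_hat, bank.phi_hat))
    S1: dict[int, np.ndarray] = {}
    S2: dict[tuple[int, int], np.ndarray] = {}
    if m >= 1:
        for j1 in range(bank.J):
            u1 = np.abs(_conv(x_hat, bank.psi_hat[j1]))
            u1_hat = np.fft.fft(u1)
            S1[j1] = np.real(_conv(u1_hat, bank.phi_hat))
            if m >= 2:
                for j2 in range(j1 + 1, bank.J):
                    u2 = np.abs(_conv(u1_hat, bank.psi_hat[j2]))
                    S2[(j1, j2)] = np.real(
                        _conv(np.fft.fft(u2), bank.phi_hat))
    return ScatteringCoeffs(S0=S0, S1=S1, S2=S2)


def energy_capture_fraction(x: np.ndarray, bank: ScatteringBank,
                            m: int = 2) -> float:
    """Fraction of window energy captured by scattering orders 0..m."""
    x = np.asarray(x, dtype=float)
    total = float(np.sum(x ** 2))
    if total == 0:
        return 1.0
    return float(sum(scatter(x, bank, m=m).energy_per_order()) / total)


def sliding_windows(series: np.ndarray, size: int = 20,
                    overlap: float = 0.5) -> np.ndarray:
    """Fixed-size windows with fractional overlap; trailing partial dropped.

    Returns an (n_windows, size) view-copy; n_windows =
    floor((L - size)/step) + 1 for L >= size, else 0.
    """
    if size < 2:
        raise ValueError("window size must be >= 2")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    x = np.asarray(series)
    step = max(1, int(round(size * (1.0 - overlap))))
    L = len(x)
    if L < size:
        return np.empty((0, size), dtype=x.dtype)
    starts = np.arange(0, L - size + 1, step)
    return np.stack([x[s:s + size] for s in starts])


def window_starts(length: int, size: int = 20, overlap: float = 0.5) -> np.ndarray:
    step = max(1, int(round(size * (1.0 - overlap))))
    if length < size:
        return np.empty(0, dtype=int)
    return np.arange(0, length - size + 1, step)


def _pad_reflect(w: np.ndarray, n: int) -> np.ndarray:
    if len(w) == n:
        return w
    total = n - len(w)
    left = total // 2
    return np.pad(w, (left, total - left), mode="reflect")


def feature_names(bank: ScatteringBank,
                  channels: tuple[str, ...]) -> list[str]:
    names = []
    for ch in channels:
        names.append(f"{ch}:S0")
        names += [f"{ch}:S1:{j}" for j in range(bank.J)]
        names += [f"{ch}:S2:{j1}-{j2}"
                  for j1 in range(bank.J) for j2 in range(j1 + 1, bank.J)]
    return names


def feature_matrix(channels: dict[str, np.ndarray], bank: ScatteringBank,
                   size: int = 20, overlap: float = 0.5, m: int = 2,
                   channel_order: tuple[str, ...] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Window every channel at common start indices and scatter each window.

    Windows shorter than the bank length are reflection-padded.  Returns
    ``(features, starts)`` with one row per window; per row the scattering
    feature vectors of the channels are concatenated in ``channel_order``
    (default: sorted key order).
    """
    order = tuple(sorted(channels)) if channel_order is None else channel_order
    lengths = {len(channels[c]) for c in order}
    if len(lengths) != 1:
        raise ValueError("channels must have equal length")
    L = lengths.pop()
    starts = window_starts(L, size, overlap)
    if len(starts) == 0:
        return np.empty((0, len(order) * bank.n_paths)), starts
    rows = np.empty((len(starts), len(order) * bank.n_paths))
    for i, s in enumerate(starts):
        feats = [
            scatter(_pad_reflect(channels[c][s:s + size], bank.n),
                    bank, m=m).feature_vector()
            for c in order
        ]
        rows[i] = np.concatenate(feats)
    return rows, starts
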