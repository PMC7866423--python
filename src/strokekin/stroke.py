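"""Stroke-cycle detection and kinematic/phase-duration statistics.

A stroke cycle on one side is delimited by successive prominent peaks of
that side's shoulder-flexion channel (the channel with the largest range of
motion, hence the most robust landmark).  Within each cycle the four
sub-phases follow the fixed order entry → pull → exit → recovery; entry,
pull and exit together form the propulsion (water-contact) part of the
cycle and recovery is the aerial return.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .body import JointAngleSeries

__all__ = [
    "PHASES",
    "SIDES",
    "CycleSet",
    "PhaseSegmentation",
    "detect_cycles",
    "time_normalize",
    "kinematic_summary",
    "mean_cycle_curve",
    "symmetry_correlation",
    "phase_durations",
]

PHASES = ("entry", "pull", "exit", "recovery")
SIDES = ("left", "right")
UNLABELED = -1


@dataclass
class CycleSet:
    """Per-side [start, end) sample-index intervals, one per full cycle."""

    side: str
    intervals: list[tuple[int, int]]
    sample_rate_hz: float

    def __post_init__(self) -> None:
        prev_end = -1
        for a, b in self.intervals:
            if a < prev_end or b <= a:
                raise ValueError("cycle intervals must be increasing and "
                                 "non-overlapping")
            prev_end = b

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class PhaseSegmentation:
    """Per-sample integer phase codes per side.

    Codes index into :data:`PHASES`; ``UNLABELED`` (-1) marks samples
    outside any scripted/annotated cycle (e.g. the static lead-in).
    """

    sample_rate_hz: float
    labels: dict[str, np.ndarray]  # side -> (N,) int array

    def __len__(self) -> int:
        return len(next(iter(self.labels.values())))


def detect_cycles(series: JointAngleSeries, side: str,
                  min_prominence_deg: float = 20.0,
                  min_period_s: float = 0.5) -> CycleSet:
    """Delimit stroke cycles by peaks of the side's SF channel."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    fs = series.sample_rate_hz
    x = series.channels["SFl" if side == "left" else "SFr"]
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of data to detect cycles")
    peaks, _ = sps.find_peaks(
        x, prominence=min_prominence_deg,
        distance=max(1, int(round(min_period_s * fs))),
    )
    if len(peaks) < 2:
        warnings.warn("fewer than 2 prominent peaks; no complete cycles",
                      stacklevel=2)
        return CycleSet(side=side, intervals=[], sample_rate_hz=fs)
    intervals = [(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])]
    return CycleSet(side=side, intervals=intervals, sample_rate_hz=fs)


def time_normalize(x: np.ndarray, cycle: tuple[int, int],
                   n_points: int = 101) -> np.ndarray:
    """Resample one cycle onto a 0–100% grid by linear interpolation."""
    a, b = cycle
    seg = np.asarray(x, dtype=float)[a:b]
    if len(seg) < 4:
        raise ValueError("cycle too short to normalize (need >= 4 samples)")
    src = np.linspace(0.0, 1.0, len(seg))
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, seg)


def mean_cycle_curve(series: JointAngleSeries, channel: str,
                     cycles: CycleSet, n_points: int = 101) -> np.ndarray:
    """Time-normalized group mean curve of one channel over a cycle set."""
    if len(cycles) == 0:
        raise ValueError("no cycles to average")
    curves = [time_normalize(series.channels[channel], c, n_points)
              for c in cycles.intervals]
    return np.mean(curves, axis=0)


def kinematic_summary(series: JointAngleSeries,
                      cycles_by_side: dict[str, CycleSet]) -> dict:
    """Per-cycle MAX/MIN/ROM/MEAN, then mean ± SD across cycles.

    Returns ``{side: {channel: {stat: {"mean": .., "sd": ..}}}}`` mirroring
    the usual summary-table layout (SD uses the n-1 denominator; SD is 0
    for a single cycle).
    """
    out: dict = {}
    for side, cycles in cycles_by_side.items():
        if len(cycles) == 0:
            raise ValueError(f"no cycles for side {side!r}")
        out[side] = {}
        for ch, x in series.channels.items():
            per_cycle = {"MAX": [], "MIN": [], "ROM": [], "MEAN": []}
            for a, b in cycles.intervals:
                seg = x[a:b]
                hi, lo = float(seg.max()), float(seg.min())
                per_cycle["MAX"].append(hi)
                per_cycle["MIN"].append(lo)
                per_cycle["ROM"].append(hi - lo)
                per_cycle["MEAN"].append(float(seg.mean()))
            out[side][ch] = {
                stat: {
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                }
                for stat, v in per_cycle.items()
            }
    return out


DEFAULT_PAIRING = (("EFl", "EFr"), ("EFr", "EFl"), ("SFl", "SFr"), ("SFr", "SFl"))


def symmetry_correlation(
    left_curves: dict[str, np.ndarray],
    right_curves: dict[str, np.ndarray],
    pairing: tuple[tuple[str, str], ...] = DEFAULT_PAIRING,
) -> dict[str, float]:
    """Pearson correlation between contralateral mean cycle curves.

    ``left_curves``/``right_curves`` hold the time-normalized mean curve of
    each channel over left-side and right-side cycles respectively; each
    pair compares a channel during the left-side stroke with its mirror
    during the right-side stroke.  Zero-variance curves yield NaN.
    """
    out = {}
    for lch, rch in pairing:
        a, b = left_curves[lch], right_curves[rch]
        if len(a) != len(b):
            raise ValueError("curves must have equal length")
        if np.std(a) == 0 or np.std(b) == 0:
            out[f"{lch}:{rch}"] = float("nan")
            continue
        out[f"{lch}:{rch}"] = float(spstats.pearsonr(a, b)[0])
    return out


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal labels as (code, start, end) with end exclusive."""
    runs = []
    n = len(labels)
    i = 0
    while i < n:
        j = i + 1
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((int(labels[i]), i, j))
        i = j
    return runs


def phase_durations(seg: PhaseSegmentation, fs: float | None = None) -> dict:
    """Sub-phase duration statistics and propulsion ratios per side.

    Complete cycles are entry→pull→exit→recovery run sequences.  Returns,
    per side, mean ± SD duration (ms) of each sub-phase plus two ratio
    readings: ``propulsion_fraction`` = (entry+pull+exit)/cycle and
    ``propulsion_over_recovery`` = (entry+pull+exit)/recovery, with a pooled
    (both sides) propulsion fraction under the key ``pooled``.
    """
    if fs is None:
        fs = seg.sample_rate_hz
    ms_per_sample = 1000.0 / fs
    report: dict = {}
    pooled_prop: list[float] = []
    for side, labels in seg.labels.items():
        runs = [r for r in _runs(labels) if r[0] != UNLABELED]
        cycles = []
        i = 0
        while i + 4 <= len(runs):
            window = runs[i:i + 4]
            contiguous = all(window[k][2] == window[k + 1][1]
                             for k in range(3))
            if [r[0] for r in window] == [0, 1, 2, 3] and contiguous:
                cycles.append(window)
                i += 4
            else:
                i += 1
        if not cycles:
            # No complete entry→pull→exit→recovery sequence: fall back to
            # sample-level accounting (e.g. a stream labeled entirely as
            # recovery has a propulsion fraction of exactly 0).
            labeled = labels[labels != UNLABELED]
            if len(labeled) == 0:
                raise ValueError(f"no labeled samples on side {side!r}")
            prop_n = int(np.isin(labeled, [0, 1, 2]).sum())
            rec_n = int((labeled == 3).sum())
            frac = prop_n / len(labeled)
            report[side] = {
                "n_cycles": 0,
                "durations_ms": {
                    p: {
                        "mean": float(np.mean(v)) if (v := [
                            (r[2] - r[1]) * ms_per_sample
                            for r in runs if r[0] == code]) else 0.0,
                        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    }
                    for code, p in enumerate(PHASES)
                },
                "propulsion_fraction": frac,
                "propulsion_over_recovery": (prop_n / rec_n if rec_n else 0.0),
            }
            pooled_prop.append(frac)
            continue
        durations = {p: [] for p in PHASES}
        fracs, ratios = [], []
        for window in cycles:
            lens = [(r[2] - r[1]) * ms_per_sample for r in window]
            for p, d in zip(PHASES, lens):
                durations[p].append(d)
            prop = sum(lens[:3])
            total = sum(lens)
            fracs.append(prop / total)
            ratios.append(prop / lens[3])
        report[side] = {
            "n_cycles": len(cycles),
            "durations_ms": {
                p: {
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                }
                for p, v in durations.items()
            },
            "propulsion_fraction": float(np.mean(fracs)),
            "propulsion_over_recovery": float(np.mean(ratios)),
        }
        pooled_prop.extend(fracs)
    report["pooled"] = {"propulsion_fraction": float(np.mean(pooled_prop))}
    return report
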