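"""File formats and report writing.

Formats (all plain text):

* IMU CSV, one file per node: header ``t,ax,ay,az,gx,gy,gz,mx,my,mz`` with
  t in seconds, accel in g, gyro in deg/s, mag in gauss.  In memory the
  package works in SI units (m/s^2, rad/s, gauss); conversion happens here.
* Quaternion CSV: ``t,q0,q1,q2,q3`` (scalar-first, unit norm).
* Joint-angle CSV: ``t,EFl,EFr,SFl,SFr`` in degrees.
* Phase-label CSV: ``t,side,phase`` with phase names or ``-`` for unlabeled.
* Magnetometer calibration: JSON ``{offset, matrix, mean_field_gauss}``.
* Run configuration: YAML.

Reports are JSON with a header recording the package version, seed and a
hash of the configuration that produced them, so a run is attributable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .body import JointAngleSeries
from .fusion import DEG, GRAVITY, SensorStream
from .preprocess import MagCalibration
from .stroke import PHASES, UNLABELED, PhaseSegmentation

__all__ = [
    "read_imu_csv", "write_imu_csv",
    "read_quat_csv", "write_quat_csv",
    "read_angles_csv", "write_angles_csv",
    "read_phases_csv", "write_phases_csv",
    "load_calibration", "save_calibration",
    "load_config", "save_config", "config_hash",
    "write_reports",
]

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]


def read_imu_csv(path: str | Path, node_id: str | None = None,
                 sample_rate_hz: float | None = None) -> SensorStream:
    """Read one node's IMU CSV, converting g → m/s² and deg/s → rad/s."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[IMU_COLUMNS].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: unparseable values at data row "
                         f"{int(np.flatnonzero(bad)[0])}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"{path}: non-monotonic timestamp at data row {row}")
    if sample_rate_hz is None:
        sample_rate_hz = (1.0 / float(np.median(np.diff(t)))
                          if len(t) > 1 else 400.0)
    return SensorStream(
        node_id=node_id or path.stem,
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float) * GRAVITY,
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float) * DEG,
        mag=df[["mx", "my", "mz"]].to_numpy(dtype=float),
        sample_rate_hz=sample_rate_hz,
    )


def write_imu_csv(stream: SensorStream, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([
            stream.t,
            stream.accel / GRAVITY,
            stream.gyro / DEG,
            stream.mag,
        ]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_quat_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (df["t"].to_numpy(dtype=float),
            df[["q0", "q1", "q2", "q3"]].to_numpy(dtype=float))


def write_quat_csv(t: np.ndarray, quats: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(np.column_stack([t, quats]),
                      columns=["t", "q0", "q1", "q2", "q3"])
    df.to_csv(path, index=False, float_format="%.9g")


def read_angles_csv(path: str | Path) -> JointAngleSeries:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 400.0
    return JointAngleSeries(
        sample_rate_hz=fs,
        channels={c: df[c].to_numpy(dtype=float)
                  for c in JointAngleSeries.CHANNELS},
    )


def write_angles_csv(series: JointAngleSeries, path: str | Path) -> None:
    n = len(series)
    t = np.arange(n) / series.sample_rate_hz
    cols = {"t": t}
    cols.update({c: series.channels[c] for c in JointAngleSeries.CHANNELS})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def write_phases_csv(seg: PhaseSegmentation, path: str | Path) -> None:
    rows = []
    for side, labels in seg.labels.items():
        t = np.arange(len(labels)) / seg.sample_rate_hz
        names = np.where(labels == UNLABELED, "-",
                         np.array(PHASES, dtype=object)[
                             np.clip(labels, 0, len(PHASES) - 1)])
        rows.append(pd.DataFrame({"t": t, "side": side, "phase": names}))
    pd.concat(rows).to_csv(path, index=False, float_format="%.9g")


def read_phases_csv(path: str | Path) -> PhaseSegmentation:
    df = pd.read_csv(path)
    code = {p: i for i, p in enumerate(PHASES)}
    labels = {}
    fs = 400.0
    for side, grp in df.groupby("side"):
        t = grp["t"].to_numpy(dtype=float)
        if len(t) > 1:
            fs = 1.0 / float(np.median(np.diff(t)))
        labels[side] = np.array(
            [code.get(p, UNLABELED) for p in grp["phase"]], dtype=int)
    return PhaseSegmentation(sample_rate_hz=fs, labels=labels)


def save_calibration(cal: MagCalibration, path: str | Path) -> None:
    Path(path).write_text(cal.to_json())


def load_calibration(path: str | Path) -> MagCalibration:
    return MagCalibration.from_json(Path(path).read_text())


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_reports(results: dict, outdir: str | Path,
                  config: dict | None = None, seed: int | None = None) -> list[Path]:
    """Write the analysis reports (kinematic summary, phase durations,
    classifier comparison) as JSON files under ``outdir``."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = {
        "package": f"strokekin {__version__}",
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }
    written = []
    for name in ("kinematic_summary", "symmetry", "phase_durations",
                 "classifier_report"):
        if name not in results or results[name] is None:
            continue
        path = outdir / f"{name}.json"
        payload = {"provenance": header, name: _jsonable(results[name])}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(path)
    return written
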