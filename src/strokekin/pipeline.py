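"""End-to-end pipeline: streams → orientations → joint angles → features →
phase classification.

This module wires the stages together the way the CLI (and the tests) run
them: per-node EKF fusion, sensor-to-segment alignment from the static
calibration hold, vectorized joint-angle reconstruction, stroke metrics,
20-sample scattering windows at 50% overlap (optionally on a decimated
series; by default windows are cut at the acquisition rate), and the
five-classifier comparison with windows pooled across sides (the channel
order of right-side windows is mirrored so "ipsilateral first" holds for
both, keeping the pooled four-class problem well posed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import classify
from .body import BodyModel, JointAngleSeries
from .fusion import EkfConfig, SensorStream, run_fusion
from .preprocess import FilterSpec, MagCalibration, apply_mag_calibration, lowpass
from .quat import quat_multiply, quat_normalize, quat_conjugate, rotate_vector
from .scattering import ScatteringBank, build_bank, feature_matrix
from .simulate import DatasetBundle, StrokeParams, make_dataset
from .stroke import (
    SIDES,
    UNLABELED,
    CycleSet,
    PhaseSegmentation,
    detect_cycles,
    kinematic_summary,
    mean_cycle_curve,
    phase_durations,
    symmetry_correlation,
)

__all__ = ["PipelineResult", "fuse_streams", "reconstruct_joint_angles",
           "decimate_series", "build_labeled_windows", "run_pipeline"]

CHANNEL_ORDER = {"left": ("EFl", "EFr", "SFl", "SFr"),
                 "right": ("EFr", "EFl", "SFr", "SFl")}


@dataclass
class PipelineResult:
    est_seq: dict[str, np.ndarray]
    sbq: dict[str, np.ndarray]
    joint_angles: JointAngleSeries
    cycles: dict[str, CycleSet]
    summary: dict
    symmetry: dict[str, float]
    durations: dict
    windows: classify.LabeledWindows | None
    reports: dict[str, classify.ClassifierReport] | None

    @property
    def best_accuracy(self) -> float:
        if not self.reports:
            raise ValueError("pipeline was run without classification")
        return max(r.accuracy for r in self.reports.values())


def fuse_streams(
    streams: dict[str, SensorStream],
    config: EkfConfig | None = None,
    mag_cal: dict[str, MagCalibration] | None = None,
    filter_spec: FilterSpec | None = None,
    init_duration_s: float = 1.0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Low-pass, calibrate and fuse each node; return (seq series, sbq).

    The mounting quaternion sbq per node is the mean estimated orientation
    over the initialization window (the static calibration hold), held
    constant afterwards.
    """
    est: dict[str, np.ndarray] = {}
    sbq: dict[str, np.ndarray] = {}
    for node, stream in streams.items():
        accel = stream.accel
        gyro = stream.gyro
        mag = stream.mag
        if filter_spec is not None:
            accel = lowpass(accel, filter_spec)
            gyro = lowpass(gyro, filter_spec)
        if mag_cal and node in mag_cal:
            mag = apply_mag_calibration(mag, mag_cal[node])
        clean = SensorStream(node_id=node, t=stream.t, accel=accel,
                             gyro=gyro, mag=mag,
                             sample_rate_hz=stream.sample_rate_hz)
        cfg = config or EkfConfig(T=1.0 / stream.sample_rate_hz)
        q = run_fusion(clean, cfg, init_duration_s=init_duration_s)
        est[node] = q
        n_init = max(1, int(round(init_duration_s * stream.sample_rate_hz)))
        q0 = q[:n_init].mean(axis=0)
        sbq[node] = quat_normalize(q0)
    return est, sbq


def reconstruct_joint_angles(
    model: BodyModel,
    est_seq: dict[str, np.ndarray],
    sbq: dict[str, np.ndarray],
    sample_rate_hz: float,
) -> JointAngleSeries:
    """Vectorized elbow/shoulder angle series from fused orientations.

    Equivalent to running forward kinematics per frame and measuring the
    interior joint angles, but computed directly on the segment direction
    vectors for speed.
    """
    node_of = {name: seg.sensor_node for name, seg in model.segments.items()}

    def beq(seg_name: str) -> np.ndarray:
        node = node_of[seg_name]
        if node is None or node not in est_seq:
            raise ValueError(f"segment {seg_name!r} has no fused sensor node")
        return quat_normalize(
            quat_multiply(est_seq[node],
                          quat_conjugate(sbq[node])[None, :]))

    def direction(seg_name: str) -> np.ndarray:
        q = beq(seg_name)
        d = model.segments[seg_name].d
        return rotate_vector(q, np.tile(d, (len(q), 1)))

    def angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        cosang = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    chest_dir = direction("chest")
    out = {}
    for suffix in ("l", "r"):
        ua_dir = direction(f"upper_arm_{suffix}")
        fa_dir = direction(f"forearm_{suffix}")
        out[f"EF{suffix}"] = angle(-ua_dir, fa_dir)
        out[f"SF{suffix}"] = angle(-chest_dir, ua_dir)
    return JointAngleSeries(sample_rate_hz=sample_rate_hz, channels=out)


def decimate_series(series: JointAngleSeries, factor: int = 4) -> JointAngleSeries:
    """Anti-aliased decimation of every channel (default 400 → 100 Hz)."""
    if factor == 1:
        return series
    channels = {c: sps.decimate(x, factor, ftype="fir", zero_phase=True)
                for c, x in series.channels.items()}
    return JointAngleSeries(sample_rate_hz=series.sample_rate_hz / factor,
                            channels=channels)


def build_labeled_windows(
    series: JointAngleSeries,
    phases: PhaseSegmentation,
    bank: ScatteringBank,
    size: int = 20,
    overlap: float = 0.5,
    m: int = 2,
    decim_factor: int = 1,
) -> classify.LabeledWindows:
    """Window, scatter and label the series, pooled across sides.

    Phase labels are decimated by simple subsampling to match the series
    rate.  Windows overlapping unlabeled samples (lead-in, tail) are
    dropped.  Right-side windows use the mirrored channel order.
    """
    parts = []
    n = len(series)
    for side in SIDES:
        order = CHANNEL_ORDER[side]
        feats, starts = feature_matrix(
            series.channels, bank, size=size, overlap=overlap, m=m,
            channel_order=order)
        labels = phases.labels[side][::decim_factor][:n]
        covered = np.array(
            [np.all(labels[s:s + size] != UNLABELED) for s in starts])
        if not np.any(covered):
            continue
        part = classify.label_windows(
            feats[covered], starts[covered], size, labels, side)
        parts.append(part)
    if not parts:
        raise ValueError("no fully labeled windows")
    return classify.concat_windows(parts)


def elbow_validation(seed: int = 0, duration_s: float = 60.0,
                     freq_hz: float = 1.0) -> tuple[float, int]:
    """Single-joint validation: Pearson r between the scripted and the
    reconstructed elbow flexion/extension angle.

    A periodic elbow movement spanning the typical stroke range is scripted,
    synthesized into noisy IMU streams, fused and reconstructed; returns
    ``(r, n_samples)`` over the active (post-lead-in) part of the recording.
    """
    from scipy.stats import pearsonr

    from .body import default_model
    from .simulate import (
        elbow_flexion_trajectory,
        simulate_imu,
        trajectory_to_orientations,
    )

    params = StrokeParams(seed=seed)
    series = elbow_flexion_trajectory(duration_s=duration_s, freq_hz=freq_hz)
    model = default_model(params.subject_height_m)
    beq = trajectory_to_orientations(series, model)
    rng = np.random.default_rng(seed)
    streams = {}
    for name, seg in model.segments.items():
        if seg.sensor_node is not None and name in beq:
            streams[seg.sensor_node] = simulate_imu(
                beq[name], params, seg.sensor_node, rng)
    est, sbq = fuse_streams(streams, init_duration_s=1.0)
    angles = reconstruct_joint_angles(model, est, sbq, params.sample_rate_hz)
    active = np.arange(len(series)) / params.sample_rate_hz >= 2.0
    r, _ = pearsonr(angles.channels["EFl"][active],
                    series.channels["EFl"][active])
    return float(r), int(active.sum())


def run_pipeline(
    params: StrokeParams | None = None,
    bundle: DatasetBundle | None = None,
    ekf_config: EkfConfig | None = None,
    filter_spec: FilterSpec | None = None,
    window_size: int = 20,
    overlap: float = 0.5,
    decim_factor: int = 1,
    bank_n: int = 32,
    J: int = 3,
    scattering_order: int = 2,
    classify_phases: bool = True,
    seed: int = 0,
) -> PipelineResult:
    """Simulate (or accept) a dataset and run every pipeline stage on it."""
    if bundle is None:
        bundle = make_dataset(params or StrokeParams(seed=seed))
    fs = bundle.params.sample_rate_hz
    init_s = bundle.params.lead_in_s * 2 / 3
    est_seq, sbq = fuse_streams(
        bundle.streams, ekf_config, filter_spec=filter_spec,
        init_duration_s=init_s)
    angles = reconstruct_joint_angles(bundle.model, est_seq, sbq, fs)

    cycles = {side: detect_cycles(angles, side) for side in SIDES}
    summary = kinematic_summary(angles, cycles)
    left_curves = {c: mean_cycle_curve(angles, c, cycles["left"])
                   for c in JointAngleSeries.CHANNELS}
    right_curves = {c: mean_cycle_curve(angles, c, cycles["right"])
                    for c in JointAngleSeries.CHANNELS}
    symmetry = symmetry_correlation(left_curves, right_curves)
    durations = phase_durations(bundle.truth_phases)

    windows = reports = None
    if classify_phases:
        decimated = decimate_series(angles, decim_factor)
        bank = build_bank(bank_n, J=J)
        windows = build_labeled_windows(
            decimated, bundle.truth_phases, bank, size=window_size,
            overlap=overlap, m=scattering_order, decim_factor=decim_factor)
        reports = classify.compare_classifiers(windows, seed=seed)

    return PipelineResult(
        est_seq=est_seq, sbq=sbq, joint_angles=angles, cycles=cycles,
        summary=summary, symmetry=symmetry, durations=durations,
        windows=windows, reports=reports,
    )
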