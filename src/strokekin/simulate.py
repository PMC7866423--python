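"""Synthetic kayak-stroke generator with ground truth.

Produces, from one seeded parameter set: scripted elbow/shoulder joint-angle
trajectories with exact per-sample phase labels, the corresponding rigid
body segment orientations, and realistic 9-axis IMU streams for each
body-mounted node — so the whole pipeline (calibration, fusion,
reconstruction, metrics, classification) is testable without recordings.

The motion model is a periodic four-phase stroke per side (entry, pull,
exit, recovery) with per-cycle duration jitter; joint angles within each
phase are cosine-eased between template keypoints scaled to the configured
per-channel extremes, so each cycle hits its MIN and MAX exactly.  The
recording starts with a static calibration hold (the N-pose: arms down,
facing north) followed by a short eased transition into the cycle, exactly
the way a wearer initializes a real session.

The arm motion is planar (sagittal flexion/extension): shoulder flexion
rotates the upper arm about the body's left-right axis and elbow flexion
folds the forearm in the same plane; the trunk is held static.  IMU signals
are derived by inverting the fusion model: gyro from quaternion finite
differences plus bias and white noise, accel as the body projection of
gravity plus noise (no translational acceleration by default), mag as the
body projection of the geomagnetic reference, optionally distorted by
hard/soft-iron terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .body import BodyModel, JointAngleSeries, default_model
from .fusion import DEG, GRAVITY, SensorStream
from .quat import (
    quat_conjugate,
    quat_from_axis_angle,
    quat_identity,
    quat_multiply,
    quat_normalize,
    rotate_vector,
)
from .stroke import PHASES, SIDES, UNLABELED, PhaseSegmentation

__all__ = ["StrokeParams", "DatasetBundle", "gen_joint_trajectory",
           "trajectory_to_orientations", "simulate_imu", "make_dataset"]


# Per-side default phase durations, mean ± SD in ms (a representative
# sprint-kayak subject; propulsion ≈ 62% of the cycle).
DEFAULT_DURATIONS = {
    "left": {"entry": (124.0, 13.0), "pull": (396.0, 28.0),
             "exit": (116.0, 15.0), "recovery": (388.0, 22.0)},
    "right": {"entry": (144.0, 15.0), "pull": (299.0, 23.0),
              "exit": (95.0, 16.0), "recovery": (371.0, 28.0)},
}

# Per-channel joint-angle extremes (MIN, MAX) in degrees, each taken from
# the side on which that arm is the drawing arm.
DEFAULT_EXTREMES = {
    "EFl": (145.2, 167.0),
    "SFl": (25.8, 99.9),
    "EFr": (138.0, 174.9),
    "SFr": (21.5, 110.0),
}

# Keypoint templates per channel kind: per phase, a list of
# (fraction-into-phase, fraction-of-[MIN, MAX]) anchors; cosine easing
# between anchors, so per-cycle extremes land exactly on MIN/MAX.
# The elbow is most extended at the catch (entry->pull boundary) and folds
# through the pull; shoulder flexion bottoms at the end of the pull and
# peaks late in the recovery swing.
_TEMPLATE = {
    "EF": {
        "entry": [(0.0, 0.65), (1.0, 1.0)],
        "pull": [(0.0, 1.0), (1.0, 0.0)],
        "exit": [(0.0, 0.0), (1.0, 0.10)],
        "recovery": [(0.0, 0.10), (1.0, 0.65)],
    },
    "SF": {
        "entry": [(0.0, 0.60), (1.0, 0.45)],
        "pull": [(0.0, 0.45), (1.0, 0.0)],
        "exit": [(0.0, 0.0), (1.0, 0.25)],
        "recovery": [(0.0, 0.25), (0.6, 1.0), (1.0, 0.60)],
    },
}


@dataclass
class StrokeParams:
    """Study conditions for one synthetic recording."""

    phase_durations_ms: dict = field(
        default_factory=lambda: {s: dict(DEFAULT_DURATIONS[s]) for s in SIDES})
    extremes_deg: dict = field(
        default_factory=lambda: dict(DEFAULT_EXTREMES))
    asymmetry: float = 0.0            # 0 = mirror-symmetric curve shapes
    jitter_scale: float = 1.0         # multiplies the duration SDs
    n_cycles: int = 30                # per side
    sample_rate_hz: float = 400.0
    lead_in_s: float = 1.5            # static N-pose hold for initialization
    transition_s: float = 0.5         # eased N-pose -> stroke posture
    gyro_noise_deg_s: float = 0.04
    accel_noise_g: float = 0.02
    mag_noise_gauss: float = 0.005
    gyro_bias_deg_s: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    mount_misalignment_deg: float = 5.0   # random fixed sensor mounting tilt
    hard_iron_gauss: np.ndarray = field(default_factory=lambda: np.zeros(3))
    soft_iron: np.ndarray = field(default_factory=lambda: np.eye(3))
    subject_height_m: float = 1.76
    seed: int = 0

    def __post_init__(self) -> None:
        self.gyro_bias_deg_s = np.asarray(self.gyro_bias_deg_s, dtype=float)
        self.hard_iron_gauss = np.asarray(self.hard_iron_gauss, dtype=float)
        self.soft_iron = np.asarray(self.soft_iron, dtype=float)
        for side in SIDES:
            for p, (m, sd) in self.phase_durations_ms[side].items():
                if m <= 0:
                    raise ValueError(f"{side}/{p} duration must be positive")
        for ch, (lo, hi) in self.extremes_deg.items():
            if not (0.0 <= lo < hi <= 180.0):
                raise ValueError(f"extremes for {ch} must satisfy "
                                 "0 <= MIN < MAX <= 180")


def _ease(f: np.ndarray) -> np.ndarray:
    """Cosine easing on [0, 1]: smooth (zero-slope) at both ends."""
    return 0.5 - 0.5 * np.cos(np.pi * f)


def _warp(v: float, alpha: float) -> float:
    """Monotone shape distortion of a keypoint fraction, fixing 0 and 1."""
    return (1.0 - alpha) * v + alpha * v * v


def _phase_keypoints(kind: str, phase: str, alpha: float) -> list[tuple[float, float]]:
    pts = _TEMPLATE[kind][phase]
    if alpha == 0.0:
        return pts
    out = []
    for i, (f, v) in enumerate(pts):
        vv = _warp(v, alpha)
        if i not in (0, len(pts) - 1):
            f = min(0.95, max(0.05, f + 0.25 * alpha * (0.5 - f)))
        out.append((f, vv))
    # keep cycle extremes reachable: restore any anchor at 0 or 1
    out = [(f, (0.0 if abs(pts[i][1]) < 1e-12 else
                1.0 if abs(pts[i][1] - 1.0) < 1e-12 else v))
           for i, (f, v) in enumerate(out)]
    return out


def _eval_keypoints(pts: list[tuple[float, float]], f: np.ndarray) -> np.ndarray:
    """Piecewise cosine-eased interpolation of (fraction, value) anchors."""
    vals = np.empty_like(f)
    for (f0, v0), (f1, v1) in zip(pts[:-1], pts[1:]):
        sel = (f >= f0) & (f <= f1)
        if not np.any(sel):
            continue
        local = (f[sel] - f0) / max(f1 - f0, 1e-12)
        vals[sel] = v0 + (v1 - v0) * _ease(local)
    return vals


def _side_phase_script(params: StrokeParams, side: str,
                       rng: np.random.Generator,
                       t_offset: float) -> list[tuple[str, float, float]]:
    """[(phase, t_start, t_end), ...] for n_cycles cycles of one side."""
    script = []
    t = params.lead_in_s + params.transition_s + t_offset
    durs = params.phase_durations_ms[side]
    for _ in range(params.n_cycles):
        for phase in PHASES:
            mean, sd = durs[phase]
            d = rng.normal(mean, sd * params.jitter_scale)
            d = max(d, 0.25 * mean) / 1000.0
            script.append((phase, t, t + d))
            t += d
    return script


def gen_joint_trajectory(
    params: StrokeParams,
    rng: np.random.Generator | None = None,
) -> tuple[JointAngleSeries, PhaseSegmentation]:
    """Scripted four-channel joint-angle series with exact phase labels.

    The left-arm channels (EFl, SFl) follow the left-side phase script and
    the right-arm channels the right-side script; the right script starts
    half a propulsion later so strokes alternate.  Samples in the lead-in /
    transition (and after a side's last scripted cycle) are UNLABELED.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    left_prop = sum(params.phase_durations_ms["left"][p][0]
                    for p in ("entry", "pull", "exit")) / 1000.0
    scripts = {
        "left": _side_phase_script(params, "left", rng, 0.0),
        "right": _side_phase_script(params, "right", rng, left_prop),
    }
    t_end = min(scripts["left"][-1][2], scripts["right"][-1][2])
    n = int(np.floor(t_end * fs))
    t = np.arange(n) / fs

    channels = {c: np.empty(n) for c in JointAngleSeries.CHANNELS}
    labels = {s: np.full(n, UNLABELED, dtype=int) for s in SIDES}

    npose = {"EF": 180.0, "SF": 0.0}
    for side, suffix in (("left", "l"), ("right", "r")):
        alpha = 0.0 if side == "left" else params.asymmetry
        for kind in ("EF", "SF"):
            ch = f"{kind}{suffix}"
            lo, hi = params.extremes_deg[ch]
            x = np.empty(n)
            script = scripts[side]
            t_start = script[0][1]
            # static N-pose then eased transition to the first scripted value
            first_pts = _phase_keypoints(kind, script[0][0], alpha)
            start_val = lo + (hi - lo) * first_pts[0][1]
            pre = t < (t_start - params.transition_s)
            x[pre] = npose[kind]
            trans = (~pre) & (t < t_start)
            if np.any(trans):
                f = ((t[trans] - (t_start - params.transition_s))
                     / params.transition_s)
                x[trans] = npose[kind] + (start_val - npose[kind]) * _ease(f)
            for phase, a, b in script:
                sel = (t >= a) & (t < b)
                if not np.any(sel):
                    continue
                f = (t[sel] - a) / (b - a)
                frac = _eval_keypoints(_phase_keypoints(kind, phase, alpha), f)
                x[sel] = lo + (hi - lo) * frac
            post = t >= script[-1][2]
            x[post] = start_val
            channels[ch] = x
        phase_code = {p: i for i, p in enumerate(PHASES)}
        lab = labels[side]
        for phase, a, b in scripts[side]:
            if b > t_end + 0.5 / fs:
                continue  # truncated by the crop: leave unlabeled
            sel = (t >= a) & (t < b)
            lab[sel] = phase_code[phase]

    series = JointAngleSeries(sample_rate_hz=fs, channels=channels)
    seg = PhaseSegmentation(sample_rate_hz=fs, labels=labels)
    return series, seg


def trajectory_to_orientations(
    series: JointAngleSeries, model: BodyModel,
) -> dict[str, np.ndarray]:
    """Segment orientation truth (beq per frame) realizing the joint angles.

    Planar inverse kinematics: trunk segments stay at identity; each upper
    arm rotates about the body y axis by -SF (flexion forward) and the
    forearm by -(SF + 180° - EF), which reproduces the interior-angle
    conventions of the reconstruction exactly.
    """
    n = len(series)
    ident = np.tile(quat_identity(), (n, 1))
    out: dict[str, np.ndarray] = {}
    for name in ("pelvis", "waist", "chest"):
        if name in model.segments:
            out[name] = ident.copy()
    y_axis = np.array([0.0, 1.0, 0.0])
    for suffix in ("l", "r"):
        sf = np.radians(series.channels[f"SF{suffix}"])
        ef = np.radians(series.channels[f"EF{suffix}"])
        if np.any(series.channels[f"EF{suffix}"] < 0) or np.any(
                series.channels[f"EF{suffix}"] > 180):
            raise ValueError("elbow angle outside [0, 180] deg")
        ua = quat_from_axis_angle(y_axis, -sf)
        fa = quat_from_axis_angle(y_axis, -(sf + np.pi - ef))
        out[f"upper_arm_{suffix}"] = ua
        out[f"forearm_{suffix}"] = fa
    return out


def _angular_rate_body(q: np.ndarray, fs: float) -> np.ndarray:
    """Body-frame angular velocity from quaternion finite differences."""
    n = len(q)
    w = np.zeros((n, 3))
    dq = quat_multiply(quat_conjugate(q[:-1]), q[1:])
    dq = np.where(dq[:, :1] < 0, -dq, dq)
    vec = dq[:, 1:]
    norm = np.linalg.norm(vec, axis=1)
    angle = 2.0 * np.arctan2(norm, dq[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(norm[:, None] > 1e-15, vec / norm[:, None], 0.0)
    w[:-1] = axis * angle[:, None] * fs
    if n > 1:
        w[-1] = w[-2]
    return w


def simulate_imu(
    orientations: np.ndarray,
    params: StrokeParams,
    node_id: str,
    rng: np.random.Generator,
    mag_reference: np.ndarray = (0.30, 0.0, -0.45),
) -> SensorStream:
    """Synthesize one node's 9-axis stream from its true seq(t) series.

    gyro = body rate from quaternion differencing + bias + white noise;
    accel = body projection of (0, 0, +g) + white noise (no translational
    acceleration); mag = soft/hard-iron distortion of the body-projected
    reference field + white noise.  All outputs in SI units.
    """
    q = np.asarray(orientations, dtype=float)
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("orientation series must be unit quaternions")
    fs = params.sample_rate_hz
    n = len(q)
    mag_reference = np.asarray(mag_reference, dtype=float)

    gyro = _angular_rate_body(q, fs)
    gyro = gyro + params.gyro_bias_deg_s * DEG
    gyro = gyro + rng.normal(0.0, params.gyro_noise_deg_s * DEG, (n, 3))

    qc = quat_conjugate(q)
    g_vec = np.array([0.0, 0.0, GRAVITY])
    accel = rotate_vector(qc, np.tile(g_vec, (n, 1)))
    accel = accel + rng.normal(0.0, params.accel_noise_g * GRAVITY, (n, 3))

    field_b = rotate_vector(qc, np.tile(mag_reference, (n, 1)))
    mag = field_b @ params.soft_iron.T + params.hard_iron_gauss
    mag = mag + rng.normal(0.0, params.mag_noise_gauss, (n, 3))

    t = np.arange(n) / fs
    return SensorStream(node_id=node_id, t=t, accel=accel, gyro=gyro,
                        mag=mag, sample_rate_hz=fs)


def elbow_flexion_trajectory(
    duration_s: float = 60.0,
    freq_hz: float = 1.0,
    fs: float = 400.0,
    ef_range: tuple[float, float] = (145.2, 167.0),
    sf_deg: float = 40.0,
    lead_in_s: float = 1.5,
    transition_s: float = 0.5,
) -> JointAngleSeries:
    """Scripted periodic elbow flexion/extension for validation runs.

    Both elbows oscillate sinusoidally across ``ef_range`` at ``freq_hz``
    while the shoulders hold a fixed flexion, after the usual static N-pose
    lead-in and an eased transition.  Mirrors the bench comparison of a
    single-joint movement against a reference system.
    """
    n = int(round((lead_in_s + transition_s + duration_s) * fs))
    t = np.arange(n) / fs
    t0 = lead_in_s + transition_s
    lo, hi = ef_range
    mid, amp = 0.5 * (lo + hi), 0.5 * (hi - lo)
    ef = np.full(n, 180.0)
    sf = np.zeros(n)
    trans = (t >= lead_in_s) & (t < t0)
    f = _ease((t[trans] - lead_in_s) / transition_s)
    ef[trans] = 180.0 + (hi - 180.0) * f
    sf[trans] = sf_deg * f
    active = t >= t0
    ef[active] = mid + amp * np.cos(2 * np.pi * freq_hz * (t[active] - t0))
    sf[active] = sf_deg
    return JointAngleSeries(
        sample_rate_hz=fs,
        channels={"EFl": ef.copy(), "EFr": ef.copy(),
                  "SFl": sf.copy(), "SFr": sf.copy()},
    )


@dataclass
class DatasetBundle:
    params: StrokeParams
    model: BodyModel
    streams: dict[str, SensorStream]
    truth_seq: dict[str, np.ndarray]        # node -> (N, 4) sensor-to-earth
    truth_beq: dict[str, np.ndarray]        # segment -> (N, 4) body-to-earth
    truth_angles: JointAngleSeries
    truth_phases: PhaseSegmentation
    mounts: dict[str, np.ndarray]           # node -> fixed mounting quat


def make_dataset(params: StrokeParams,
                 model: BodyModel | None = None) -> DatasetBundle:
    """One seeded call yielding streams, truth orientations, angles, phases.

    Randomness is split into independent sub-streams (duration jitter,
    sensor mounting, per-node measurement noise), so e.g. two seeds share an
    identical ground-truth script when jitter is zero.
    """
    if model is None:
        model = default_model(params.subject_height_m)
    root = np.random.default_rng(params.seed)
    seeds = root.spawn(4)
    rng_jitter, rng_mount, rng_noise, _ = seeds

    series, seg = gen_joint_trajectory(params, rng_jitter)
    beq = trajectory_to_orientations(series, model)

    instrumented = [s for s in model.segments.values()
                    if s.sensor_node is not None]
    streams: dict[str, SensorStream] = {}
    truth_seq: dict[str, np.ndarray] = {}
    mounts: dict[str, np.ndarray] = {}
    for seg_rec in instrumented:
        node = seg_rec.sensor_node
        tilt = params.mount_misalignment_deg * DEG
        if tilt > 0:
            axis = rng_mount.normal(size=3)
            axis /= np.linalg.norm(axis)
            mount = quat_from_axis_angle(axis, rng_mount.uniform(0, tilt))
        else:
            mount = quat_identity()
        mounts[node] = mount
        seq = quat_normalize(
            quat_multiply(beq[seg_rec.name], np.tile(mount, (len(series), 1))))
        truth_seq[node] = seq
        streams[node] = simulate_imu(
            seq, params, node, np.random.default_rng(rng_noise.spawn(1)[0]))

    return DatasetBundle(
        params=params, model=model, streams=streams, truth_seq=truth_seq,
        truth_beq=beq, truth_angles=series, truth_phases=seg, mounts=mounts,
    )
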