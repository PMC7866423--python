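"""17-segment rigid-body model, forward kinematics and joint angles.

The skeleton is a bar model: a tree of rigid segments rooted at the pelvis,
each carrying a fixed-length direction vector ``d`` expressed in the body
frame at the calibration pose (standing, arms down, facing magnetic north —
the "N-pose", where body and earth axes coincide).  Segment lengths scale
with subject height using standard anthropometric proportions.

Per-segment orientation comes from the sensor fusion output: with the
sensor-to-earth quaternion ``seq(t)`` and the constant mounting quaternion
``sbq = seq(0)`` captured at the calibration pose, the body-to-earth
orientation of the segment is ``beq(t) = seq(t) ⊗ sbq*``.  Positions follow
by accumulating ``start + rotate(beq, d)`` down the tree.

Joint-angle conventions (pinned so typical elbow/shoulder kinematics read
naturally): the elbow angle EF is the interior angle between upper arm and
forearm (a straight arm reads 180°); the shoulder angle SF is measured from
the trunk-down direction (arms at the sides read 0°).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quat import quat_conjugate, quat_identity, quat_multiply, quat_normalize, rotate_vector

__all__ = [
    "Segment",
    "BodyModel",
    "SegmentPose",
    "JointAngleSeries",
    "default_model",
    "sensor_alignment",
    "segment_orientation",
    "forward_kinematics",
    "joint_angle",
    "extract_joint_series",
    "SENSOR_LAYOUT_6",
    "SENSOR_LAYOUT_10",
]


@dataclass
class Segment:
    name: str
    parent: str | None
    d: np.ndarray                # (3,) length vector, m, N-pose body frame
    sensor_node: str | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.parent is not None and np.linalg.norm(self.d) == 0:
            raise ValueError(f"segment {self.name!r} has zero length")


@dataclass
class SegmentPose:
    beq: np.ndarray    # (4,) body-to-earth quaternion
    start: np.ndarray  # (3,) ECS, m
    end: np.ndarray    # (3,) ECS, m


@dataclass
class JointAngleSeries:
    """Four elbow/shoulder flexion channels in degrees at a fixed rate."""

    sample_rate_hz: float
    channels: dict[str, np.ndarray]  # keys EFl, EFr, SFl, SFr

    CHANNELS = ("EFl", "EFr", "SFl", "SFr")

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("joint-angle channels have unequal lengths")

    def __len__(self) -> int:
        return len(next(iter(self.channels.values())))


# Anthropometric segment lengths as fractions of standing height.
SEGMENT_RATIOS: dict[str, float] = {
    "pelvis": 0.0,        # root, zero extent in the bar model
    "waist": 0.144,
    "chest": 0.144,       # waist + chest = trunk 0.288
    "neck": 0.052,
    "head": 0.130,        # neck + head = 0.182
    "upper_arm": 0.186,
    "forearm": 0.146,
    "hand": 0.108,
    "thigh": 0.245,
    "calf": 0.246,
    "foot": 0.152,
}

# Segment direction unit vectors in the N-pose body frame
# (x forward/north, y left-ish completing right-handed, z up).
_UP = np.array([0.0, 0.0, 1.0])
_DOWN = np.array([0.0, 0.0, -1.0])
_FWD = np.array([1.0, 0.0, 0.0])

_TOPOLOGY: list[tuple[str, str | None, str, np.ndarray]] = [
    # (name, parent, ratio key, unit direction)
    ("pelvis", None, "pelvis", _UP),
    ("waist", "pelvis", "waist", _UP),
    ("chest", "waist", "chest", _UP),
    ("neck", "chest", "neck", _UP),
    ("head", "neck", "head", _UP),
    ("upper_arm_l", "chest", "upper_arm", _DOWN),
    ("forearm_l", "upper_arm_l", "forearm", _DOWN),
    ("hand_l", "forearm_l", "hand", _DOWN),
    ("upper_arm_r", "chest", "upper_arm", _DOWN),
    ("forearm_r", "upper_arm_r", "forearm", _DOWN),
    ("hand_r", "forearm_r", "hand", _DOWN),
    ("thigh_l", "pelvis", "thigh", _DOWN),
    ("calf_l", "thigh_l", "calf", _DOWN),
    ("foot_l", "calf_l", "foot", _FWD),
    ("thigh_r", "pelvis", "thigh", _DOWN),
    ("calf_r", "thigh_r", "calf", _DOWN),
    ("foot_r", "calf_r", "foot", _FWD),
]

# Upper-limb layout (6 nodes) and full-body layout (10 nodes); head and feet
# are uninstrumented and inherit the neighboring segment's orientation.
SENSOR_LAYOUT_6: dict[str, str] = {
    "pelvis": "pelvis",
    "chest": "chest",
    "upper_arm_l": "upper_arm_l",
    "forearm_l": "forearm_l",
    "upper_arm_r": "upper_arm_r",
    "forearm_r": "forearm_r",
}
SENSOR_LAYOUT_10: dict[str, str] = dict(
    SENSOR_LAYOUT_6,
    thigh_l="thigh_l",
    calf_l="calf_l",
    thigh_r="thigh_r",
    calf_r="calf_r",
)


@dataclass
class BodyModel:
    segments: dict[str, Segment]
    subject_height: float

    def __post_init__(self) -> None:
        if len(self.segments) != 17:
            raise ValueError(
                f"body model must have 17 segments, got {len(self.segments)}")
        roots = [s for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise ValueError("body model must have exactly one root segment")
        self.root = roots[0].name
        # cycle / dangling-parent check via a walk to the root
        for s in self.segments.values():
            seen, cur = set(), s.name
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle detected at segment {cur!r}")
                seen.add(cur)
                parent = self.segments[cur].parent
                if parent is not None and parent not in self.segments:
                    raise ValueError(f"unknown parent {parent!r} of {cur!r}")
                cur = parent

    def topological_order(self) -> list[str]:
        order: list[str] = []
        remaining = dict(self.segments)
        placed = set()
        while remaining:
            for name, seg in list(remaining.items()):
                if seg.parent is None or seg.parent in placed:
                    order.append(name)
                    placed.add(name)
                    del remaining[name]
        return order


def default_model(height_m: float,
                  sensor_layout: dict[str, str] | None = None,
                  ratios: dict[str, float] | None = None) -> BodyModel:
    """Build the 17-segment model for a subject of the given height.

    ``sensor_layout`` maps segment name -> sensor node id (default: the
    6-node upper-limb layout).  ``ratios`` overrides individual entries of
    the anthropometric proportion table.
    """
    if not 1.0 <= height_m <= 2.5:
        raise ValueError(f"subject height {height_m} m out of range [1.0, 2.5]")
    layout = SENSOR_LAYOUT_6 if sensor_layout is None else sensor_layout
    table = dict(SEGMENT_RATIOS)
    if ratios:
        table.update(ratios)
    segments = {}
    for name, parent, key, unit in _TOPOLOGY:
        segments[name] = Segment(
            name=name,
            parent=parent,
            d=table[key] * height_m * unit,
            sensor_node=layout.get(name),
        )
    return BodyModel(segments=segments, subject_height=height_m)


def sensor_alignment(initial_orientations: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Sensor-to-body mounting quaternions from the calibration pose.

    At the N-pose body and earth frames coincide, so the mounting rotation
    sbq equals the initial sensor-to-earth orientation seq(0) and is held
    constant for the whole recording.
    """
    return {node: quat_normalize(np.asarray(q, dtype=float))
            for node, q in initial_orientations.items()}


def segment_orientation(seq_t: np.ndarray, sbq: np.ndarray) -> np.ndarray:
    """beq(t) = seq(t) ⊗ sbq* — strip the constant mounting rotation."""
    return quat_normalize(quat_multiply(seq_t, quat_conjugate(sbq)))


def forward_kinematics(model: BodyModel,
                       beq_map: dict[str, np.ndarray]) -> dict[str, SegmentPose]:
    """Propagate segment orientations into ECS positions down the tree.

    Segments missing from ``beq_map`` inherit their parent's (resolved)
    orientation; a missing root orientation is an error.
    """
    poses: dict[str, SegmentPose] = {}
    resolved: dict[str, np.ndarray] = {}
    for name in model.topological_order():
        seg = model.segments[name]
        if name in beq_map:
            beq = np.asarray(beq_map[name], dtype=float)
        elif seg.parent is not None:
            beq = resolved[seg.parent]
        else:
            raise ValueError(
                f"no orientation for root segment {name!r} and no parent "
                "to inherit from")
        resolved[name] = beq
        start = (np.zeros(3) if seg.parent is None
                 else poses[seg.parent].end)
        if np.linalg.norm(seg.d) == 0:
            end = start
        else:
            end = start + rotate_vector(beq, seg.d)
        poses[name] = SegmentPose(beq=beq, start=start, end=end)
    return poses


def joint_angle(proximal: SegmentPose, distal: SegmentPose,
                atol: float = 1e-6) -> float:
    """Interior angle (degrees) at the joint shared by two segment poses.

    The angle is between the vectors joint->proximal.start and
    joint->distal.end; collinear opposite-pointing segments (a straight
    limb) read 180°.
    """
    joint = distal.start
    if np.linalg.norm(proximal.end - joint) > max(atol, 1e-6):
        raise ValueError("segments do not share a joint")
    v1 = proximal.start - joint
    v2 = distal.end - joint
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length segment vector at the joint")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def extract_joint_series(pose_frames: list[dict[str, SegmentPose]],
                         model: BodyModel,
                         sample_rate_hz: float) -> JointAngleSeries:
    """Elbow (EF) and shoulder (SF) flexion series from per-frame poses.

    EF: interior angle at the elbow between upper arm and forearm.
    SF: angle of the upper arm away from the trunk-down direction, i.e. the
    interior angle at the shoulder between chest and upper arm.
    """
    if not pose_frames:
        raise ValueError("need at least one pose frame")
    n = len(pose_frames)
    out = {c: np.empty(n) for c in JointAngleSeries.CHANNELS}
    for i, poses in enumerate(pose_frames):
        for side, suffix in (("l", "l"), ("r", "r")):
            ua = poses[f"upper_arm_{side}"]
            fa = poses[f"forearm_{side}"]
            chest = poses["chest"]
            out[f"EF{suffix}"][i] = joint_angle(ua, fa)
            out[f"SF{suffix}"][i] = joint_angle(chest, ua)
    return JointAngleSeries(sample_rate_hz=sample_rate_hz, channels=out)
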