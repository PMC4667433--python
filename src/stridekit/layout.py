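"""Skeleton layout: the 20-joint body model used by Kinect-style trackers.

All trial walks in this package are sequences of skeleton vectors holding
the 3D positions (meters) of these 20 joints.  Joint order is fixed and
shared by every file format and every in-memory array, so a joint name
maps to a contiguous block of three coordinate columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical joint order.  Index i owns columns [3i, 3i+3) of a flattened
#: 60-dimensional skeleton vector.
JOINT_NAMES: tuple[str, ...] = (
    "hip_center",
    "spine",
    "shoulder_center",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "hand_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hand_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
)

N_JOINTS = 20

#: Arm joints excluded when estimating the vertical axis of the canonical
#: reference frame (robustness to unusual / asymmetric arm movement).
ARM_JOINTS: tuple[str, ...] = (
    "elbow_left",
    "wrist_left",
    "hand_left",
    "elbow_right",
    "wrist_right",
    "hand_right",
)

#: Joints used by the template matching: all leg joints plus the hip
#: center (9 joints, 27 coordinates).
MATCHING_JOINTS: tuple[str, ...] = (
    "hip_center",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
)

#: Joints averaged to form the per-frame skeleton center point.
CENTER_JOINTS: tuple[str, ...] = ("hip_left", "hip_right", "hip_center")


@dataclass(frozen=True)
class SkeletonLayout:
    """Ordered list of the 20 joint names plus the name -> index map."""

    joint_names: tuple[str, ...] = JOINT_NAMES
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.joint_names) != N_JOINTS:
            raise ValueError(
                f"skeleton layout needs exactly {N_JOINTS} joints, "
                f"got {len(self.joint_names)}"
            )
        if len(set(self.joint_names)) != N_JOINTS:
            raise ValueError("joint names must be unique")
        object.__setattr__(
            self, "index", {name: i for i, name in enumerate(self.joint_names)}
        )

    def indices(self, names) -> list[int]:
        """Joint indices for a sequence of joint names."""
        return [self.index[n] for n in names]

    def columns(self, names) -> list[int]:
        """Flat coordinate-column indices (into a 60-vector) for joints."""
        cols: list[int] = []
        for n in names:
            j = self.index[n]
            cols.extend((3 * j, 3 * j + 1, 3 * j + 2))
        return cols


DEFAULT_LAYOUT = SkeletonLayout()
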