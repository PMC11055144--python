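"""Core in-memory containers for multi-joint IMU motion data.

A motion profile holds, per frame and per joint, six data types
(position, velocity, acceleration, orientation, angular velocity,
angular acceleration), each a 3-vector, uniformly sampled at a fixed
rate.  Orientation is stored as a rotation vector (radians) so that
every data type is a plain 3-vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError

#: Data types per joint, in the fixed column order used everywhere.
DATA_TYPES: tuple[str, ...] = ("pos", "vel", "acc", "ori", "angvel", "angacc")

#: Axis labels mapped to the R, G, B channels of action images.
AXES: tuple[str, ...] = ("x", "y", "z")

#: Default 23-segment full-body joint set (MVN-style naming).
DEFAULT_JOINTS: tuple[str, ...] = (
    "pelvis", "l5", "l3", "t12", "t8", "neck", "head",
    "right_shoulder", "right_upper_arm", "right_forearm", "right_hand",
    "left_shoulder", "left_upper_arm", "left_forearm", "left_hand",
    "right_upper_leg", "right_lower_leg", "right_foot", "right_toe",
    "left_upper_leg", "left_lower_leg", "left_foot", "left_toe",
)

#: The four end-effectors whose speeds define the representative velocity.
END_EFFECTORS: tuple[str, ...] = ("left_hand", "right_hand", "left_foot", "right_foot")

#: Reduced joint subsets used in the scalability experiments.
REDUCED_4: tuple[str, ...] = END_EFFECTORS
REDUCED_8: tuple[str, ...] = END_EFFECTORS + (
    "left_forearm", "right_forearm", "left_lower_leg", "right_lower_leg",
)

#: The 16 unit-action identifiers.
ACTION_IDS: tuple[str, ...] = tuple(f"A{i}" for i in range(1, 17))


@dataclass
class MotionProfile:
    """Uniformly sampled multi-joint motion time series.

    Parameters
    ----------
    values
        Real tensor of shape ``(T, n_joints, 6, 3)`` — frames x joints x
        data types (order :data:`DATA_TYPES`) x axes (x, y, z).
    sample_rate
        Sampling frequency in Hz (default 240).
    joints
        Ordered joint names; must match ``values.shape[1]``.
    """

    values: np.ndarray
    sample_rate: float = 240.0
    joints: tuple[str, ...] = DEFAULT_JOINTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.joints = tuple(self.joints)
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.values.ndim != 4 or self.values.shape[2:] != (6, 3):
            raise ValidationError(
                f"values must have shape (T, n_joints, 6, 3), got {self.values.shape}"
            )
        if self.values.shape[0] < 2:
            raise ValidationError("a motion profile needs at least 2 frames")
        if self.values.shape[1] != len(self.joints):
            raise ValidationError(
                f"{self.values.shape[1]} joint slots but {len(self.joints)} joint names"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_joints(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Final sample time t_f = (T - 1) / sample_rate, seconds."""
        return (self.n_frames - 1) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    # -- accessors ------------------------------------------------------
    def joint_index(self, joint: str) -> int:
        try:
            return self.joints.index(joint)
        except ValueError:
            raise ConfigurationError(
                f"joint {joint!r} not present in profile (have {len(self.joints)} joints)"
            ) from None

    def channel(self, joint: str, dtype: str) -> np.ndarray:
        """Return the (T, 3) series for one joint and data type."""
        if dtype not in DATA_TYPES:
            raise ConfigurationError(f"unknown data type {dtype!r}; expected one of {DATA_TYPES}")
        return self.values[:, self.joint_index(joint), DATA_TYPES.index(dtype), :]

    def select_joints(self, joints) -> "MotionProfile":
        """Profile restricted to the given joints, in the given order."""
        idx = [self.joint_index(j) for j in joints]
        return MotionProfile(self.values[:, idx], self.sample_rate, tuple(joints))

    def slice_frames(self, start: int, end: int) -> "MotionProfile":
        """Sub-profile over the half-open frame interval [start, end)."""
        if not (0 <= start < end <= self.n_frames):
            raise ValidationError(f"invalid frame slice [{start}, {end}) for T={self.n_frames}")
        if end - start < 2:
            raise ValidationError("a sliced segment needs at least 2 frames")
        return MotionProfile(self.values[start:end], self.sample_rate, self.joints)

    def copy(self) -> "MotionProfile":
        return MotionProfile(self.values.copy(), self.sample_rate, self.joints)


@dataclass(frozen=True)
class SegmentMeta:
    """Location and labelling of one unit-action repetition.

    Frame indices are 0-based and the interval is half-open
    ``[start_frame, end_frame)``.
    """

    subject_id: str
    action_id: str
    repetition_index: int
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.action_id not in ACTION_IDS:
            raise ValidationError(f"action_id {self.action_id!r} not in {ACTION_IDS[0]}..{ACTION_IDS[-1]}")
        if not (0 <= self.start_frame < self.end_frame):
            raise ValidationError(
                f"need 0 <= start < end, got [{self.start_frame}, {self.end_frame})"
            )
        if self.repetition_index < 1:
            raise ValidationError("repetition_index is 1-based")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "action_id": self.action_id,
            "repetition_index": self.repetition_index,
            "start_frame": self.start_frame,
            "end_frame": self.end_frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentMeta":
        return cls(
            subject_id=d["subject_id"],
            action_id=d["action_id"],
            repetition_index=int(d["repetition_index"]),
            start_frame=int(d["start_frame"]),
            end_frame=int(d["end_frame"]),
        )
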