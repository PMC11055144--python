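"""Velocity-based segmentation of a session into unit-action repetitions.

The representative velocity V_rep(t) is the arithmetic mean of the
speed magnitudes of the two hands and two feet.  A session recorded as
[rest | rep | rest | ... | rep | rest] is cut by smoothing V_rep,
thresholding at a fraction of its peak, merging nearby above-threshold
runs, discarding spuriously short ones and padding the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .profile import DATA_TYPES, END_EFFECTORS, MotionProfile

_VEL = DATA_TYPES.index("vel")


@dataclass
class VelocitySeries:
    """Representative velocity V_rep and its end-effector components."""

    sample_rate: float
    values: np.ndarray                      # (T,) nonnegative
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("velocity series must be 1-D")
        if np.any(self.values < 0):
            raise ValidationError("velocity magnitudes cannot be negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    def slice_frames(self, start: int, end: int) -> "VelocitySeries":
        return VelocitySeries(
            self.sample_rate,
            self.values[start:end],
            {k: v[start:end] for k, v in self.components.items()},
        )


@dataclass(frozen=True)
class SegmenterParams:
    """Tunable parameters of the threshold segmenter (all in seconds
    except the dimensionless peak fraction)."""

    smoothing_window: float = 0.25
    threshold_fraction: float = 0.10
    min_duration: float = 0.3
    min_gap: float = 0.2
    padding: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction < 1):
            raise ConfigurationError("threshold_fraction must lie in (0, 1)")
        for name in ("smoothing_window", "min_duration", "min_gap", "padding"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def representative_velocity(
    profile: MotionProfile, end_effectors=END_EFFECTORS
) -> VelocitySeries:
    """Mean end-effector speed per frame.

    V_rep[t] = 1/4 (|v_hl| + |v_hr| + |v_fl| + |v_fr|), using the
    velocity channel of the four configured end-effector joints.
    """
    comps: dict[str, np.ndarray] = {}
    for joint in end_effectors:
        if joint not in profile.joints:
            raise ConfigurationError(
                f"end-effector joint {joint!r} missing from profile"
            )
        v = profile.channel(joint, "vel")
        comps[joint] = np.linalg.norm(v, axis=1)
    stacked = np.stack(list(comps.values()), axis=0)
    return VelocitySeries(profile.sample_rate, stacked.mean(axis=0), comps)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def _runs(mask: np.ndarray) -> list[list[int]]:
    """Half-open [start, end) index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [[int(s), int(e)] for s, e in zip(idx[::2], idx[1::2])]


def segment_actions(
    velocity: VelocitySeries, params: SegmenterParams = SegmenterParams()
) -> list[tuple[int, int]]:
    """Cut a session into unit-action frame intervals.

    Returns sorted, pairwise-disjoint half-open ``(start, end)`` frame
    intervals.  A session with no motion (zero peak velocity) yields an
    empty list.  The threshold is relative to the smoothed peak, so the
    result is invariant to positive rescaling of the velocity.
    """
    fs = velocity.sample_rate
    win = max(1, int(round(params.smoothing_window * fs)))
    smoothed = _moving_average(velocity.values, win)
    peak = smoothed.max(initial=0.0)
    if peak <= 0:
        return []

    mask = smoothed > params.threshold_fraction * peak
    runs = _runs(mask)
    if not runs:
        return []

    # Merge runs whose separating gap is shorter than min_gap.
    gap = int(round(params.min_gap * fs))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # Drop runs shorter than min_duration, then pad and clip.
    min_len = int(round(params.min_duration * fs))
    pad = int(round(params.padding * fs))
    T = velocity.n_frames
    padded = [
        [max(0, s - pad), min(T, e + pad)]
        for s, e in merged
        if e - s >= min_len
    ]
    if not padded:
        return []

    # Padding may create overlaps; merge them to keep intervals disjoint.
    out = [padded[0]]
    for s, e in padded[1:]:
        if s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def match_segments(found, truth, tolerance_frames: int):
    """Pair detected intervals with ground-truth intervals in order.

    Returns the list of (found, truth) pairs whose start and end both
    agree within ``tolerance_frames``.  Helper for validating the
    segmenter against the synthetic generator's ground truth.
    """
    pairs = []
    for f, t in zip(found, truth):
        if abs(f[0] - t[0]) <= tolerance_frames and abs(f[1] - t[1]) <= tolerance_frames:
            pairs.append((f, t))
    return pairs
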