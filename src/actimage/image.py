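"""Rendering motion segments as RGB action images.

Rows index (warped) time, columns index joint x data type (six columns
per joint, in the order position, velocity, acceleration, orientation,
angular velocity, angular acceleration) and the x/y/z components of
each datum map to the R/G/B channels.  Each column is min-max
normalized so pixel values lie in [0, 1].

Two normalization rules are provided.  ``per_axis`` (default) rescales
each axis of each column by its own extrema — the standard min-max
map, guaranteed to land in [0, 1].  ``shared_x_denominator``
reproduces the alternative formulation in which all three channels are
divided by the x-axis range with no minimum subtracted; values are
clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError

SCOPES = ("per_segment", "global")
AXIS_RULES = ("per_axis", "shared_x_denominator")


@dataclass(frozen=True)
class NormalizationSpec:
    scope: str = "per_segment"
    axis_rule: str = "per_axis"
    constant_fill: float = 0.0

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValidationError(f"scope must be one of {SCOPES}")
        if self.axis_rule not in AXIS_RULES:
            raise ValidationError(f"axis_rule must be one of {AXIS_RULES}")
        if not (0.0 <= self.constant_fill <= 1.0):
            raise ValidationError("constant_fill must lie in [0, 1]")


@dataclass
class ActionImage:
    """H x W x 3 raster with pixel values in [0, 1].

    W = 6 x n_joints; column 6j+k holds data type k of joint j.
    """

    pixels: np.ndarray
    label: Optional[str] = None
    joints: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(f"pixels must be (H, W, 3), got {self.pixels.shape}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _columns(segment) -> np.ndarray:
    """(H, W, 3) column-major view of a profile-like object's values."""
    vals = np.asarray(segment.values, dtype=float)
    h = vals.shape[0]
    return vals.reshape(h, -1, 3)


def channel_extents(segment, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Per-column, per-axis (min, max) pairs, shape (W, 3, 2).

    For ``scope="per_segment"`` the extrema are taken over this
    segment; under global scope callers pool extents across segments
    with :func:`combine_extents` and pass the result to
    :func:`render_action_image`.
    """
    cols = _columns(segment)
    if cols.shape[0] == 0:
        raise ValidationError("cannot take extents of an empty segment")
    return np.stack([cols.min(axis=0), cols.max(axis=0)], axis=-1)


def combine_extents(extents_list) -> np.ndarray:
    """Pool per-segment extents into global extents."""
    stacked = np.stack(extents_list)
    return np.stack(
        [stacked[..., 0].min(axis=0), stacked[..., 1].max(axis=0)], axis=-1
    )


def render_action_image(
    segment,
    spec: NormalizationSpec = NormalizationSpec(),
    extents: np.ndarray | None = None,
    label: Optional[str] = None,
) -> ActionImage:
    """Map a (warped) segment onto the RGB color space.

    ``segment`` is any profile-like object with a ``values`` tensor of
    shape (H, n_joints, 6, 3) — the H rows become image rows top-down.
    ``extents`` overrides the per-segment extrema (global scope).
    Columns with zero range render as ``spec.constant_fill``.
    """
    cols = _columns(segment)                      # (H, W, 3)
    if extents is None:
        ext = channel_extents(segment, spec)
    else:
        ext = np.asarray(extents, dtype=float)
        if ext.shape != (cols.shape[1], 3, 2):
            raise ValidationError(
                f"extents shape {ext.shape} does not match image width {cols.shape[1]}"
            )
    lo, hi = ext[..., 0], ext[..., 1]             # (W, 3)

    if spec.axis_rule == "per_axis":
        rng = hi - lo
        safe = np.where(rng > 0, rng, 1.0)
        px = (cols - lo) / safe
        px = np.where(rng > 0, px, spec.constant_fill)
    else:  # shared_x_denominator: divide all axes by the x range, no min shift
        xr = (hi[:, 0] - lo[:, 0])[:, None]       # (W, 1)
        safe = np.where(xr > 0, xr, 1.0)
        px = cols / safe
        px = np.where(xr > 0, px, spec.constant_fill)
    px = np.clip(px, 0.0, 1.0)
    joints = tuple(getattr(segment, "joints", ()))
    return ActionImage(pixels=px, label=label, joints=joints)


def velocity_brightness(image: ActionImage) -> np.ndarray:
    """Per-row brightness of the active velocity columns.

    Velocity channels are signed, so after min-max normalization a
    large speed maps to a pixel near either extreme while zero
    velocity sits mid-range; "brightness" here is therefore the mean
    extremeness ``2 |pixel - 1/2|`` over the velocity-column channels
    that vary at all (constant channels carry no motion information).
    Returns a length-H vector in [0, 1].
    """
    vel_cols = image.pixels[:, 1::6, :]        # data type 1 = velocity
    active = vel_cols.max(axis=0) > 0
    if not active.any():
        return np.zeros(image.height)
    return (2 * np.abs(vel_cols[:, active] - 0.5)).mean(axis=1)


def bright_row_count(image: ActionImage, threshold: float = 0.5) -> int:
    """Number of rows whose velocity brightness exceeds ``threshold``."""
    return int((velocity_brightness(image) > threshold).sum())
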