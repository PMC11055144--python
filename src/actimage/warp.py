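"""Velocity-driven temporal reparameterization ("time warping").

A unit-action segment is resampled along its time axis according to
the normalized cumulative representative velocity

    s(t) = int_0^t V_rep dτ / int_0^{t_f} V_rep dτ  in [0, 1],

so that intervals of rapid motion occupy a larger share of the output
rows.  Two modes are provided:

``expand_fast`` (default)
    Output rows are uniform in cumulative velocity: row i samples the
    input at s^{-1}(i / (n_rows - 1)).  Fast intervals, which
    accumulate velocity quickly, receive proportionally more rows —
    the slow-motion effect.

``literal_eq7``
    Row i samples the input at t_warp(t_i) = s(t_i) · t_f on a uniform
    output grid, i.e. the direct composition p(t_warp).  This is the
    inverse reparameterization (it compresses fast intervals); it is
    retained for fidelity studies.

This is unrelated to dynamic time warping between sequence pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .profile import MotionProfile
from .segmentation import VelocitySeries

MODES = ("expand_fast", "literal_eq7")
INTEGRATION_RULES = ("trapezoid", "left_riemann")

# Tiny monotonicity regularizer so s is strictly increasing even across
# zero-velocity plateaus; changes the map by at most ~1e-9 of t_f.
_EPS_STRICT = 1e-9


@dataclass
class WarpMap:
    """Monotone map between original time and cumulative-velocity phase."""

    t_f: float
    grid: np.ndarray          # input sample times, uniform, grid[0]=0
    cumulative: np.ndarray    # s(t) on the grid, s[0]=0, s[-1]=1 (or identity)
    mode: str = "expand_fast"
    integration_rule: str = "trapezoid"

    def source_times(self, n_rows: int) -> np.ndarray:
        """Input times sampled by each of ``n_rows`` output rows."""
        if n_rows < 2:
            raise ValidationError("n_rows must be at least 2")
        if self.mode == "literal_eq7":
            t_uniform = np.linspace(0.0, self.t_f, n_rows)
            return np.interp(t_uniform, self.grid, self.cumulative) * self.t_f
        # expand_fast: invert s on a strictly increasing copy
        u = np.linspace(0.0, 1.0, n_rows)
        s_strict = (self.cumulative + _EPS_STRICT * self.grid / max(self.t_f, 1e-300))
        s_strict /= s_strict[-1]
        return np.interp(u, s_strict, self.grid)


@dataclass
class WarpedProfile:
    """A segment resampled onto warped time; rows map to source_times."""

    values: np.ndarray            # (n_rows, n_joints, 6, 3)
    source_times: np.ndarray      # (n_rows,)
    joints: tuple[str, ...]
    sample_rate: float            # of the source segment

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def build_warp_map(
    velocity: VelocitySeries,
    integration_rule: str = "trapezoid",
    mode: str = "expand_fast",
) -> WarpMap:
    """Cumulative-velocity map over a segment's uniform time grid.

    The cumulative integral is computed with the chosen quadrature and
    normalized by its total.  If the total is zero (a motionless
    segment) the map degrades gracefully to the identity s(t) = t/t_f.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if integration_rule not in INTEGRATION_RULES:
        raise ValidationError(
            f"integration_rule must be one of {INTEGRATION_RULES}, got {integration_rule!r}"
        )
    v = velocity.values
    if np.any(v < 0):
        raise ValidationError("representative velocity cannot be negative")
    if velocity.n_frames < 2:
        raise ValidationError("a segment needs at least 2 frames to warp")
    grid = velocity.times
    t_f = velocity.duration
    dt = 1.0 / velocity.sample_rate
    if integration_rule == "trapezoid":
        cum = cumulative_trapezoid(v, dx=dt, initial=0.0)
    else:  # left_riemann: accumulate v[0..i-1] * dt
        cum = np.concatenate(([0.0], np.cumsum(v[:-1]) * dt))
    total = cum[-1]
    if total <= 0:
        s = grid / t_f
    else:
        s = cum / total
    return WarpMap(t_f=t_f, grid=grid, cumulative=s, mode=mode,
                   integration_rule=integration_rule)


def warp_profile(segment: MotionProfile, warp_map: WarpMap, n_rows: int) -> WarpedProfile:
    """Resample all channels of a segment at the warped sample times.

    Every joint/data-type/axis series is interpolated with a natural
    cubic spline; query times are clamped to [0, t_f].
    """
    if n_rows < 2:
        raise ValidationError("n_rows must be at least 2")
    src = np.clip(warp_map.source_times(n_rows), 0.0, warp_map.t_f)
    flat = segment.values.reshape(segment.n_frames, -1)
    spline = CubicSpline(segment.times, flat, axis=0, bc_type="natural")
    out = spline(src).reshape(n_rows, segment.n_joints, 6, 3)
    return WarpedProfile(values=out, source_times=src,
                         joints=segment.joints, sample_rate=segment.sample_rate)


def resample_profile(segment: MotionProfile, n_rows: int) -> WarpedProfile:
    """Uniform (unwarped) resampling to ``n_rows`` rows via the same spline.

    Equivalent to warping with a constant-velocity map; used as the
    "normal" arm of warped-vs-normal comparisons.
    """
    identity = WarpMap(
        t_f=segment.duration,
        grid=segment.times,
        cumulative=segment.times / segment.duration,
        mode="expand_fast",
    )
    return warp_profile(segment, identity, n_rows)
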