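"""Seeded generator of labeled Taekwondo-like motion sessions.

The generator emulates the collection protocol of the target study
design: 40 subjects x 16 unit actions x 12 repetitions, 23 joints,
240 Hz, with rest gaps between repetitions.  Each action is defined by
an :class:`ActionTemplate` — per-joint keyframes on a normalized phase
axis [0, 1] with a designated *fast interval* during which the
striking end-effector covers most of its distance.  Positions follow
piecewise minimum-jerk interpolation through the keyframes (zero
velocity and acceleration at every keyframe), so the velocity and
acceleration channels are exact analytic derivatives of position.
Angular channels are generated the same way from a secondary keyframe
set of rotation vectors.

The templates are stylized, not biomechanically faithful: movement
amplitudes and speeds are deliberately moderate so that discrete
derivative checks at 240 Hz remain truncation-dominated, and
uninvolved joints hold the standing pose.  What the templates do
preserve is the *structure* the downstream method exploits —
class-distinct trajectories, a concentrated high-speed interval per
repetition, near-duplicate action pairs, and rest gaps that make
velocity-threshold segmentation well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .profile import (
    ACTION_IDS,
    DATA_TYPES,
    DEFAULT_JOINTS,
    MotionProfile,
    SegmentMeta,
)

# -- standing rest pose (meters; x lateral-right, y forward, z up) ------

REST_POSE: dict[str, tuple[float, float, float]] = {
    "pelvis": (0.0, 0.0, 1.00),
    "l5": (0.0, 0.0, 1.10),
    "l3": (0.0, 0.0, 1.20),
    "t12": (0.0, 0.0, 1.30),
    "t8": (0.0, 0.0, 1.40),
    "neck": (0.0, 0.0, 1.55),
    "head": (0.0, 0.0, 1.70),
    "right_shoulder": (0.20, 0.0, 1.50),
    "right_upper_arm": (0.33, 0.0, 1.35),
    "right_forearm": (0.38, 0.0, 1.10),
    "right_hand": (0.42, 0.0, 0.90),
    "left_shoulder": (-0.20, 0.0, 1.50),
    "left_upper_arm": (-0.33, 0.0, 1.35),
    "left_forearm": (-0.38, 0.0, 1.10),
    "left_hand": (-0.42, 0.0, 0.90),
    "right_upper_leg": (0.10, 0.0, 0.90),
    "right_lower_leg": (0.10, 0.0, 0.50),
    "right_foot": (0.10, 0.05, 0.10),
    "right_toe": (0.10, 0.17, 0.05),
    "left_upper_leg": (-0.10, 0.0, 0.90),
    "left_lower_leg": (-0.10, 0.0, 0.50),
    "left_foot": (-0.10, 0.05, 0.10),
    "left_toe": (-0.10, 0.17, 0.05),
}

#: Fractional excursion of proximal joints relative to the end-effector.
_ARM_CHAIN = {"hand": 1.0, "forearm": 0.6, "upper_arm": 0.3}
_LEG_CHAIN = {"foot": 1.0, "toe": 0.95, "lower_leg": 0.6, "upper_leg": 0.3}

#: Standard deviation (m or rad) of per-repetition keyframe jitter.
KEYFRAME_JITTER = 0.015


@dataclass
class ActionTemplate:
    """Keyframe description of one unit action on a phase axis [0, 1]."""

    action_id: str
    name: str
    keyframes: Mapping[str, Sequence[tuple[float, Sequence[float]]]]
    angular_keyframes: Mapping[str, Sequence[tuple[float, Sequence[float]]]]
    fast_interval: tuple[float, float]
    speed_gain: float
    duration_mean: float
    duration_sd: float

    def __post_init__(self) -> None:
        a, b = self.fast_interval
        if not (0.0 <= a < b <= 1.0):
            raise ValidationError(f"fast_interval must satisfy 0 <= a < b <= 1, got {self.fast_interval}")
        if self.speed_gain < 1.0:
            raise ValidationError("speed_gain must be >= 1")
        if self.duration_mean <= 0 or self.duration_sd < 0:
            raise ValidationError("invalid duration parameters")
        for mapping in (self.keyframes, self.angular_keyframes):
            for joint, kfs in mapping.items():
                phases = [p for p, _ in kfs]
                if phases != sorted(phases) or phases[0] != 0.0 or phases[-1] != 1.0:
                    raise ValidationError(
                        f"{self.action_id}/{joint}: keyframe phases must ascend from 0 to 1"
                    )

    def to_dict(self) -> dict:
        def ser(mapping):
            return {
                j: [[float(p), [float(x) for x in pos]] for p, pos in kfs]
                for j, kfs in mapping.items()
            }

        return {
            "action_id": self.action_id,
            "name": self.name,
            "keyframes": ser(self.keyframes),
            "angular_keyframes": ser(self.angular_keyframes),
            "fast_interval": list(self.fast_interval),
            "speed_gain": self.speed_gain,
            "duration_mean": self.duration_mean,
            "duration_sd": self.duration_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActionTemplate":
        def de(mapping):
            return {
                j: [(float(p), tuple(pos)) for p, pos in kfs]
                for j, kfs in mapping.items()
            }

        return cls(
            action_id=d["action_id"],
            name=d["name"],
            keyframes=de(d["keyframes"]),
            angular_keyframes=de(d["angular_keyframes"]),
            fast_interval=tuple(d["fast_interval"]),
            speed_gain=float(d["speed_gain"]),
            duration_mean=float(d["duration_mean"]),
            duration_sd=float(d["duration_sd"]),
        )


@dataclass(frozen=True)
class ProtocolConfig:
    """Collection-protocol parameters (defaults follow the study design)."""

    n_subjects: int = 40
    n_actions: int = 16
    n_repetitions: int = 12
    sample_rate: float = 240.0
    rest_duration: float = 1.0
    subject_variability: float = 0.05
    noise_base: str = "rms"          # "rms" or "range" scale base for add_noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_actions", "n_repetitions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_actions > len(ACTION_IDS):
            raise ConfigurationError(f"at most {len(ACTION_IDS)} actions are defined")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.rest_duration <= 0:
            raise ConfigurationError(
                "rest_duration must be positive: segmentation needs rest gaps"
            )
        if self.subject_variability < 0:
            raise ConfigurationError("subject_variability cannot be negative")
        if self.noise_base not in ("rms", "range"):
            raise ConfigurationError("noise_base must be 'rms' or 'range'")


# -- default templates --------------------------------------------------

def _limb_keyframes(side: str, kind: str, stages: Sequence[tuple[float, np.ndarray]]):
    """Keyframes for a whole limb chain from end-effector offsets.

    ``stages`` are (phase, offset-from-rest) for the end-effector;
    proximal joints follow with attenuated excursions.
    """
    chain = _ARM_CHAIN if kind == "arm" else _LEG_CHAIN
    out = {}
    for part, scale in chain.items():
        joint = f"{side}_{part}"
        rest = np.asarray(REST_POSE[joint])
        out[joint] = [(p, tuple(rest + scale * np.asarray(off))) for p, off in stages]
    return out


def _angular(side: str, kind: str, axis: Sequence[float], magnitude: float,
             a: float, b: float):
    """Rotation-vector keyframes: ramp to ``magnitude`` about ``axis``."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    parts = ("hand", "forearm") if kind == "arm" else ("foot", "lower_leg")
    scales = (1.0, 0.5)
    out = {}
    for part, sc in zip(parts, scales):
        r = magnitude * sc * u
        out[f"{side}_{part}"] = [
            (0.0, (0.0, 0.0, 0.0)),
            (a, tuple(0.35 * r)),
            (b, tuple(r)),
            (1.0, (0.0, 0.0, 0.0)),
        ]
    return out


def _simple_template(action_id, name, side, kind, chamber, target, fast, gain,
                     dur, ang_axis, ang_mag=1.0):
    a, b = fast
    stages = [
        (0.0, np.zeros(3)),
        (a, np.asarray(chamber)),
        (b, np.asarray(target)),
        (1.0, np.zeros(3)),
    ]
    return ActionTemplate(
        action_id=action_id,
        name=name,
        keyframes=_limb_keyframes(side, kind, stages),
        angular_keyframes=_angular(side, kind, ang_axis, ang_mag, a, b),
        fast_interval=fast,
        speed_gain=gain,
        duration_mean=dur,
        duration_sd=0.05,
    )


def _kick_template(action_id, name, chamber, target, phases, gain, dur, ang_axis):
    """Out-and-back kick: slow chamber, fast strike + re-chamber, slow lower."""
    a, mid, b = phases
    stages = [
        (0.0, np.zeros(3)),
        (a, np.asarray(chamber)),
        (mid, np.asarray(target)),
        (b, np.asarray(chamber)),
        (1.0, np.zeros(3)),
    ]
    return ActionTemplate(
        action_id=action_id, name=name,
        keyframes=_limb_keyframes("right", "leg", stages),
        angular_keyframes=_angular("right", "leg", ang_axis, 1.0, a, b),
        fast_interval=(a, b), speed_gain=gain,
        duration_mean=dur, duration_sd=0.05,
    )


def _double_punch_template() -> ActionTemplate:
    """A7: alternating right/left punch, one fast interval spanning both."""
    ch_r, tg_r = np.array([-0.05, -0.22, 0.10]), np.array([-0.15, 0.42, 0.30])
    ch_l, tg_l = np.array([0.05, -0.22, 0.10]), np.array([0.15, 0.42, 0.30])
    right = [(0.0, np.zeros(3)), (0.25, ch_r), (0.50, tg_r), (0.75, ch_r), (1.0, np.zeros(3))]
    left = [(0.0, np.zeros(3)), (0.25, ch_l), (0.50, ch_l), (0.75, tg_l), (1.0, np.zeros(3))]
    kf = {}
    kf.update(_limb_keyframes("right", "arm", right))
    kf.update(_limb_keyframes("left", "arm", left))
    ang = {}
    ang.update(_angular("right", "arm", (0, 1, 0), 1.2, 0.25, 0.50))
    ang.update(_angular("left", "arm", (0, 1, 0), 1.2, 0.55, 0.75))
    return ActionTemplate(
        action_id="A7", name="double_punch", keyframes=kf, angular_keyframes=ang,
        fast_interval=(0.25, 0.75), speed_gain=2.5, duration_mean=2.4, duration_sd=0.05,
    )


def _swallow_form_template() -> ActionTemplate:
    """A12: right inside strike with a simultaneous slow left guard."""
    strike = [
        (0.0, np.zeros(3)),
        (0.40, np.array([0.24, 0.05, 0.24])),
        (0.60, np.array([-0.18, 0.26, 0.22])),
        (1.0, np.zeros(3)),
    ]
    guard = [
        (0.0, np.zeros(3)),
        (0.40, np.array([0.05, 0.08, 0.12])),
        (0.60, np.array([0.05, 0.08, 0.12])),
        (1.0, np.zeros(3)),
    ]
    kf = {}
    kf.update(_limb_keyframes("right", "arm", strike))
    kf.update(_limb_keyframes("left", "arm", guard))
    ang = _angular("right", "arm", (1, 0, 1), 1.1, 0.40, 0.60)
    return ActionTemplate(
        action_id="A12", name="swallow_form_inside_strike", keyframes=kf,
        angular_keyframes=ang, fast_interval=(0.40, 0.60), speed_gain=2.5,
        duration_mean=2.3, duration_sd=0.05,
    )


def _turning_kick_template() -> ActionTemplate:
    """A16: arcing kick through lateral waypoints, out and back."""
    arc = [
        (0.0, np.zeros(3)),
        (0.30, np.array([0.12, 0.04, 0.32])),
        (0.45, np.array([0.28, 0.18, 0.42])),
        (0.60, np.array([0.14, 0.30, 0.44])),
        (0.75, np.array([0.12, 0.04, 0.32])),
        (1.0, np.zeros(3)),
    ]
    kf = _limb_keyframes("right", "leg", arc)
    ang = _angular("right", "leg", (0, 0, 1), 1.4, 0.30, 0.75)
    return ActionTemplate(
        action_id="A16", name="turning_kick", keyframes=kf, angular_keyframes=ang,
        fast_interval=(0.30, 0.75), speed_gain=2.0, duration_mean=2.8, duration_sd=0.05,
    )


def default_templates() -> dict[str, ActionTemplate]:
    """The 16 stock unit-action templates, keyed by action id.

    A6 (body punch) and A8 (face punch) form a near-duplicate pair
    differing only in the hand's target height.
    """
    t = {}
    t["A1"] = _simple_template(
        "A1", "single_knife_hand_block", "left", "arm",
        (0.18, 0.05, 0.26), (-0.20, 0.18, 0.14), (0.36, 0.64), 2.5, 1.9, (0, 1, 0))
    t["A2"] = _simple_template(
        "A2", "knife_hand_inward_outside", "right", "arm",
        (-0.26, 0.08, 0.18), (0.20, 0.20, 0.12), (0.35, 0.63), 2.5, 1.9, (0, 0, 1))
    t["A3"] = _simple_template(
        "A3", "body_inside_block", "right", "arm",
        (0.24, 0.08, 0.14), (-0.18, 0.20, 0.10), (0.37, 0.65), 2.5, 1.8, (1, 0, 0))
    t["A4"] = _simple_template(
        "A4", "low_block", "right", "arm",
        (-0.08, 0.08, 0.30), (0.06, 0.16, -0.16), (0.36, 0.63), 2.5, 1.8, (1, 0, 1))
    t["A5"] = _simple_template(
        "A5", "high_block", "right", "arm",
        (-0.04, 0.12, -0.14), (0.04, 0.16, 0.30), (0.37, 0.64), 2.5, 1.9, (0, 1, 1))
    t["A6"] = _simple_template(
        "A6", "body_punch", "right", "arm",
        (-0.04, -0.20, 0.08), (-0.10, 0.32, 0.20), (0.36, 0.64), 3.0, 1.8, (0, 1, 0))
    t["A7"] = _double_punch_template()
    # A8 is the near-duplicate of A6: same chamber, near-identical timing,
    # target raised to face height.
    t["A8"] = _simple_template(
        "A8", "face_punch", "right", "arm",
        (-0.04, -0.20, 0.08), (-0.10, 0.30, 0.38), (0.36, 0.65), 3.0, 1.8, (0, 1, 0))
    t["A9"] = _simple_template(
        "A9", "spear_hand_thrust", "right", "arm",
        (-0.04, -0.16, 0.12), (-0.06, 0.38, 0.22), (0.35, 0.64), 3.0, 1.8, (1, 1, 0))
    t["A10"] = _simple_template(
        "A10", "inside_knife_hand_strike", "right", "arm",
        (0.24, 0.05, 0.24), (-0.20, 0.22, 0.20), (0.36, 0.62), 2.5, 1.9, (1, 0, 0), 1.2)
    t["A11"] = _simple_template(
        "A11", "side_knife_hand_strike", "right", "arm",
        (-0.22, 0.05, 0.24), (0.24, 0.16, 0.28), (0.37, 0.66), 2.5, 1.9, (0, 0, 1), 1.2)
    t["A12"] = _swallow_form_template()
    t["A13"] = _simple_template(
        "A13", "back_fist_front_strike", "right", "arm",
        (-0.18, 0.04, 0.04), (0.02, 0.28, 0.30), (0.38, 0.64), 3.0, 1.8, (1, 0, 0), 1.4)
    t["A14"] = _kick_template(
        "A14", "front_kick",
        (0.0, 0.12, 0.30), (0.0, 0.36, 0.50), (0.325, 0.50, 0.675), 2.5, 2.4, (1, 0, 0))
    t["A15"] = _kick_template(
        "A15", "side_kick",
        (0.06, 0.08, 0.32), (0.30, 0.16, 0.50), (0.33, 0.505, 0.68), 2.5, 2.4, (0, 1, 0))
    t["A16"] = _turning_kick_template()
    return t


def fast_contrast_templates(n_classes: int = 4) -> dict[str, ActionTemplate]:
    """Templates whose classes differ *only* inside the fast interval.

    All classes share the same chamber position, timing and rest pose;
    the strike target direction is the sole class-distinguishing
    feature, and it is visited only during the (short) fast interval.
    Used to probe whether time warping helps when the discriminative
    information is confined to rapid movement.
    """
    if not (2 <= n_classes <= 8):
        raise ConfigurationError("fast-contrast set supports 2..8 classes")
    chamber = (-0.05, -0.20, 0.10)
    angles = np.linspace(0, 2 * np.pi, n_classes, endpoint=False)
    out = {}
    for k, th in enumerate(angles):
        aid = f"A{k + 1}"
        target = (
            chamber[0] + 0.28 * np.cos(th),
            chamber[1] + 0.30,
            chamber[2] + 0.28 * np.sin(th),
        )
        out[aid] = _simple_template(
            aid, f"fast_contrast_{k}", "right", "arm",
            chamber, target, (0.40, 0.62), 2.0, 1.9, (0, 1, 0))
    return out


# -- minimum-jerk evaluation -------------------------------------------

def _minjerk_piecewise(phase, ctrl_phases, ctrl_points, duration):
    """Evaluate a piecewise minimum-jerk curve and its time derivatives.

    Each keyframe interval uses the quintic blend
    s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5 (zero velocity and
    acceleration at both ends).  Returns (pos, vel, acc), each
    (len(phase), 3); velocities are per second given ``duration``.
    """
    ctrl_phases = np.asarray(ctrl_phases, dtype=float)
    ctrl_points = np.asarray(ctrl_points, dtype=float)
    pos = np.empty((len(phase), 3))
    vel = np.empty_like(pos)
    acc = np.empty_like(pos)
    k = np.clip(np.searchsorted(ctrl_phases, phase, side="right") - 1, 0,
                len(ctrl_phases) - 2)
    p0 = ctrl_points[k]
    dp = ctrl_points[k + 1] - p0
    span = (ctrl_phases[k + 1] - ctrl_phases[k])
    tau = np.clip((phase - ctrl_phases[k]) / span, 0.0, 1.0)
    s = tau**3 * (10 - 15 * tau + 6 * tau**2)
    ds = 30 * tau**2 * (1 - tau) ** 2
    dds = 60 * tau * (1 - 3 * tau + 2 * tau**2)
    seg_t = span * duration
    pos[:] = p0 + dp * s[:, None]
    vel[:] = dp * (ds / seg_t)[:, None]
    acc[:] = dp * (dds / seg_t**2)[:, None]
    return pos, vel, acc


def _rest_frame(joints) -> np.ndarray:
    """(n_joints, 6, 3) standing-pose frame with zero derivatives."""
    frame = np.zeros((len(joints), 6, 3))
    for j, name in enumerate(joints):
        frame[j, 0] = REST_POSE[name]
    return frame


def _repetition_block(template, duration, amplitude, rng, joints, sample_rate):
    """One repetition as a (n, n_joints, 6, 3) tensor.

    The nominal duration is snapped to the sampling grid — the block
    spans exactly (n - 1) / sample_rate seconds — so the analytic
    velocity/acceleration channels are consistent with the frame
    spacing of the assembled session.
    """
    n = max(4, int(round(duration * sample_rate)) + 1)
    duration = (n - 1) / sample_rate
    phase = np.arange(n) / (n - 1)
    block = np.repeat(_rest_frame(joints)[None], n, axis=0)
    jidx = {name: i for i, name in enumerate(joints)}

    for mapping, base_offset in ((template.keyframes, 0), (template.angular_keyframes, 3)):
        for joint, kfs in mapping.items():
            if joint not in jidx:
                continue  # reduced-joint profiles simply drop the channel
            phases = [p for p, _ in kfs]
            if base_offset == 0:
                rest = np.asarray(REST_POSE[joint])
                pts = [rest + amplitude * (np.asarray(p) - rest) for _, p in kfs]
            else:
                pts = [amplitude * np.asarray(p) for _, p in kfs]
            # per-repetition jitter on interior keyframes only, so every
            # repetition starts and ends exactly at rest
            pts = [
                p if i in (0, len(pts) - 1) else p + rng.normal(0.0, KEYFRAME_JITTER, 3)
                for i, p in enumerate(pts)
            ]
            pos, vel, acc = _minjerk_piecewise(phase, phases, pts, duration)
            j = jidx[joint]
            block[:, j, base_offset + 0] = pos
            block[:, j, base_offset + 1] = vel
            block[:, j, base_offset + 2] = acc
    return block


def generate_session(
    template: ActionTemplate,
    config: ProtocolConfig,
    subject_id: str,
    seed: int,
    amplitude_scale: Optional[float] = None,
    timing_scale: Optional[float] = None,
    joints: tuple[str, ...] = DEFAULT_JOINTS,
) -> tuple[MotionProfile, list[SegmentMeta]]:
    """One subject performing one action ``n_repetitions`` times.

    The session layout is [rest | rep 1 | rest | ... | rep n | rest].
    Ground-truth :class:`SegmentMeta` is returned for every repetition.
    Subject-level amplitude/timing scales may be supplied (as
    :func:`generate_dataset` does, drawing them once per subject);
    otherwise they are drawn from this session's stream.
    """
    rng = np.random.default_rng(seed)
    sv = config.subject_variability
    if amplitude_scale is None:
        amplitude_scale = float(np.clip(rng.normal(1.0, sv), 0.6, 1.6))
    if timing_scale is None:
        timing_scale = float(np.clip(rng.normal(1.0, sv), 0.6, 1.6))

    fs = config.sample_rate
    n_rest = max(2, int(round(config.rest_duration * fs)))
    rest_block = np.repeat(_rest_frame(joints)[None], n_rest, axis=0)

    blocks = [rest_block]
    metas = []
    cursor = n_rest
    for rep in range(1, config.n_repetitions + 1):
        dur = rng.normal(template.duration_mean * timing_scale, template.duration_sd)
        dur = float(np.clip(dur, 0.5 * template.duration_mean, 2.0 * template.duration_mean))
        amp = amplitude_scale * float(np.clip(rng.normal(1.0, sv / 2), 0.7, 1.4))
        block = _repetition_block(template, dur, amp, rng, joints, fs)
        blocks.append(block)
        metas.append(SegmentMeta(
            subject_id=subject_id,
            action_id=template.action_id,
            repetition_index=rep,
            start_frame=cursor,
            end_frame=cursor + block.shape[0],
        ))
        cursor += block.shape[0]
        blocks.append(rest_block)
        cursor += n_rest
    profile = MotionProfile(np.concatenate(blocks, axis=0), fs, joints)
    return profile, metas


def _session_plan(config: ProtocolConfig, templates):
    """Deterministic per-session (subject, template, seed, scales) plan."""
    if templates is None:
        templates = default_templates()
    ids = sorted(templates.keys(), key=lambda a: int(a[1:]))[: config.n_actions]
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)
    for si, sseq in enumerate(subject_seqs):
        subject_id = f"T{si + 1}"
        srng = np.random.default_rng(sseq)
        amp = float(np.clip(srng.normal(1.0, config.subject_variability), 0.6, 1.6))
        tim = float(np.clip(srng.normal(1.0, config.subject_variability), 0.6, 1.6))
        session_seeds = sseq.generate_state(config.n_actions + 1)[1:] & 0x7FFFFFFF
        for ai, aid in enumerate(ids):
            yield subject_id, templates[aid], int(session_seeds[ai]), amp, tim


def iter_sessions(
    config: ProtocolConfig,
    templates: Optional[dict[str, ActionTemplate]] = None,
    joints: tuple[str, ...] = DEFAULT_JOINTS,
) -> Iterator[tuple[MotionProfile, list[SegmentMeta]]]:
    """Stream the dataset one session at a time (constant memory)."""
    for subject_id, template, seed, amp, tim in _session_plan(config, templates):
        yield generate_session(template, config, subject_id, seed,
                               amplitude_scale=amp, timing_scale=tim, joints=joints)


def generate_dataset(
    config: ProtocolConfig,
    templates: Optional[dict[str, ActionTemplate]] = None,
    joints: tuple[str, ...] = DEFAULT_JOINTS,
) -> tuple[list[MotionProfile], list[SegmentMeta]]:
    """Materialize all n_subjects x n_actions sessions.

    Total ground-truth segments = n_subjects x n_actions x
    n_repetitions.  For full-protocol scales prefer
    :func:`iter_sessions`: 640 sessions of ~20 MB each do not fit in
    memory at once.
    """
    profiles, metas = [], []
    for profile, session_metas in iter_sessions(config, templates, joints):
        profiles.append(profile)
        metas.extend(session_metas)
    return profiles, metas


def add_noise(
    profile: MotionProfile, pct: float, seed: int, base: str = "rms"
) -> MotionProfile:
    """Superimpose zero-mean Gaussian noise scaled per channel.

    The noise standard deviation for each joint/data-type/axis channel
    is (pct / 100) times that channel's root-mean-square value over the
    profile (or its value range with ``base="range"``).
    """
    if pct < 0:
        raise ValidationError("noise percentage cannot be negative")
    if base not in ("rms", "range"):
        raise ValidationError("noise base must be 'rms' or 'range'")
    if pct == 0:
        return profile.copy()
    v = profile.values
    if base == "rms":
        scale = np.sqrt(np.mean(v**2, axis=0))
    else:
        scale = v.max(axis=0) - v.min(axis=0)
    rng = np.random.default_rng(seed)
    noisy = v + rng.normal(0.0, 1.0, v.shape) * (pct / 100.0) * scale
    return MotionProfile(noisy, profile.sample_rate, profile.joints)
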