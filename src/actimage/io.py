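"""Reading and writing the package's interchange formats.

Motion tables are CSV files with a leading ``time`` column followed by
one column per joint/data-type/axis combination, named
``{joint}.{dtype}.{axis}`` (dtype in pos, vel, acc, ori, angvel,
angacc; axis in x, y, z).  A JSON sidecar next to the CSV records the
sample rate, joint order and optional labels; the sidecar's sample
rate is authoritative and the time column is derived from it.

Action images are written both as 8-bit PNG (value v stored as
round(255 v)) and, on request, as a float-preserving delimited text
file so training pipelines need not pay the quantization cost.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError, ValidationError
from .image import ActionImage
from .profile import AXES, DATA_TYPES, MotionProfile, SegmentMeta

#: Relative tolerance for time-axis uniformity checks.
TIME_RTOL = 1e-6


def motion_table_columns(joints) -> list[str]:
    """Deterministic CSV column order for a joint list."""
    return ["time"] + [f"{j}.{d}.{a}" for j in joints for d in DATA_TYPES for a in AXES]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_motion_table(profile: MotionProfile, path, meta: dict | None = None) -> None:
    """Write a motion profile as CSV plus JSON sidecar.

    ``meta`` may carry extra sidecar entries (e.g. subject_id,
    action labels, ground-truth segments).
    """
    path = Path(path)
    cols = motion_table_columns(profile.joints)
    flat = profile.values.reshape(profile.n_frames, -1)
    df = pd.DataFrame(
        np.column_stack([profile.times, flat]), columns=cols
    )
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "sample_rate": profile.sample_rate,
        "joints": list(profile.joints),
        "frames": profile.n_frames,
    }
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_motion_table(path) -> MotionProfile:
    """Read a motion table written by :func:`write_motion_table`.

    Raises
    ------
    FormatError
        If a required column is missing (names the first absent one)
        or the sidecar is absent/inconsistent.
    SamplingError
        If the time column is not uniform within ``TIME_RTOL``.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar {side}")
    sidecar = json.loads(side.read_text())
    sample_rate = float(sidecar["sample_rate"])
    joints = tuple(sidecar["joints"])

    df = pd.read_csv(path)
    expected = motion_table_columns(joints)
    present = set(df.columns)
    for col in expected:
        if col not in present:
            raise FormatError(f"motion table {path} is missing required column {col!r}")

    t = df["time"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        nominal = 1.0 / sample_rate
        if np.any(np.abs(dt - nominal) > TIME_RTOL * max(nominal, 1.0)):
            raise SamplingError(
                f"time column of {path} is not uniform at {sample_rate} Hz"
            )
    values = df[expected[1:]].to_numpy(dtype=float).reshape(len(df), len(joints), 6, 3)
    return MotionProfile(values, sample_rate, joints)


# -- segment metadata ---------------------------------------------------

def write_segments(metas, path) -> None:
    Path(path).write_text(
        json.dumps([m.to_dict() for m in metas], indent=1)
    )


def read_segments(path) -> list[SegmentMeta]:
    return [SegmentMeta.from_dict(d) for d in json.loads(Path(path).read_text())]


# -- action images ------------------------------------------------------

def write_action_image(image: ActionImage, path, float_path=None) -> None:
    """Write an action image as 8-bit PNG, optionally also as float text.

    Pixel value v in [0, 1] is stored as round(255 v).  ``float_path``,
    if given, receives a delimited text dump that round-trips exactly.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.min() < 0 or px.max() > 1:
        raise ValidationError(
            f"pixel values must lie in [0, 1], got range [{px.min():g}, {px.max():g}]"
        )
    quantized = np.rint(px * 255).astype(np.uint8)
    iio.imwrite(Path(path), quantized)
    if float_path is not None:
        write_action_image_text(image, float_path)


def read_action_image(path) -> ActionImage:
    """Read a PNG action image back to floats in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:  # grayscale PNG of a constant image
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return ActionImage(pixels=arr[:, :, :3].astype(float) / 255.0)


def write_action_image_text(image: ActionImage, path) -> None:
    """Float-preserving text dump: header line ``H W``, then H rows of 3W floats."""
    px = np.asarray(image.pixels, dtype=float)
    h, w, _ = px.shape
    with open(path, "w") as fh:
        fh.write(f"# {h} {w}\n")
        np.savetxt(fh, px.reshape(h, w * 3), fmt="%.17g")


def read_action_image_text(path) -> ActionImage:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '# H W' header line")
        h, w = (int(x) for x in header[1:].split())
        flat = np.loadtxt(fh, ndmin=2)
    if flat.shape != (h, w * 3):
        raise FormatError(f"{path}: body shape {flat.shape} does not match header {h}x{w}")
    return ActionImage(pixels=flat.reshape(h, w, 3))
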