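"""Classification metrics and the three experiment harnesses.

Per-class metrics are one-vs-rest: for class k, TP/TN/FP/FN are
counted by treating k as positive and every other class as negative,
and accuracy = (TP + TN) / (TP + TN + FP + FN), precision =
TP / (TP + FP), recall = TP / (TP + FN), F1 = 2 P R / (P + R).  Macro
values are unweighted means over classes.

The harnesses run warped-vs-normal, joint-subset and noise-sensitivity
comparisons end to end on synthetic data; within each harness the
folds, seeds and model specification are held fixed so that the only
varying factor is the named experimental variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix

from .classifier import ModelSpec, TrainConfig, train
from .errors import ConfigurationError, ValidationError
from .image import NormalizationSpec, render_action_image
from .profile import (
    ACTION_IDS,
    DEFAULT_JOINTS,
    MotionProfile,
    REDUCED_4,
    REDUCED_8,
    SegmentMeta,
)
from .synthetic import ProtocolConfig, add_noise, iter_sessions
from .warp import build_warp_map, resample_profile, warp_profile
from .segmentation import representative_velocity


# -- metrics ------------------------------------------------------------

@dataclass
class ClassificationReport:
    confusion: np.ndarray                      # rows true, cols predicted
    per_class: dict[str, np.ndarray]           # tp/tn/fp/fn + 4 metrics
    macro: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
            "macro": self.macro,
        }


def compute_report(true_labels, predicted_labels, n_classes: int) -> ClassificationReport:
    """One-vs-rest classification report from label sequences."""
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label sequences must have equal length")
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValidationError(f"{name} label outside [0, {n_classes})")

    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def _safe(num, den, what):
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if not ok.all():
            warnings.warn(
                f"{what}: zero denominator for classes {np.flatnonzero(~ok).tolist()}; "
                "metric reported as 0", stacklevel=3,
            )
        return out

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * precision * recall, precision + recall, "F1")
    accuracy = (tp + tn) / total if total else np.zeros_like(tp)

    per_class = {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": accuracy, "precision": precision,
        "recall": recall, "f1": f1,
    }
    macro = {
        k: float(per_class[k].mean())
        for k in ("accuracy", "precision", "recall", "f1")
    }
    return ClassificationReport(confusion=cm, per_class=per_class, macro=macro)


def report_deltas(a: ClassificationReport, b: ClassificationReport) -> dict[str, float]:
    """Macro-metric differences a - b."""
    return {k: a.macro[k] - b.macro[k] for k in a.macro}


# -- joint subsets ------------------------------------------------------

@dataclass(frozen=True)
class JointSubset:
    name: str
    joints: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.joints:
            raise ConfigurationError("a joint subset cannot be empty")


FULL_23 = JointSubset("full_23", DEFAULT_JOINTS)
SUBSET_8 = JointSubset("reduced_8", REDUCED_8)
SUBSET_4 = JointSubset("reduced_4", REDUCED_4)


# -- dataset assembly ---------------------------------------------------

@dataclass
class SegmentRecord:
    """One ground-truth unit-action segment cut from a session."""

    segment: MotionProfile
    meta: SegmentMeta

    @property
    def label_index(self) -> int:
        return ACTION_IDS.index(self.meta.action_id)


def collect_segments(config: ProtocolConfig, templates=None,
                     joints=DEFAULT_JOINTS) -> list[SegmentRecord]:
    """Generate sessions and cut them at the ground-truth boundaries."""
    records = []
    for profile, metas in iter_sessions(config, templates, joints):
        for m in metas:
            records.append(SegmentRecord(
                segment=profile.slice_frames(m.start_frame, m.end_frame), meta=m))
    return records


def render_images(
    records: Sequence[SegmentRecord],
    n_rows: int,
    warp: bool = True,
    joints: Optional[Sequence[str]] = None,
    image_spec: NormalizationSpec = NormalizationSpec(),
    warp_mode: str = "expand_fast",
) -> tuple[np.ndarray, np.ndarray]:
    """Render segments to an image batch (N, n_rows, 6*n_joints, 3) + labels.

    With ``warp=True`` each segment is time-warped by its own
    representative velocity before rendering; otherwise it is uniformly
    resampled.  ``joints`` restricts the columns to a subset (the
    segment still carries all joints, so the representative velocity is
    unchanged).
    """
    xs, ys = [], []
    for rec in records:
        seg = rec.segment
        if warp:
            vel = representative_velocity(seg)
            wmap = build_warp_map(vel, mode=warp_mode)
            warped = warp_profile(seg if joints is None else seg.select_joints(joints),
                                  wmap, n_rows)
        else:
            warped = resample_profile(
                seg if joints is None else seg.select_joints(joints), n_rows)
        img = render_action_image(warped, image_spec, label=rec.meta.action_id)
        xs.append(img.pixels)
        ys.append(rec.label_index)
    x = np.asarray(xs, dtype=np.float32)
    y_raw = np.asarray(ys, dtype=int)
    # compact labels to 0..k-1 preserving action-id order
    classes = np.unique(y_raw)
    y = np.searchsorted(classes, y_raw)
    return x, y


def _spec_for(x: np.ndarray, spec: ModelSpec, n_classes: int) -> ModelSpec:
    return ModelSpec(
        input_shape=(x.shape[1], x.shape[2], x.shape[3]),
        conv_channels=spec.conv_channels,
        kernel_sizes=spec.kernel_sizes,
        hidden_units=spec.hidden_units,
        n_classes=n_classes,
    )


def _evaluate(x, y, spec: ModelSpec, config: TrainConfig) -> ClassificationReport:
    n_classes = int(y.max()) + 1
    result = train(x, y, _spec_for(x, spec, n_classes), config)
    if config.split == "five_fold_cv":
        mask = result.oof_labels >= 0
    else:
        mask = np.zeros(len(y), dtype=bool)
        mask[result.folds[0].val_indices] = True
    return compute_report(y[mask], result.oof_labels[mask], n_classes)


# -- harnesses ----------------------------------------------------------

def run_warp_comparison(
    records: Sequence[SegmentRecord],
    spec: ModelSpec,
    config: TrainConfig,
    n_rows: int = 64,
    joints: Optional[Sequence[str]] = None,
) -> dict:
    """Paired normal-vs-warped evaluation with identical folds and seeds."""
    x_norm, y = render_images(records, n_rows, warp=False, joints=joints)
    x_warp, y2 = render_images(records, n_rows, warp=True, joints=joints)
    assert np.array_equal(y, y2)
    normal = _evaluate(x_norm, y, spec, config)
    warped = _evaluate(x_warp, y, spec, config)
    return {
        "normal": normal,
        "warped": warped,
        "deltas": report_deltas(warped, normal),
    }


def run_joint_subset_experiment(
    records: Sequence[SegmentRecord],
    subsets: Sequence[JointSubset],
    spec: ModelSpec,
    config: TrainConfig,
    n_rows: int = 64,
) -> dict[str, ClassificationReport]:
    """Re-render per subset (image width 6 x |subset|) and evaluate each."""
    available = records[0].segment.joints if records else ()
    out = {}
    for subset in subsets:
        for j in subset.joints:
            if j not in available:
                raise ConfigurationError(
                    f"subset {subset.name!r} names joint {j!r} absent from the data")
        x, y = render_images(records, n_rows, warp=True, joints=subset.joints)
        out[subset.name] = _evaluate(x, y, spec, config)
    return out


def run_sensitivity_experiment(
    records: Sequence[SegmentRecord],
    noise_levels: Sequence[float],
    spec: ModelSpec,
    config: TrainConfig,
    n_rows: int = 64,
    joints: Optional[Sequence[str]] = None,
    noise_seed: int = 0,
) -> dict[float, ClassificationReport]:
    """Evaluate under Gaussian perturbation of the motion profiles.

    Noise is injected into each segment's motion profile *before*
    warping and image generation, so both the velocity-derived warp map
    and the rendered pixels feel the perturbation.
    """
    if any(lv < 0 for lv in noise_levels):
        raise ValidationError("noise levels cannot be negative")
    out = {}
    for li, level in enumerate(noise_levels):
        if level == 0:
            noisy = list(records)
        else:
            noisy = [
                SegmentRecord(
                    segment=add_noise(rec.segment, level, seed=noise_seed + 104729 * li + ri),
                    meta=rec.meta,
                )
                for ri, rec in enumerate(records)
            ]
        x, y = render_images(noisy, n_rows, warp=True, joints=joints)
        out[level] = _evaluate(x, y, spec, config)
    return out


def confusion_heatmap(report: ClassificationReport, path, class_names=None) -> None:
    """Render the confusion matrix as a heatmap image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.confusion
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm, cmap="viridis")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if class_names is not None:
        ax.set_xticks(range(len(class_names)), class_names, rotation=90, fontsize=6)
        ax.set_yticks(range(len(class_names)), class_names, fontsize=6)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
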