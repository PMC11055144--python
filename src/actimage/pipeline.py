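"""End-to-end pipeline runner with a deterministic artifact manifest.

A single YAML/dict configuration fully determines a run:
simulate -> segment -> warp+imagegen -> train -> evaluate
(-> optional experiments).  Every stage records its parameters and the
SHA-256 checksums of its artifacts in ``manifest.json``; re-running
the same configuration reproduces the manifest bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .classifier import ModelSpec, TrainConfig, save_model, train
from .errors import ActimageError, ConfigurationError
from .evaluation import (
    FULL_23,
    SUBSET_4,
    SUBSET_8,
    SegmentRecord,
    compute_report,
    confusion_heatmap,
    run_joint_subset_experiment,
    run_sensitivity_experiment,
    run_warp_comparison,
)
from .image import NormalizationSpec, render_action_image
from .profile import ACTION_IDS, DEFAULT_JOINTS, REDUCED_4, REDUCED_8, SegmentMeta
from .segmentation import SegmenterParams, representative_velocity, segment_actions
from .synthetic import ProtocolConfig, default_templates, iter_sessions
from .warp import build_warp_map, warp_profile
from . import io as mio

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "protocol", "segmenter", "warp", "image", "joints", "model",
         "training", "experiments", "log_level"},
    "protocol": {"n_subjects", "n_actions", "n_repetitions", "sample_rate",
                 "rest_duration", "subject_variability", "noise_base"},
    "segmenter": {"smoothing_window", "threshold_fraction", "min_duration",
                  "min_gap", "padding"},
    "warp": {"mode", "integration_rule", "n_rows", "enabled"},
    "image": {"scope", "axis_rule", "constant_fill"},
    "model": {"conv_channels", "kernel_sizes", "hidden_units"},
    "training": {"learning_rate", "batch_size", "epochs", "split", "n_folds"},
    "experiments": {"warp_comparison", "joint_subsets", "noise_levels"},
}

_SUBSETS = {"full_23": FULL_23, "reduced_8": SUBSET_8, "reduced_4": SUBSET_4}

_JOINT_SETS = {"full_23": DEFAULT_JOINTS, "reduced_8": REDUCED_8, "reduced_4": REDUCED_4}


def validate_config(config: dict) -> dict:
    """Reject unknown keys at every level; return the config unchanged."""
    def check(section: str, mapping: dict):
        allowed = _SCHEMA[section]
        for key in mapping:
            if key not in allowed:
                raise ConfigurationError(
                    f"unknown configuration key {key!r}"
                    + (f" in section {section!r}" if section else "")
                )
    check("", config)
    for section in config:
        if section in _SCHEMA and section and isinstance(config[section], dict):
            check(section, config[section])
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _array_digest(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute every stage under ``out_dir``; returns the run directory.

    Any stage failure is re-raised with the stage name prepended.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config, "stages": {}}
    seed = int(config.get("seed", 0))
    stage = "configure"
    try:
        protocol = ProtocolConfig(seed=seed, **config.get("protocol", {}))
        seg_params = SegmenterParams(**config.get("segmenter", {}))
        warp_cfg = dict(config.get("warp", {}))
        n_rows = int(warp_cfg.get("n_rows", 64))
        warp_mode = warp_cfg.get("mode", "expand_fast")
        warp_enabled = bool(warp_cfg.get("enabled", True))
        image_spec = NormalizationSpec(**config.get("image", {}))
        joints_key = config.get("joints", "full_23")
        joints = _JOINT_SETS[joints_key] if isinstance(joints_key, str) else tuple(joints_key)
        model_cfg = dict(config.get("model", {}))
        if "conv_channels" in model_cfg:
            model_cfg["conv_channels"] = tuple(model_cfg["conv_channels"])
        if "kernel_sizes" in model_cfg:
            model_cfg["kernel_sizes"] = tuple(model_cfg["kernel_sizes"])
        train_cfg = TrainConfig(seed=seed, **config.get("training", {}))
        templates = default_templates()

        # -- simulate + segment -------------------------------------------
        stage = "simulate"
        sessions_dir = out / "sessions"
        sessions_dir.mkdir(exist_ok=True)
        records: list[SegmentRecord] = []
        session_manifest = []
        for profile, metas in iter_sessions(protocol, templates):
            sid, aid = metas[0].subject_id, metas[0].action_id
            name = f"{sid}_{aid}"
            csv_path = sessions_dir / f"{name}.csv"
            mio.write_motion_table(profile, csv_path,
                                   meta={"subject_id": sid, "action_id": aid})
            stage = "segment"
            vel = representative_velocity(profile)
            intervals = segment_actions(vel, seg_params)
            if len(intervals) != len(metas):
                raise ActimageError(
                    f"session {name}: segmenter found {len(intervals)} segments, "
                    f"expected {len(metas)} (check segmenter parameters)"
                )
            detected = [
                SegmentMeta(sid, aid, i + 1, s, e)
                for i, (s, e) in enumerate(intervals)
            ]
            mio.write_segments(detected, sessions_dir / f"{name}.segments.json")
            for m in detected:
                records.append(SegmentRecord(
                    segment=profile.slice_frames(m.start_frame, m.end_frame), meta=m))
            session_manifest.append({
                "session": name,
                "csv_sha256": _sha256(csv_path),
                "n_segments": len(detected),
            })
            stage = "simulate"
        manifest["stages"]["simulate+segment"] = {
            "protocol": protocol.__dict__,
            "segmenter": seg_params.__dict__,
            "sessions": session_manifest,
            "n_segments": len(records),
        }

        # -- warp + imagegen ----------------------------------------------
        stage = "imagegen"
        images_dir = out / "images"
        images_dir.mkdir(exist_ok=True)
        xs, ys, image_manifest = [], [], []
        for k, rec in enumerate(records):
            seg = rec.segment
            vel = representative_velocity(seg)
            sub = seg.select_joints(joints) if joints != seg.joints else seg
            if warp_enabled:
                wmap = build_warp_map(vel, warp_cfg.get("integration_rule", "trapezoid"),
                                      warp_mode)
                warped = warp_profile(sub, wmap, n_rows)
            else:
                from .warp import resample_profile
                warped = resample_profile(sub, n_rows)
            img = render_action_image(warped, image_spec, label=rec.meta.action_id)
            png = images_dir / f"img_{k:05d}.png"
            txt = images_dir / f"img_{k:05d}.txt"
            mio.write_action_image(img, png, float_path=txt)
            xs.append(img.pixels.astype(np.float32))
            ys.append(ACTION_IDS.index(rec.meta.action_id))
            image_manifest.append({
                "file": png.name, "label": rec.meta.action_id,
                "sha256": _sha256(png),
            })
        (images_dir / "labels.json").write_text(json.dumps(image_manifest, indent=1))
        manifest["stages"]["imagegen"] = {
            "n_rows": n_rows, "mode": warp_mode if warp_enabled else "none",
            "joints": list(joints),
            "labels_sha256": _sha256(images_dir / "labels.json"),
        }

        # -- train ----------------------------------------------------------
        stage = "train"
        x = np.asarray(xs, dtype=np.float32)
        y_raw = np.asarray(ys)
        classes = np.unique(y_raw)
        y = np.searchsorted(classes, y_raw)
        spec = ModelSpec(input_shape=x.shape[1:], n_classes=len(classes), **model_cfg)
        result = train(x, y, spec, train_cfg)
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        weight_digests = []
        for i, fold in enumerate(result.folds):
            save_model(fold.model, spec, models_dir / f"fold_{i}")
            weight_digests.append(_array_digest(fold.model.params))
        (models_dir / "history.json").write_text(
            json.dumps(result.histories, indent=1))
        manifest["stages"]["train"] = {
            "model": {"conv_channels": list(spec.conv_channels),
                      "kernel_sizes": list(spec.kernel_sizes),
                      "hidden_units": spec.hidden_units,
                      "n_classes": spec.n_classes},
            "training": train_cfg.__dict__,
            "weights_sha256": weight_digests,
        }

        # -- evaluate ---------------------------------------------------------
        stage = "evaluate"
        if train_cfg.split == "five_fold_cv":
            mask = result.oof_labels >= 0
        else:
            mask = np.zeros(len(y), dtype=bool)
            mask[result.folds[0].val_indices] = True
        report = compute_report(y[mask], result.oof_labels[mask], len(classes))
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        class_names = [ACTION_IDS[c] for c in classes]
        confusion_heatmap(report, out / "confusion.png", class_names)
        manifest["stages"]["evaluate"] = {
            "macro": report.macro,
            "report_sha256": _sha256(out / "report.json"),
        }

        # -- optional experiments --------------------------------------------
        experiments = config.get("experiments", {})
        if experiments:
            stage = "experiment"
            exp_out = {}
            if experiments.get("warp_comparison"):
                cmp_res = run_warp_comparison(records, spec, train_cfg, n_rows=n_rows)
                exp_out["warp_comparison"] = {
                    "normal": cmp_res["normal"].macro,
                    "warped": cmp_res["warped"].macro,
                    "deltas": cmp_res["deltas"],
                }
            subset_names = experiments.get("joint_subsets") or []
            if subset_names:
                subs = [_SUBSETS[nm] for nm in subset_names]
                sub_res = run_joint_subset_experiment(records, subs, spec,
                                                      train_cfg, n_rows=n_rows)
                exp_out["joint_subsets"] = {nm: r.macro for nm, r in sub_res.items()}
            levels = experiments.get("noise_levels") or []
            if levels:
                sens = run_sensitivity_experiment(records, levels, spec, train_cfg,
                                                  n_rows=n_rows, noise_seed=seed)
                exp_out["noise_levels"] = {str(lv): r.macro for lv, r in sens.items()}
            (out / "experiments.json").write_text(json.dumps(exp_out, indent=1))
            manifest["stages"]["experiment"] = {
                "experiments_sha256": _sha256(out / "experiments.json")}
    except ActimageError as err:
        raise ActimageError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
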