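"""End-to-end pipeline: simulate -> preprocess -> spectrogram -> train -> evaluate.

Each stage reads the previous stage's outputs from the working
directory and records what it produced in a run manifest (config hash,
seeds, per-stage outputs).  Re-running with an unchanged config skips
stages whose outputs already exist under the same config hash, so a
run is resumable and reproducible.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np

from whistlekit.annotations import read_annotations, write_annotations
from whistlekit.audio import load_audio, average_channels, save_wav
from whistlekit.config import PipelineConfig
from whistlekit.evaluate import confusion, metrics_from_counts, roc_auc, run_cv, train_final
from whistlekit.models import (
    TrainingConfig,
    TransferModelSpec,
    VanillaCNNSpec,
    build_transfer_model,
    build_vanilla_cnn,
)
from whistlekit.preprocess import bandpass_filter, detect_cutoffs, remove_transients
from whistlekit.spectrogram import (
    SpectrogramConfig,
    compute_spectrogram,
    label_segments,
    render_grayscale,
    segment_audio,
    to_model_input,
)
from whistlekit.synthetic import NoiseProfile, generate_dataset

STAGES = ("simulate", "preprocess", "spectrogram", "train", "evaluate")

log = logging.getLogger("whistlekit")


class StageInputError(RuntimeError):
    """A stage's required input is missing; names the producing stage."""


def _json_log(stage: str, level: str, message: str, **extra) -> None:
    log.info(json.dumps({"stage": stage, "level": level, "message": message, **extra}))


def _spectrogram_cfg(cfg: PipelineConfig) -> SpectrogramConfig:
    s = cfg.spectrogram
    return SpectrogramConfig(
        window_len=s.window_len,
        window_type=s.window_type,
        hop=s.hop,
        segment_len_s=s.segment_len_s,
        segment_shift_s=s.segment_shift_s,
        f_min=s.f_min,
        f_max=s.f_max,
        db_floor=s.db_floor,
    )


def _model_builder(cfg: PipelineConfig):
    t = cfg.training
    if t.model == "vanilla":
        spec = VanillaCNNSpec(
            conv_blocks=tuple(tuple(b) for b in cfg.vanilla.conv_blocks),
            pool_size=cfg.vanilla.pool_size,
            dropout_rate=cfg.vanilla.dropout_rate,
            dense_sizes=tuple(cfg.vanilla.dense_sizes),
            learning_rate=cfg.vanilla.learning_rate,
        )
        return (lambda seed: build_vanilla_cnn(spec, seed=seed)), spec.learning_rate
    spec = TransferModelSpec(
        backbone=cfg.transfer.backbone,
        head_dense_sizes=tuple(cfg.transfer.head_dense_sizes),
        fine_tune_all=cfg.transfer.fine_tune_all,
        learning_rate=cfg.transfer.learning_rate,
    )
    return (lambda seed: build_transfer_model(spec, seed=seed)), spec.learning_rate


def run_pipeline(cfg: PipelineConfig, stages: tuple = STAGES) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    os.makedirs(cfg.work_dir, exist_ok=True)
    manifest_path = os.path.join(cfg.work_dir, "run_manifest.json")
    chash = cfg.content_hash()
    manifest: dict = {"config_hash": chash, "seed": cfg.seed, "stages": {}}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            prev = json.load(fh)
        if prev.get("config_hash") == chash:
            manifest = prev
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage in manifest["stages"] and manifest["stages"][stage].get("completed"):
            outputs = manifest["stages"][stage].get("outputs", [])
            if all(os.path.exists(os.path.join(cfg.work_dir, o)) for o in outputs):
                _json_log(stage, "info", "skipped (up to date)")
                manifest["stages"][stage]["skipped"] = True
                continue
        t0 = time.time()
        outputs = _STAGE_FNS[stage](cfg)
        manifest["stages"][stage] = {
            "completed": True,
            "skipped": False,
            "outputs": outputs,
            "elapsed_s": round(time.time() - t0, 2),
        }
        _json_log(stage, "info", "completed", outputs=outputs)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_simulate(cfg: PipelineConfig) -> list[str]:
    sim = cfg.simulator
    out = os.path.join(cfg.work_dir, "scenes")
    generate_dataset(
        out,
        n_scenes=sim.n_scenes,
        events_per_scene_range=tuple(sim.events_per_scene),
        snr_range_db=tuple(sim.snr_range_db),
        seed=cfg.seed,
        scene_duration_s=sim.scene_duration_s,
        sample_rate=sim.sample_rate,
        noise=NoiseProfile(
            spectral_slope=sim.spectral_slope,
            transient_rate=sim.transient_rate,
            ship_tonals=tuple(tuple(t) for t in sim.ship_tonals),
            level_db=sim.level_db,
        ),
        write_tensors=False,
    )
    return ["scenes/manifest.json", "scenes/annotations.csv"]


def _stage_preprocess(cfg: PipelineConfig) -> list[str]:
    scenes = os.path.join(cfg.work_dir, "scenes")
    if not os.path.exists(os.path.join(scenes, "manifest.json")):
        raise StageInputError("preprocess needs scene audio; run the 'simulate' stage first")
    out = os.path.join(cfg.work_dir, "preprocessed")
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(scenes, "manifest.json")) as fh:
        scene_manifest = json.load(fh)
    pp = cfg.preprocess
    outputs = []
    for fname in scene_manifest["scenes"]:
        clip = load_audio(os.path.join(scenes, fname))
        clip = average_channels(clip)
        clip = bandpass_filter(clip, pp.band_low_hz, pp.band_high_hz)
        if pp.denoise:
            clip = remove_transients(clip)
        if pp.detect_cutoffs:
            bad = detect_cutoffs(clip)
            with open(os.path.join(out, fname + ".cutoffs.json"), "w") as fh:
                json.dump(bad, fh)
        save_wav(os.path.join(out, fname), clip)
        outputs.append(os.path.join("preprocessed", fname))
    return outputs


def _stage_spectrogram(cfg: PipelineConfig) -> list[str]:
    pre = os.path.join(cfg.work_dir, "preprocessed")
    scenes = os.path.join(cfg.work_dir, "scenes")
    if not os.path.isdir(pre):
        raise StageInputError("spectrogram needs conditioned audio; run 'preprocess' first")
    anns = read_annotations(
        os.path.join(scenes, "annotations.csv"), os.path.join(scenes, "contours.json")
    )
    scfg = _spectrogram_cfg(cfg)
    tensors, labels = [], []
    for fname in sorted(os.listdir(pre)):
        if not fname.endswith(".wav"):
            continue
        clip = load_audio(os.path.join(pre, fname))
        source = os.path.splitext(fname)[0]
        segs = segment_audio(clip, scfg)
        seg_anns = [a for a in anns if a.source_id == source]
        labs = label_segments(segs, seg_anns)
        for seg, lab in zip(segs, labs):
            spec = compute_spectrogram(seg, scfg)
            render_grayscale(spec)
            tensors.append(to_model_input(spec).tensor[:, :, 0])
            labels.append(lab)
    out = os.path.join(cfg.work_dir, "segments.npz")
    np.savez_compressed(
        out, tensors=np.stack(tensors), labels=np.asarray(labels, dtype=np.int64)
    )
    return ["segments.npz"]


def _load_segments(cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    path = os.path.join(cfg.work_dir, "segments.npz")
    if not os.path.exists(path):
        raise StageInputError("training needs segment tensors; run 'spectrogram' first")
    data = np.load(path)
    x = data["tensors"].astype(np.float32)
    x = np.repeat(x[..., np.newaxis], 3, axis=3)
    return x, data["labels"]


def _training_cfg(cfg: PipelineConfig, lr: float) -> TrainingConfig:
    t = cfg.training
    return TrainingConfig(
        learning_rate=lr,
        max_epochs=t.max_epochs,
        batch_size=t.batch_size,
        early_stopping_patience=t.early_stopping_patience,
        validation_fraction=t.validation_fraction,
        seed=cfg.seed,
    )


def _stage_train(cfg: PipelineConfig) -> list[str]:
    x, y = _load_segments(cfg)
    builder, lr = _model_builder(cfg)
    tcfg = _training_cfg(cfg, lr)
    ckpt = os.path.join(cfg.work_dir, "model.npz")
    cv_report = None
    if cfg.training.cv_folds >= 2 and np.bincount(y, minlength=2).min() >= cfg.training.cv_folds:
        cv = run_cv(x, y, builder, tcfg, k=cfg.training.cv_folds, seed=cfg.seed)
        cv_report = {
            "fold_accuracy": cv["fold_accuracy"],
            "mean_accuracy": cv["mean_accuracy"],
            "sd_accuracy": cv["sd_accuracy"],
        }
    model, history = train_final(x, y, builder, tcfg, checkpoint_path=ckpt)
    with open(os.path.join(cfg.work_dir, "training_report.json"), "w") as fh:
        json.dump(
            {
                "cv": cv_report,
                "stopped_epoch": history["stopped_epoch"],
                "best_epoch": history["best_epoch"],
                "final_train_loss": history["train_loss"][-1],
            },
            fh,
            indent=2,
        )
    return ["model.npz", "training_report.json"]


def _stage_evaluate(cfg: PipelineConfig) -> list[str]:
    ckpt = os.path.join(cfg.work_dir, "model.npz")
    if not os.path.exists(ckpt):
        raise StageInputError("evaluation needs a checkpoint; run 'train' first")
    x, y = _load_segments(cfg)
    builder, lr = _model_builder(cfg)
    model = builder(cfg.seed)
    model.load_weights(ckpt)
    scores = model.predict_proba(x)[:, 1]
    pred = (scores >= 0.5).astype(int)
    counts = confusion(y, pred)
    metrics = metrics_from_counts(counts)
    report = {
        "counts": {"tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn},
        "metrics": metrics.as_percent_strings(),
    }
    if len(np.unique(y)) == 2:
        roc = roc_auc(y, scores)
        report["auc"] = roc.auc
        np.savetxt(
            os.path.join(cfg.work_dir, "roc_points.csv"),
            np.column_stack((roc.fpr_points, roc.tpr_points)),
            delimiter=",",
            header="fpr,tpr",
            comments="",
        )
    with open(os.path.join(cfg.work_dir, "evaluation.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return ["evaluation.json"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "spectrogram": _stage_spectrogram,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}
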