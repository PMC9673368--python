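"""End-to-end experiment orchestration.

generate -> split -> augment -> train the zoo -> ensemble -> evaluate ->
Grad-CAM -> triage, driven by one ExperimentConfig and a base seed. Stage
seeds derive deterministically from the base seed (base_seed + repetition
for everything inside a repetition), so the whole output bundle is a pure
function of the config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment as _augment
from . import backbone as _backbone
from . import evaluate as _evaluate
from . import gradcam as _gradcam
from . import synthgen as _synthgen
from . import triage as _triage
from .synthgen import CLASSES

log = logging.getLogger("ovus")

#: config defaults mirror the reference training recipe
_DEFAULTS = {
    "n_per_class": 200,
    "image_size": [64, 64],
    "manifest": None,
    "train_fraction": 0.7,
    "epochs": 30,
    "batch_size": 32,
    "learning_rate": 1e-4,
    "rotation_angles": [30.0, -30.0],
    "enable_flip": True,
    "speckle_variance": 0.05,
    "backbones": list(_backbone.PRESETS),
    "repetitions": 10,
    "weight_factor": 1.5,
    "triage_threshold": 0.86,
    "metric_mode": "as_printed",
    "base_seed": 0,
    "output_dir": "ovus-output",
}


@dataclass(frozen=True)
class ExperimentConfig:
    n_per_class: int = 200
    image_size: tuple[int, int] = (64, 64)
    manifest: str | None = None          # external dataset; overrides synthesis
    train_fraction: float = 0.7
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-4
    rotation_angles: tuple[float, ...] = (30.0, -30.0)
    enable_flip: bool = True
    speckle_variance: float = 0.05
    backbones: tuple[str, ...] = tuple(_backbone.PRESETS)
    repetitions: int = 10
    weight_factor: float = 1.5
    triage_threshold: float = 0.86
    metric_mode: str = "as_printed"
    base_seed: int = 0
    output_dir: str = "ovus-output"

    def training_config(self) -> _backbone.TrainingConfig:
        return _backbone.TrainingConfig(epochs=self.epochs,
                                        batch_size=self.batch_size,
                                        learning_rate=self.learning_rate,
                                        seed=self.base_seed)

    def augmentation_config(self) -> _augment.AugmentationConfig:
        return _augment.AugmentationConfig(
            rotation_angles=tuple(self.rotation_angles),
            enable_flip=self.enable_flip,
            speckle_variance=self.speckle_variance, seed=self.base_seed)

    def backbone_specs(self) -> list[_backbone.BackboneSpec]:
        return [_backbone.PRESETS[name] for name in self.backbones]


def validate_config(raw: dict) -> ExperimentConfig:
    """Fill missing fields with defaults; reject unknown keys and bad values
    with messages naming the offending field."""
    raw = dict(raw or {})
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}

    def _fail(name, msg):
        raise ValueError(f"config field '{name}': {msg}")

    for name in ("n_per_class", "epochs", "batch_size", "repetitions"):
        v = merged[name]
        if not isinstance(v, int) or isinstance(v, bool):
            _fail(name, f"expected an integer, got {v!r}")
    if merged["n_per_class"] < 1:
        _fail("n_per_class", "must be >= 1")
    if merged["epochs"] < 0:
        _fail("epochs", "must be >= 0")
    if merged["batch_size"] < 1:
        _fail("batch_size", "must be >= 1")
    if merged["repetitions"] < 1:
        _fail("repetitions", "must be >= 1")
    if not (0.0 < merged["train_fraction"] < 1.0):
        _fail("train_fraction", "must lie in (0, 1)")
    if merged["learning_rate"] <= 0:
        _fail("learning_rate", "must be positive")
    if merged["speckle_variance"] < 0:
        _fail("speckle_variance", "must be non-negative")
    if merged["weight_factor"] <= 0:
        _fail("weight_factor", "must be positive")
    if not (0.0 <= merged["triage_threshold"] <= 1.0):
        _fail("triage_threshold", "must lie in [0, 1]")
    if merged["metric_mode"] not in ("as_printed", "conventional"):
        _fail("metric_mode", "must be 'as_printed' or 'conventional'")
    size = tuple(int(x) for x in merged["image_size"])
    if len(size) != 2 or min(size) < 32:
        _fail("image_size", "must be (H, W) with H, W >= 32")
    for b in merged["backbones"]:
        if b not in _backbone.PRESETS:
            _fail("backbones", f"unknown preset {b!r}; "
                  f"available: {list(_backbone.PRESETS)}")
    return ExperimentConfig(
        n_per_class=merged["n_per_class"], image_size=size,
        manifest=merged["manifest"],
        train_fraction=float(merged["train_fraction"]),
        epochs=merged["epochs"], batch_size=merged["batch_size"],
        learning_rate=float(merged["learning_rate"]),
        rotation_angles=tuple(float(a) for a in merged["rotation_angles"]),
        enable_flip=bool(merged["enable_flip"]),
        speckle_variance=float(merged["speckle_variance"]),
        backbones=tuple(merged["backbones"]),
        repetitions=merged["repetitions"],
        weight_factor=float(merged["weight_factor"]),
        triage_threshold=float(merged["triage_threshold"]),
        metric_mode=merged["metric_mode"],
        base_seed=int(merged["base_seed"]),
        output_dir=str(merged["output_dir"]))


def load_config(path) -> ExperimentConfig:
    import yaml
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _stage(name, seed, fn, manifest):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        manifest["stages"].append({"stage": name, "seed": seed,
                                   "status": "failed", "error": str(exc)})
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    manifest["stages"].append({"stage": name, "seed": seed, "status": "ok",
                               "seconds": round(time.perf_counter() - t0, 3)})
    return result


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute all stages and write the report bundle under output_dir.

    Returns a dict with the RepetitionSummary, triage curve/report, and the
    paths of everything written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": []}
    paths = {}

    if config.manifest:
        dataset = _stage("load", config.base_seed,
                         lambda: _synthgen.load_dataset(config.manifest),
                         manifest)
    else:
        dataset = _stage("simulate", config.base_seed,
                         lambda: _synthgen.generate_dataset(
                             config.n_per_class, config.image_size,
                             seed=config.base_seed), manifest)

    summary = _stage("train+evaluate", config.base_seed,
                     lambda: _evaluate.repeated_holdout(
                         dataset, config.backbone_specs(),
                         config.training_config(),
                         config.augmentation_config(),
                         repetitions=config.repetitions,
                         train_fraction=config.train_fraction,
                         base_seed=config.base_seed,
                         weight_factor=config.weight_factor,
                         metric_mode=config.metric_mode), manifest)

    paths["metrics"] = out / "metrics_per_repetition.csv"
    summary.to_frame().to_csv(paths["metrics"], index=False)
    paths["summary"] = out / "metrics_summary.csv"
    summary.summary_frame().to_csv(paths["summary"], index=False)
    paths["decisions"] = out / "decisions.csv"
    summary.records.to_csv(paths["decisions"], index=False)

    singles = [n for n in summary.per_rep if not n.startswith("ensemble_")]
    pairs = [(s, singles[0]) for s in summary.per_rep if s.startswith("ensemble_")]
    paths["t_tests"] = out / "t_tests.csv"
    if config.repetitions >= 2:
        ttests = _evaluate.t_test_frame(summary, pairs)
    else:   # a paired t needs at least two repetitions
        ttests = pd.DataFrame(columns=["pair", "t", "df", "p"])
    ttests.to_csv(paths["t_tests"], index=False)

    def _gradcam_stage():
        # one exemplar per class from the last repetition's validation fold
        plan = _synthgen.split_dataset(
            dataset, config.train_fraction,
            seed=config.base_seed + config.repetitions - 1, mode="pooled")
        val = dataset.subset(plan.validation_indices)
        train = dataset.subset(plan.train_indices)
        aug, _ = _augment.build_augmented_training_set(
            train, replace(config.augmentation_config(),
                           seed=config.base_seed + config.repetitions - 1))
        models = []
        for spec in config.backbone_specs():
            m = _backbone.build_backbone(
                spec, seed=config.base_seed + config.repetitions - 1)
            _backbone.train_model(m, aug, replace(
                config.training_config(),
                seed=config.base_seed + config.repetitions - 1))
            models.append(m)
        rows, written = [], []
        for cls in CLASSES:
            exemplar = next(i for i in val.items if i.label == cls)
            per_model = [_gradcam.gradcam_heatmap(m, exemplar, cls)
                         for m in models]
            combined = _gradcam.ensemble_heatmap(per_model)
            for m, hm in zip(models, per_model):
                p = out / f"gradcam_{cls}_{m.name}.png"
                _gradcam.save_heatmap_png(hm, p)
                written.append(p)
                rows.append({"image_id": exemplar.subject_id,
                             "model_ids": m.name, "target_class": cls})
            p = out / f"gradcam_{cls}_ensemble.png"
            _gradcam.save_heatmap_png(combined, p)
            overlay = _gradcam.overlay_heatmap(exemplar, combined, alpha=0.4)
            po = out / f"gradcam_{cls}_ensemble_overlay.png"
            _gradcam.save_overlay_png(overlay, po)
            written += [p, po]
            rows.append({"image_id": exemplar.subject_id,
                         "model_ids": "+".join(m.name for m in models),
                         "target_class": cls})
        pd.DataFrame(rows).to_csv(out / "gradcam_index.csv", index=False)
        return written

    paths["gradcam"] = _stage("gradcam", config.base_seed, _gradcam_stage,
                              manifest)

    def _triage_stage():
        df = summary.records
        ens = df[df["source"] == "ensemble_sum"]
        records = _triage.records_from_frame(
            ens[["image_id", "truth", "predicted", "confidence"]])
        curve = _triage.threshold_sweep(records)
        report = _triage.triage_report(records, config.triage_threshold)
        curve.to_frame().to_csv(out / "triage_curve.csv", index=False)
        with open(out / "triage_report.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        return curve, report

    curve, report = _stage("triage", config.base_seed, _triage_stage, manifest)
    paths["triage_curve"] = out / "triage_curve.csv"
    paths["triage_report"] = out / "triage_report.json"

    with open(out / "experiment_log.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {"summary": summary, "triage_curve": curve,
            "triage_report": report, "paths": paths, "log": manifest}
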