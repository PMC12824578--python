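"""Config-driven end-to-end runs: simulate -> CV -> curves -> attributions.

A run is described by a YAML/JSON document with ``generator``, ``model``,
``training``, ``evaluation`` and ``interpret`` sections plus a global seed and
output directory.  Unknown keys are rejected before any work starts.  The
global seed fans out to per-stage seeds through a CRC32 hash of the stage
name, so each stage is independently reproducible and two runs with the same
config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (GeneratorConfig, read_cohort, simulate, write_cohort)
from .evaluation import (MODEL_KINDS, calibration_curve, cross_validate,
                         decision_curve)
from .interpret import aggregate_attributions
from .model import HEAD_NAMES, ModelConfig, save_checkpoint
from .preprocessing import (compute_class_weights, fit_standardizer, transform)
from .training import TrainConfig, train_model

__all__ = ["RunConfig", "EvalSection", "InterpretSection", "run_pipeline",
           "load_run_config", "stage_seed"]

PRED_HEAD_COLS = {"live_30": "p_live30", "live_180": "p_live180",
                  "heal_180": "p_heal180"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EvalSection:
    k: int = 5
    strat_on: str = "heal_180"
    threshold: float = 0.5
    models: tuple = MODEL_KINDS
    n_bins: int = 10

    def __post_init__(self):
        unknown = set(self.models) - set(MODEL_KINDS)
        if unknown:
            raise ConfigError(f"unknown model kinds {sorted(unknown)}")


@dataclass(frozen=True)
class InterpretSection:
    enabled: bool = True
    head: str = "heal_180"
    steps: int = 32
    method: str = "ig"


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    data_dir: str | None = None   # load an existing cohort instead of simulating
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalSection = field(default_factory=EvalSection)
    interpret: InterpretSection = field(default_factory=InterpretSection)


_SECTION_TYPES = {"generator": GeneratorConfig, "model": ModelConfig,
                  "training": TrainConfig, "evaluation": EvalSection,
                  "interpret": InterpretSection}


def _build_section(cls, doc: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    doc = dict(doc)
    for key in ("prevalences", "models"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    return cls(**doc)


def load_run_config(doc_or_path) -> RunConfig:
    """Parse and validate a run config from a YAML/JSON file or dict."""
    if isinstance(doc_or_path, (str, Path)):
        doc = yaml.safe_load(Path(doc_or_path).read_text())
    else:
        doc = dict(doc_or_path)
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in doc.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value or {})
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Documented fan-out: CRC32 of the stage name mixed with the global seed."""
    return int((global_seed * 2654435761 + zlib.crc32(stage.encode()))
               % (2 ** 31))


def _config_hash(config: RunConfig) -> str:
    doc = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full run matrix and write a report directory.

    Outputs: the simulated cohort, per-fold and summary metric tables for
    every requested model kind, pooled ROC/calibration/decision-curve grids
    per head for the MultiStep model, an attribution table, a checkpoint of
    the full-data model, logs and a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log_lines: list[str] = []

    def log(stage: str, **info):
        entry = {"stage": stage, **info}
        log_lines.append(json.dumps(entry))

    t0 = time.time()
    try:
        # ---- data
        if config.data_dir:
            dataset = read_cohort(config.data_dir)
            log("load", source=str(config.data_dir), n=dataset.n_patients)
        else:
            gen = replace(config.generator,
                          seed=stage_seed(config.seed, "simulate"))
            dataset = simulate(gen)
            log("simulate", n=dataset.n_patients, seed=gen.seed)
        write_cohort(dataset, out / "cohort")

        # ---- cross-validation for every requested model kind
        all_metrics, all_summaries, all_preds = [], [], []
        for kind in config.evaluation.models:
            cv = cross_validate(
                dataset, kind, k=config.evaluation.k,
                seed=stage_seed(config.seed, f"cv:{kind}"),
                model_cfg=config.model, train_cfg=config.training,
                strat_on=config.evaluation.strat_on,
                threshold=config.evaluation.threshold)
            all_metrics.append(cv.metrics)
            all_summaries.append(cv.summary)
            all_preds.append(cv.predictions)
            log("cross_validate", model=kind, folds=config.evaluation.k)
        metrics = pd.concat(all_metrics, ignore_index=True)
        summary = pd.concat(all_summaries, ignore_index=True)
        preds = pd.concat(all_preds, ignore_index=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        preds.to_csv(out / "predictions.csv", index=False)

        # ---- pooled curves for the primary model
        primary = ("multistep" if "multistep" in config.evaluation.models
                   else config.evaluation.models[0])
        pooled = preds[preds["model"] == primary]
        curve_rows, cal_rows, dca_rows = [], [], []
        from sklearn.metrics import roc_curve
        for head, pcol in PRED_HEAD_COLS.items():
            p = pooled[pcol].to_numpy()
            y = pooled[head].to_numpy()
            fpr, tpr, thr = roc_curve(y, p)
            curve_rows.append(pd.DataFrame(
                {"head": head, "fpr": fpr, "tpr": tpr, "threshold": thr}))
            cal = calibration_curve(p, y, n_bins=config.evaluation.n_bins)
            cal_rows.append(pd.DataFrame(
                {"head": head, "mean_predicted": cal.mean_predicted,
                 "observed_frequency": cal.observed_frequency}))
            dca = decision_curve(p, y).to_frame()
            dca.insert(0, "head", head)
            dca_rows.append(dca)
        pd.concat(curve_rows, ignore_index=True).to_csv(out / "roc.csv", index=False)
        pd.concat(cal_rows, ignore_index=True).to_csv(out / "calibration.csv", index=False)
        pd.concat(dca_rows, ignore_index=True).to_csv(out / "dca.csv", index=False)
        log("curves", model=primary)

        # ---- full-data model: checkpoint + attributions
        if config.interpret.enabled and primary == "multistep":
            std = fit_standardizer(dataset)
            data_z = transform(dataset, std)
            labels = dataset.labels.as_matrix()
            weights = {h: compute_class_weights(labels[:, j])
                       for j, h in enumerate(HEAD_NAMES)}
            fseed = stage_seed(config.seed, "fullfit")
            params, _ = train_model(
                data_z, replace(config.training, seed=fseed),
                replace(config.model, seed=fseed), weights)
            save_checkpoint(out / "model.ckpt.npz", params, config.model,
                            dataset.schema)
            attr = aggregate_attributions(
                params, data_z, config.interpret.head, config=config.model,
                steps=config.interpret.steps, method=config.interpret.method)
            attr.to_csv(out / "attributions.csv", index=False)
            (out / "standardizer.json").write_text(std.to_json())
            log("interpret", head=config.interpret.head,
                steps=config.interpret.steps)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "config": asdict(config),
            "stage_seeds": {s: stage_seed(config.seed, s)
                            for s in ["simulate", "fullfit"]
                            + [f"cv:{k}" for k in config.evaluation.models]},
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
    finally:
        log_path.write_text("\n".join(log_lines) + "\n")
    return out
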