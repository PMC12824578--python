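"""Metrics, ROC/calibration/decision-curve analysis and the CV harness.

Conventions fixed here (and relied on by tests):

* confusion counts threshold at 0.5 by default, ties at the threshold count
  positive;
* zero-denominator precision/recall/F1 yield 0.0 (flagged);
* AUROC uses the rank (Mann-Whitney) formulation with ties counted 1/2;
  across folds the 95% CI is mean +/- 1.96*SD/sqrt(k);
* net benefit follows the standard Vickers formulation
  ``TP/n - FP/n * p_t/(1-p_t)`` with treat-all/treat-none references;
* every model kind (MultiStep Transformer and baselines) goes through the
  identical fold / standardizer / weight / metric code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortDataset
from .model import HEAD_NAMES, ModelConfig, predict_cohort
from .preprocessing import (compute_class_weights, fit_standardizer,
                            stratified_kfold, transform)
from .training import TrainConfig, train_model

__all__ = ["ConfusionCounts", "confusion_counts", "classification_metrics",
           "roc_auc", "auroc_ci", "brier", "calibration_curve",
           "CalibrationCurve", "decision_curve", "NetBenefitCurve",
           "cross_validate", "CVResult", "MODEL_KINDS"]

MODEL_KINDS = ("multistep", "gru", "tcn", "transformer")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(probs, labels, threshold: float = 0.5) -> ConfusionCounts:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size == 0:
        raise ValueError("cannot compute confusion counts on empty input")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)), fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)), fn=int(np.sum(~pred & pos)))


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, positive-class precision/recall and F1.

    A zero denominator yields 0.0 and is flagged in the ``undefined`` set.
    """
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    accuracy = ratio(c.tp + c.tn, c.n, "accuracy")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "undefined": undefined}


def roc_auc(probs, labels) -> float:
    """AUROC by the rank / Mann-Whitney formulation; ties count 1/2."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUROC undefined: only one class present")
    ranks = rankdata(probs)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auroc_ci(fold_aucs) -> tuple[float, float, float]:
    """(mean, lower, upper) 95% CI via the normal approximation over folds."""
    a = np.asarray([x for x in fold_aucs if np.isfinite(x)], dtype=float)
    mean = float(a.mean())
    half = 1.96 * float(a.std(ddof=1)) / np.sqrt(len(a)) if len(a) > 1 else 0.0
    return mean, mean - half, mean + half


def brier(probs, labels) -> float:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    return float(np.mean((probs - labels) ** 2))


@dataclass
class CalibrationCurve:
    bin_edges: np.ndarray       # n_bins + 1 edges on [0, 1]
    mean_predicted: np.ndarray  # per non-empty bin
    observed_frequency: np.ndarray
    counts: np.ndarray          # length n_bins, sums to n (empty bins = 0)


def calibration_curve(probs, labels, n_bins: int = 10) -> CalibrationCurve:
    """Equal-width reliability curve; empty bins are reported with count 0
    but omitted from the curve arrays."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mean_pred, obs_freq = [], []
    for b in range(n_bins):
        sel = idx == b
        if counts[b] > 0:
            mean_pred.append(probs[sel].mean())
            obs_freq.append(labels[sel].mean())
    return CalibrationCurve(edges, np.asarray(mean_pred),
                            np.asarray(obs_freq), counts)


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "model": self.model,
                             "treat_all": self.treat_all,
                             "treat_none": self.treat_none})


def decision_curve(probs, labels, thresholds=None) -> NetBenefitCurve:
    """Net benefit NB(p_t) = TP/n - FP/n * p_t/(1-p_t) over a threshold grid."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = labels.size
    prevalence = labels.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        c = confusion_counts(probs, labels, threshold=pt)
        nb_model[i] = c.tp / n - c.fp / n * odds[i]
    nb_all = prevalence - (1.0 - prevalence) * odds
    nb_none = np.zeros_like(thresholds)
    return NetBenefitCurve(thresholds, nb_model, nb_all, nb_none)


# ---------------------------------------------------------------------------
# Cross-validation harness

@dataclass
class CVResult:
    metrics: pd.DataFrame      # per (model, head, fold)
    summary: pd.DataFrame      # mean and SD across folds
    predictions: pd.DataFrame  # per-patient validation probabilities


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 7919 + fold * 104729 + 1) % (2 ** 31))


def cross_validate(dataset: CohortDataset, model_kind: str = "multistep",
                   k: int = 5, seed: int = 0,
                   model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   strat_on: str = "heal_180",
                   threshold: float = 0.5) -> CVResult:
    """Stratified k-fold CV with fold-local standardization and class weights.

    Every model kind runs through this same harness: per fold, the
    standardizer and class weights are fitted on the training folds only, the
    model is trained, and all metrics are computed on the held-out fold.
    """
    from .baselines import build_baseline, pad_align, train_baseline  # cycle

    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    folds = stratified_kfold(dataset.labels, k=k, strat_on=strat_on, seed=seed)

    rows, pred_rows = [], []
    for fold in range(k):
        tr = dataset.subset(folds.train_indices(fold))
        va = dataset.subset(folds.val_indices(fold))
        std = fit_standardizer(tr)
        tr_z, va_z = transform(tr, std), transform(va, std)
        labels_tr = tr.labels.as_matrix()
        weights = {head: compute_class_weights(labels_tr[:, j])
                   for j, head in enumerate(HEAD_NAMES)}
        fseed = _fold_seed(seed, fold)
        m_cfg = dc_replace(model_cfg, seed=fseed)
        t_cfg = dc_replace(train_cfg, seed=fseed)

        if model_kind == "multistep":
            params, _ = train_model(tr_z, t_cfg, m_cfg, weights)
            probs = predict_cohort(params, va_z, m_cfg)
        else:
            Xtr = pad_align(tr_z, m_cfg)
            Xva = pad_align(va_z, m_cfg)
            model = build_baseline(model_kind, Xtr.d_max, m_cfg)
            params, _ = train_baseline(model, Xtr.values, labels_tr,
                                       weights, t_cfg)
            probs = np.asarray(model.forward(params, Xva.values))

        labels_va = va.labels.as_matrix()
        for j, head in enumerate(HEAD_NAMES):
            p, y = probs[:, j], labels_va[:, j]
            c = confusion_counts(p, y, threshold=threshold)
            met = classification_metrics(c)
            if len(np.unique(y)) < 2:
                warnings.warn(
                    f"fold {fold}, head {head}: single-class validation fold; "
                    "AUROC undefined, excluded from aggregation")
                auc = np.nan
            else:
                auc = roc_auc(p, y)
            rows.append({"model": model_kind, "head": head, "fold": fold,
                         "accuracy": met["accuracy"],
                         "precision": met["precision"],
                         "recall": met["recall"], "f1": met["f1"],
                         "auroc": auc, "brier": brier(p, y)})
        for i, pid in enumerate(va.patient_ids):
            pred_rows.append({"patient_id": pid, "fold": fold,
                              "model": model_kind,
                              "p_live30": probs[i, 0],
                              "p_live180": probs[i, 1],
                              "p_heal180": probs[i, 2],
                              "live_30": labels_va[i, 0],
                              "live_180": labels_va[i, 1],
                              "heal_180": labels_va[i, 2]})

    metrics = pd.DataFrame(rows)
    metric_cols = ["accuracy", "precision", "recall", "f1", "auroc", "brier"]
    summary = (metrics.groupby(["model", "head"])[metric_cols]
               .agg(["mean", "std"]).reset_index())
    summary.columns = ["model", "head"] + [f"{m}_{s}" for m in metric_cols
                                           for s in ("mean", "sd")]
    return CVResult(metrics, summary, pd.DataFrame(pred_rows))
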