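"""Standardization, zero-imputation, stratified folds and class weights.

Conventions (fixed and relied on by the model and tests):

* per-feature statistics are computed from the *observed* rows of the fitting
  split only, with sample SD (ddof=1); zero-variance features keep SD=1;
* blocks a patient never had are filled with exact zeros *after*
  standardization, so the imputed value is the feature mean on the
  standardized scale;
* folds are stratified on one outcome head (``heal_180`` by default, the
  closest to balanced) or jointly on the feasible label triples;
* class weights use the balanced convention ``w_c = n / (2 n_c)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortDataset, FeatureBlock, OutcomeLabels, LABEL_NAMES

__all__ = ["Standardizer", "fit_standardizer", "transform",
           "stratified_kfold", "compute_class_weights", "ClassWeights",
           "FoldAssignment"]


class PreprocessingError(ValueError):
    pass


@dataclass
class Standardizer:
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]

    def to_json(self) -> str:
        doc = {name: {"mean": self.means[name].tolist(),
                      "sd": self.sds[name].tolist()}
               for name in self.means}
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Standardizer":
        doc = json.loads(text)
        return cls({k: np.asarray(v["mean"]) for k, v in doc.items()},
                   {k: np.asarray(v["sd"]) for k, v in doc.items()})


def fit_standardizer(train: CohortDataset) -> Standardizer:
    """Per-block, per-feature mean and sample SD over observed rows only."""
    means, sds = {}, {}
    for name, block in train.blocks.items():
        rows = block.values[block.observed]
        if rows.shape[0] == 0:
            raise PreprocessingError(
                f"block {name!r} observed for zero training patients; "
                "lower its missing rate or drop the block")
        mean = rows.mean(axis=0)
        if rows.shape[0] > 1:
            sd = rows.std(axis=0, ddof=1)
        else:
            sd = np.zeros(rows.shape[1])
        sd = np.where(sd > 0, sd, 1.0)  # zero-variance features pass through
        means[name], sds[name] = mean, sd
    return Standardizer(means, sds)


def transform(dataset: CohortDataset, s: Standardizer) -> CohortDataset:
    """Z-score observed rows; set every entry of an unobserved block to 0.

    Observation flags are preserved so the model still knows which blocks to
    impute recursively.
    """
    if set(s.means) != set(dataset.blocks):
        raise PreprocessingError(
            "standardizer blocks do not match dataset schema: "
            f"{sorted(s.means)} vs {sorted(dataset.blocks)}")
    blocks = {}
    for name, block in dataset.blocks.items():
        if s.means[name].shape[0] != block.spec.dim:
            raise PreprocessingError(
                f"block {name!r}: standardizer width {s.means[name].shape[0]} "
                f"!= schema dim {block.spec.dim}")
        z = (block.values - s.means[name]) / s.sds[name]
        z[~block.observed] = 0.0
        blocks[name] = FeatureBlock(block.spec, z, block.observed.copy())
    return CohortDataset(dataset.patient_ids, blocks, dataset.labels,
                         list(dataset.schema))


@dataclass
class FoldAssignment:
    fold: np.ndarray  # fold index per patient
    k: int

    def val_indices(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.fold == i)

    def train_indices(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.fold != i)


def _joint_strata(labels: OutcomeLabels) -> np.ndarray:
    # the hierarchy admits 4 label triples: 000, 100, 110, 111
    return labels.live_30 + labels.live_180 + labels.heal_180


def stratified_kfold(labels: OutcomeLabels, k: int = 5,
                     strat_on: str = "heal_180", seed: int = 0) -> FoldAssignment:
    """Deterministic stratified k-fold assignment.

    ``strat_on`` is one outcome head or ``"joint"`` (stratify on the feasible
    label triples).  Per-fold positive counts of the stratification label
    differ from n_pos/k by at most 1.
    """
    if k < 2:
        raise PreprocessingError("k must be >= 2")
    if strat_on == "joint":
        y = _joint_strata(labels)
    elif strat_on in LABEL_NAMES:
        y = getattr(labels, strat_on)
    else:
        raise PreprocessingError(f"unknown stratification label {strat_on!r}")
    classes, counts = np.unique(y, return_counts=True)
    for c, cnt in zip(classes, counts):
        if cnt < k:
            raise PreprocessingError(
                f"class {c} of {strat_on!r} has only {cnt} members (< k={k})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(y), dtype=int)
    for i, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold[val_idx] = i
    return FoldAssignment(fold, k)


@dataclass(frozen=True)
class ClassWeights:
    w0: float
    w1: float


def compute_class_weights(labels: np.ndarray) -> ClassWeights:
    """Balanced convention: w_c = n / (2 n_c), so w0*n0 == w1*n1."""
    labels = np.asarray(labels)
    n = labels.size
    n1 = int(labels.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise PreprocessingError("both classes must be present to weight them")
    return ClassWeights(w0=n / (2.0 * n0), w1=n / (2.0 * n1))
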