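"""Two-phase optimization of the MultiStep Transformer.

Phase 1 ("stepwise") trains each cycle map alone, in temporal order, on its
feature-prediction loss; the prefix it consumes is held constant, so no
gradient reaches earlier maps, the encoder or the head.  Phase 2 trains every
parameter jointly on the class-weighted outcome cross-entropy plus a weighted
sum of the feature-prediction losses.  Adam with a fixed learning rate of
0.001 and 200 total epochs per fold are the defaults.

During training, observed blocks are fed to the encoder as-is (teacher
forcing); cycle predictions replace only genuinely missing blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import value_and_grad

from ._optim import Adam
from .cohort import CohortDataset
from .model import (ModelConfig, complete_sequence, cycle_predict, forward,
                    init_params, model_schema, HEAD_NAMES)
from .preprocessing import ClassWeights

__all__ = ["TrainConfig", "feature_loss", "outcome_loss", "train_model",
           "TrainHistory"]

_EPS = 1e-7


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 200
    warmup_epochs: int = 50       # phase-1 epochs (cycle maps only)
    batch_size: int = 32
    lambda_feat: float = 0.1      # weight of feature losses in phase 2
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if not 0 <= self.warmup_epochs <= self.epochs:
            raise ValueError("warmup_epochs must lie within total epochs")
        if self.lambda_feat < 0:
            raise ValueError("lambda_feat must be nonnegative")


@dataclass
class TrainHistory:
    records: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def feature_loss(predicted, observed_values, observed_mask):
    """Mean squared error over patients whose block is observed (0 if none)."""
    mask = np.asarray(observed_mask, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        return 0.0
    diff = (predicted - observed_values) * mask[:, None]
    return anp.sum(diff ** 2) / (n_obs * observed_values.shape[1])


def outcome_loss(probs, labels, weights: dict):
    """Sum over the three heads of class-weighted binary cross-entropy.

    ``weights`` maps head name to ClassWeights; w1 multiplies positive terms
    and w0 negative terms, and each head's loss is averaged over the batch.
    """
    p = anp.clip(probs, _EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    total = 0.0
    for j, head in enumerate(HEAD_NAMES):
        w = weights[head]
        terms = -(w.w1 * y[:, j] * anp.log(p[:, j])
                  + w.w0 * (1.0 - y[:, j]) * anp.log(1.0 - p[:, j]))
        total = total + anp.mean(terms)
    return total


def _check_finite(value, epoch, component):
    if not np.isfinite(value):
        raise TrainingError(
            f"non-finite loss ({value}) at epoch {epoch} in {component}")


def train_model(train: CohortDataset, train_cfg: TrainConfig,
                model_cfg: ModelConfig,
                class_weights: dict[str, ClassWeights]):
    """Fit the MultiStep Transformer on a standardized training split.

    Returns ``(params, TrainHistory)``.  Deterministic given the two config
    seeds: parameter init draws from ``model_cfg.seed``; batch order and
    dropout masks from ``train_cfg.seed``.
    """
    rng = np.random.default_rng(train_cfg.seed)
    seq = model_schema(train.schema, model_cfg)
    params = init_params(train.schema, model_cfg)
    blocks = {s.name: train.blocks[s.name].values for s in seq}
    observed = {s.name: train.blocks[s.name].observed for s in seq}
    labels = train.labels.as_matrix()
    n = train.n_patients
    temporal = [s.name for s in seq[2:]]
    history = []

    # ---- Phase 1: each cycle map on its own feature loss, prefix constant.
    optimizers = {t: Adam(params["cycle"][t], lr=train_cfg.learning_rate)
                  for t in temporal}
    for epoch in range(train_cfg.warmup_epochs):
        rec = {"epoch": epoch, "phase": 1, "outcome_loss": np.nan}
        # recursively completed sequence under current maps, held constant
        used_const, _, _ = complete_sequence(blocks, observed, params, seq)
        prefix_names = ["ft", "op"]
        for t in temporal:
            prefix_const = [np.asarray(used_const[p]) for p in prefix_names]
            mask = observed[t]

            def loss_fn(cyc_t, _prefix=prefix_const, _t=t, _mask=mask):
                trial = {"cycle": {**params["cycle"], _t: cyc_t},
                         "embed": params["embed"]}
                pred = cycle_predict(_prefix, _t, trial)
                return feature_loss(pred, blocks[_t], _mask)

            value, g = value_and_grad(loss_fn)(params["cycle"][t])
            _check_finite(value, epoch, f"cycle map {t}")
            params["cycle"][t] = optimizers[t].step(params["cycle"][t], g)
            rec[f"feat_loss_{t}"] = float(value)
            prefix_names.append(t)
        rec["total_loss"] = float(np.nansum(
            [rec[f"feat_loss_{t}"] for t in temporal]))
        history.append(rec)

    # ---- Phase 2: joint optimization on outcome + feature losses.
    optimizer = Adam(params, lr=train_cfg.learning_rate)

    def joint_loss(p, idx, drop_rng):
        b = {name: blocks[name][idx] for name in blocks}
        o = {name: observed[name][idx] for name in observed}
        probs, aux = forward(p, b, o, model_cfg, train.schema, train=True,
                             rng=drop_rng, return_aux=True)
        loss = outcome_loss(probs, labels[idx], class_weights)
        if train_cfg.lambda_feat > 0:
            for t in temporal:
                loss = loss + train_cfg.lambda_feat * feature_loss(
                    aux["xhat"][t], b[t], o[t])
        return loss

    joint_vg = value_and_grad(joint_loss)
    for epoch in range(train_cfg.warmup_epochs, train_cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            drop_seed = int(rng.integers(2 ** 31))
            value, g = joint_vg(params, idx, np.random.default_rng(drop_seed))
            _check_finite(value, epoch, "joint loss")
            params = optimizer.step(params, g)
            epoch_losses.append(float(value))
        history.append({"epoch": epoch, "phase": 2,
                        "outcome_loss": float(np.mean(epoch_losses)),
                        "total_loss": float(np.mean(epoch_losses))})

    return params, TrainHistory(history)
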