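"""Comparator sequence models: GRU, TCN and a vanilla transformer.

Mainstream sequence models need rectangular input, so the heterogeneous-width
block sequence is right-padded with zeros to the widest block and missing
blocks become all-zero rows.  All three baselines share the 3-sigmoid outcome
head and the same training loop and are evaluated through the identical
cross-validation harness as the MultiStep Transformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from ._optim import Adam
from .cohort import CohortDataset
from .model import (ModelConfig, _attention, _gelu, _layer_norm, _sigmoid,
                    model_schema)
from .training import TrainConfig, outcome_loss

__all__ = ["PaddedSequence", "pad_align", "build_baseline", "train_baseline",
           "BASELINE_KINDS"]

BASELINE_KINDS = ("gru", "tcn", "transformer")


@dataclass
class PaddedSequence:
    values: np.ndarray      # (n, T, d_max)
    widths: list[int]       # original width per token
    names: list[str]

    @property
    def d_max(self) -> int:
        return self.values.shape[2]

    def unpad(self, token: int) -> np.ndarray:
        """Recover the original (unpadded) values of one token."""
        return self.values[:, token, :self.widths[token]]


def pad_align(dataset: CohortDataset,
              config: ModelConfig | None = None) -> PaddedSequence:
    """Right-pad every block with zeros to the widest block's width.

    Unobserved blocks come out as all-zero rows (consistent with the
    zero-imputation convention of preprocessing.transform).
    """
    config = config or ModelConfig()
    seq = model_schema(dataset.schema, config)
    d_max = max(s.dim for s in seq)
    n = dataset.n_patients
    X = np.zeros((n, len(seq), d_max))
    for i, s in enumerate(seq):
        b = dataset.blocks[s.name]
        X[:, i, :s.dim] = b.values * b.observed[:, None]
    return PaddedSequence(X, [s.dim for s in seq], [s.name for s in seq])


def _glorot(rng, shape):
    return rng.normal(0.0, np.sqrt(2.0 / sum(shape)), size=shape)


class _Baseline:
    """Shared head plumbing; subclasses implement the sequence encoder."""

    def __init__(self, d_input: int, config: ModelConfig):
        self.d_input = d_input
        self.config = config

    def init_params(self) -> dict:
        raise NotImplementedError

    def _head(self, rng, d):
        return {"W": _glorot(rng, (d, 3)), "b": np.zeros(3)}

    def forward(self, params, X, train=False, rng=None):
        raise NotImplementedError


class GRUBaseline(_Baseline):
    """Stacked gated recurrent units; last hidden state feeds the head."""

    def init_params(self):
        rng = np.random.default_rng(self.config.seed)
        d = self.config.d_model
        layers = []
        d_in = self.d_input
        for _ in range(self.config.n_layers):
            layers.append({
                g: _glorot(rng, (d_in, d)) for g in ("Wz", "Wr", "Wh")
            } | {
                g: _glorot(rng, (d, d)) for g in ("Uz", "Ur", "Uh")
            } | {"bz": np.zeros(d), "br": np.zeros(d), "bh": np.zeros(d)})
            d_in = d
        return {"layers": layers, "head": self._head(rng, d)}

    def forward(self, params, X, train=False, rng=None):
        h_seq = X
        for layer in params["layers"]:
            B = h_seq.shape[0]
            h = anp.zeros((B, layer["Uz"].shape[0]))
            outs = []
            for t in range(h_seq.shape[1]):
                x = h_seq[:, t, :]
                z = _sigmoid(anp.dot(x, layer["Wz"]) + anp.dot(h, layer["Uz"]) + layer["bz"])
                r = _sigmoid(anp.dot(x, layer["Wr"]) + anp.dot(h, layer["Ur"]) + layer["br"])
                cand = anp.tanh(anp.dot(x, layer["Wh"]) + anp.dot(r * h, layer["Uh"]) + layer["bh"])
                h = (1.0 - z) * h + z * cand
                outs.append(h)
            h_seq = anp.stack(outs, axis=1)
        last = h_seq[:, -1, :]
        return _sigmoid(anp.dot(last, params["head"]["W"]) + params["head"]["b"])


class TCNBaseline(_Baseline):
    """Causal 1-D convolutions (kernel 2) with dilations 1, 2, 4 over the
    6-step axis; the last step feeds the head."""

    dilations = (1, 2, 4)

    def init_params(self):
        rng = np.random.default_rng(self.config.seed)
        d = self.config.d_model
        layers = []
        d_in = self.d_input
        for _ in self.dilations:
            layers.append({"W_prev": _glorot(rng, (d_in, d)),
                           "W_curr": _glorot(rng, (d_in, d)),
                           "b": np.zeros(d)})
            d_in = d
        return {"layers": layers, "head": self._head(rng, d)}

    def hidden(self, params, X):
        """Final-layer hidden sequence (exposed so causality is checkable)."""
        h = X
        for layer, dil in zip(params["layers"], self.dilations):
            B, T, _ = h.shape
            pad = anp.zeros((B, dil, h.shape[2]))
            shifted = anp.concatenate([pad, h[:, :T - dil, :]], axis=1)
            h = anp.maximum(anp.dot(shifted, layer["W_prev"])
                            + anp.dot(h, layer["W_curr"]) + layer["b"], 0.0)
        return h

    def forward(self, params, X, train=False, rng=None):
        last = self.hidden(params, X)[:, -1, :]
        return _sigmoid(anp.dot(last, params["head"]["W"]) + params["head"]["b"])


class TransformerBaseline(_Baseline):
    """Vanilla transformer: one shared embedding for all (padded) tokens,
    learned positional encoding, the same encoder stack as the MultiStep
    model, but no cycle prediction."""

    n_tokens = 6

    def init_params(self):
        rng = np.random.default_rng(self.config.seed)
        d = self.config.d_model
        params = {"embed": {"W": _glorot(rng, (self.d_input, d)),
                            "b": np.zeros(d)},
                  "pos": 0.02 * rng.standard_normal((self.n_tokens, d)),
                  "layers": []}
        for _ in range(self.config.n_layers):
            params["layers"].append({
                "Wq": _glorot(rng, (d, d)), "bq": np.zeros(d),
                "Wk": _glorot(rng, (d, d)), "bk": np.zeros(d),
                "Wv": _glorot(rng, (d, d)), "bv": np.zeros(d),
                "Wo": _glorot(rng, (d, d)), "bo": np.zeros(d),
                "ln1_g": np.ones(d), "ln1_b": np.zeros(d),
                "W1": _glorot(rng, (d, self.config.d_ff)),
                "b1": np.zeros(self.config.d_ff),
                "W2": _glorot(rng, (self.config.d_ff, d)), "b2": np.zeros(d),
                "ln2_g": np.ones(d), "ln2_b": np.zeros(d),
            })
        params["head"] = self._head(rng, d)
        return params

    def forward(self, params, X, train=False, rng=None):
        Z = anp.dot(X, params["embed"]["W"]) + params["embed"]["b"] + params["pos"]
        for layer in params["layers"]:
            a = _attention(Z, layer, self.config.n_heads)
            Z = _layer_norm(Z + a, layer["ln1_g"], layer["ln1_b"])
            f = anp.dot(_gelu(anp.dot(Z, layer["W1"]) + layer["b1"]),
                        layer["W2"]) + layer["b2"]
            Z = _layer_norm(Z + f, layer["ln2_g"], layer["ln2_b"])
        last = Z[:, -1, :]
        return _sigmoid(anp.dot(last, params["head"]["W"]) + params["head"]["b"])


def build_baseline(kind: str, d_input: int,
                   config: ModelConfig | None = None) -> _Baseline:
    config = config or ModelConfig()
    table = {"gru": GRUBaseline, "tcn": TCNBaseline,
             "transformer": TransformerBaseline}
    if kind not in table:
        raise ValueError(f"unknown baseline kind {kind!r}; choose from {BASELINE_KINDS}")
    return table[kind](d_input, config)


def train_baseline(model: _Baseline, X: np.ndarray, labels: np.ndarray,
                   class_weights: dict, train_cfg: TrainConfig):
    """Adam on the class-weighted outcome loss; same loop for every kind."""
    rng = np.random.default_rng(train_cfg.seed)
    params = model.init_params()
    optimizer = Adam(params, lr=train_cfg.learning_rate)
    n = X.shape[0]

    def loss_fn(p, idx):
        probs = model.forward(p, X[idx])
        return outcome_loss(probs, labels[idx], class_weights)

    vg = value_and_grad(loss_fn)
    history = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            value, g = vg(params, idx)
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite baseline loss at epoch {epoch}")
            params = optimizer.step(params, g)
            losses.append(float(value))
        history.append({"epoch": epoch, "outcome_loss": float(np.mean(losses))})
    return params, history
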