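"""The MultiStep Transformer.

A dynamic prognostic model over a sequence of postoperative feature blocks of
heterogeneous widths.  Three mechanisms cooperate:

1. **Cycle prediction** — for each temporal block t (days 1, 3, 7, 14) an
   affine map ``LR_t`` predicts that block's features from the concatenation
   of the fixed block, the day-of-surgery block and every earlier temporal
   block.  At inference any block beyond the declared prefix is replaced by
   its recursive prediction, so the model accepts any prefix of time points.
2. **Time-sharing embedding** — a per-time-point affine map ``(W_t, d_t)``
   projects each block (width 48, 47, ... 10) to a common model width, giving
   the encoder a rectangular token sequence.
3. **Transformer encoder** — stacked multihead self-attention + feed-forward
   layers over the 6 tokens (no causal mask: the same sequence is query, key
   and value).  The final token's encoding feeds a 3-unit sigmoid head that
   outputs the probabilities of 30-day survival, 180-day survival and 180-day
   favorable functional outcome, in that order.

All forward functions are pure (parameters in, arrays out) and written with
``autograd.numpy`` so the training module can differentiate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .cohort import CohortDataset, TimePointSpec

__all__ = ["ModelConfig", "init_params", "embed_timepoint", "cycle_predict",
           "complete_sequence", "encode", "predict_outcomes", "forward",
           "predict_cohort", "model_schema", "HEAD_NAMES",
           "save_checkpoint", "load_checkpoint", "prefix_flags"]

HEAD_NAMES = ("live_30", "live_180", "heal_180")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    dropout: float = 0.1
    positional_encoding: bool = True
    include_tube: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ModelError("d_model must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ModelError("dropout must be in [0, 1)")


def model_schema(schema: list[TimePointSpec],
                 config: ModelConfig) -> list[TimePointSpec]:
    """The token sequence the model consumes.

    The tube-removal block sits outside the default sequence because its
    timing varies per patient; a config switch appends it as a seventh token.
    """
    names = ["ft", "op", "d1", "d3", "d7", "d14"]
    if config.include_tube:
        names.append("tube")
    by_name = {s.name: s for s in schema}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ModelError(f"schema lacks required blocks: {missing}")
    return [by_name[n] for n in names]


def _temporal_names(seq: list[TimePointSpec]) -> list[str]:
    return [s.name for s in seq if s.name not in ("ft", "op")]


def _glorot(rng, shape):
    scale = np.sqrt(2.0 / (shape[0] + shape[1]))
    return rng.normal(0.0, scale, size=shape)


def init_params(schema: list[TimePointSpec], config: ModelConfig) -> dict:
    """Fresh parameter tree for the given token schema (seeded)."""
    rng = np.random.default_rng(config.seed)
    seq = model_schema(schema, config)
    d = config.d_model
    params: dict = {"embed": {}, "cycle": {}, "layers": [], "head": {}}

    for s in seq:
        params["embed"][s.name] = {"W": _glorot(rng, (s.dim, d)),
                                   "b": np.zeros(d)}
    params["pos"] = 0.02 * rng.standard_normal((len(seq), d))

    prefix_dim = sum(s.dim for s in seq[:2])  # ft + op
    for s in seq[2:]:
        params["cycle"][s.name] = {"W": _glorot(rng, (prefix_dim, s.dim)),
                                   "b": np.zeros(s.dim)}
        prefix_dim += s.dim

    for _ in range(config.n_layers):
        layer = {
            "Wq": _glorot(rng, (d, d)), "bq": np.zeros(d),
            "Wk": _glorot(rng, (d, d)), "bk": np.zeros(d),
            "Wv": _glorot(rng, (d, d)), "bv": np.zeros(d),
            "Wo": _glorot(rng, (d, d)), "bo": np.zeros(d),
            "ln1_g": np.ones(d), "ln1_b": np.zeros(d),
            "W1": _glorot(rng, (d, config.d_ff)), "b1": np.zeros(config.d_ff),
            "W2": _glorot(rng, (config.d_ff, d)), "b2": np.zeros(d),
            "ln2_g": np.ones(d), "ln2_b": np.zeros(d),
        }
        params["layers"].append(layer)

    params["head"] = {"W": _glorot(rng, (d, 3)), "b": np.zeros(3)}
    return params


# ---------------------------------------------------------------------------
# Forward pieces

def embed_timepoint(x, name: str, params) -> anp.ndarray:
    """Affine projection W_t x + d_t of one block to the model width."""
    emb = params["embed"].get(name)
    if emb is None:
        raise ModelError(f"no embedding for block {name!r}")
    if x.shape[-1] != emb["W"].shape[0]:
        raise ModelError(
            f"block {name!r}: input width {x.shape[-1]} does not match "
            f"embedding width {emb['W'].shape[0]}")
    return anp.dot(x, emb["W"]) + emb["b"]


def cycle_predict(prefix: list, name: str, params) -> anp.ndarray:
    """x̂^t = LR_t([ft, op, earlier temporal blocks]) for one temporal block."""
    cyc = params["cycle"].get(name)
    if cyc is None:
        raise ModelError(f"no cycle map for block {name!r}")
    cat = anp.concatenate(prefix, axis=-1)
    if cat.shape[-1] != cyc["W"].shape[0]:
        raise ModelError(
            f"cycle map {name!r}: prefix width {cat.shape[-1]} does not match "
            f"expected {cyc['W'].shape[0]} (gap in the prefix?)")
    return anp.dot(cat, cyc["W"]) + cyc["b"]


def complete_sequence(blocks: dict, observed: dict, params,
                      seq: list[TimePointSpec]):
    """Fill every unobserved temporal block by recursive cycle prediction.

    Returns ``(used, xhat, predicted)``: the per-block arrays actually fed to
    the encoder, the raw cycle predictions for every temporal block (used for
    the feature-prediction loss), and per-block boolean vectors flagging
    patients whose block was substituted.
    """
    for required in ("ft", "op"):
        if required not in blocks:
            raise ModelError(f"block {required!r} must be supplied")
        obs = np.asarray(observed.get(required, True))
        if not np.all(obs):
            raise ModelError(f"block {required!r} must be observed for all patients")

    used = {"ft": blocks["ft"], "op": blocks["op"]}
    prefix = [blocks["ft"], blocks["op"]]
    xhat: dict = {}
    predicted: dict = {}
    for s in seq[2:]:
        t = s.name
        pred = cycle_predict(prefix, t, params)
        xhat[t] = pred
        if t not in observed:
            raise ModelError(f"observation flags missing for block {t!r}")
        obs = np.asarray(observed[t], dtype=bool)
        predicted[t] = ~obs
        if t in blocks:
            take = blocks[t] * obs[:, None] + pred * (~obs)[:, None]
        else:
            take = pred
        used[t] = take
        prefix.append(take)
    return used, xhat, predicted


def _layer_norm(x, g, b, eps=1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return g * (x - mu) / anp.sqrt(var + eps) + b


def _softmax(x):
    m = anp.max(x, axis=-1, keepdims=True)
    e = anp.exp(x - m)
    return e / anp.sum(e, axis=-1, keepdims=True)


def _attention(h, layer, n_heads):
    B, T, d = h.shape
    dh = d // n_heads

    def split(x):  # (B,T,d) -> (B,heads,T,dh)
        return anp.transpose(anp.reshape(x, (B, T, n_heads, dh)), (0, 2, 1, 3))

    q = split(anp.dot(h, layer["Wq"]) + layer["bq"])
    k = split(anp.dot(h, layer["Wk"]) + layer["bk"])
    v = split(anp.dot(h, layer["Wv"]) + layer["bv"])
    scores = anp.einsum("bhtd,bhsd->bhts", q, k) / np.sqrt(dh)
    attn = _softmax(scores)  # every token attends to every token
    out = anp.einsum("bhts,bhsd->bhtd", attn, v)
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (B, T, d))
    return anp.dot(out, layer["Wo"]) + layer["bo"]


def _dropout_masks(config: ModelConfig, shape_tok, rng):
    """Inverted-dropout masks drawn outside the autodiff trace."""
    p = config.dropout
    keep = 1.0 - p
    masks = []
    for _ in range(config.n_layers):
        masks.append((
            (rng.random(shape_tok) < keep) / keep,
            (rng.random(shape_tok) < keep) / keep,
        ))
    return masks


def encode(blocks_used: dict, params, config: ModelConfig,
           seq: list[TimePointSpec], train: bool = False, rng=None):
    """Embed the full block sequence and run the transformer encoder.

    Returns ``(H, Z, z_last)``: the embedded token sequence, the encoder
    output, and the final token's encoding vector.
    """
    tokens = [embed_timepoint(blocks_used[s.name], s.name, params)
              for s in seq]
    H = anp.stack(tokens, axis=1)  # (B, T, d_model)
    if config.positional_encoding:
        H = H + params["pos"]

    drop = None
    if train and config.dropout > 0:
        if rng is None:
            raise ModelError("training-mode dropout needs an rng")
        drop = _dropout_masks(config, H.shape, rng)

    Z = H
    for i, layer in enumerate(params["layers"]):
        a = _attention(Z, layer, config.n_heads)
        if drop is not None:
            a = a * drop[i][0]
        Z = _layer_norm(Z + a, layer["ln1_g"], layer["ln1_b"])
        f = anp.dot(_gelu(anp.dot(Z, layer["W1"]) + layer["b1"]),
                    layer["W2"]) + layer["b2"]
        if drop is not None:
            f = f * drop[i][1]
        Z = _layer_norm(Z + f, layer["ln2_g"], layer["ln2_b"])
    return H, Z, Z[:, -1, :]


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)  # numerically stable on both tails


def _gelu(x):
    # smooth activation (tanh form); smoothness also keeps gradient-path
    # integrals (integrated gradients) well behaved
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608028654
                                     * (x + 0.044715 * x ** 3)))


def predict_outcomes(z_last, params):
    """Three independent sigmoid heads in the order (live_30, live_180, heal_180)."""
    logits = anp.dot(z_last, params["head"]["W"]) + params["head"]["b"]
    return _sigmoid(logits)


def forward(params, blocks: dict, observed: dict, config: ModelConfig,
            schema: list[TimePointSpec], train: bool = False, rng=None,
            return_aux: bool = False):
    """Probability triple for a batch from any missingness pattern.

    ``blocks`` maps block name to an (n, dim) array; ``observed`` maps block
    name to an (n,) boolean vector.  Unobserved blocks are recursively
    cycle-predicted before encoding, so outputs depend only on observed
    values.  With dropout off the call is deterministic.
    """
    seq = model_schema(schema, config)
    used, xhat, predicted = complete_sequence(blocks, observed, params, seq)
    H, Z, z_last = encode(used, params, config, seq, train=train, rng=rng)
    probs = predict_outcomes(z_last, params)
    if return_aux:
        return probs, {"used": used, "xhat": xhat, "predicted": predicted,
                       "H": H, "Z": Z}
    return probs


def save_checkpoint(path, params, config: ModelConfig,
                    schema: list[TimePointSpec]) -> None:
    """Single-archive checkpoint: config + schema as JSON, parameters as
    flattened tensors (numpy .npz)."""
    import json
    from dataclasses import asdict

    flat = {}

    def _flatten(tree, prefix):
        if isinstance(tree, dict):
            for k, v in tree.items():
                _flatten(v, f"{prefix}/{k}")
        elif isinstance(tree, (list, tuple)):
            for i, v in enumerate(tree):
                _flatten(v, f"{prefix}/{i}")
        else:
            flat[prefix] = np.asarray(tree)

    _flatten(params, "params")
    meta = {"config": asdict(config),
            "schema": [{"name": s.name, "dim": s.dim,
                        "order_index": s.order_index} for s in schema],
            "n_layers": config.n_layers}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **flat)


def load_checkpoint(path):
    """Inverse of save_checkpoint; returns (params, config, schema)."""
    import json

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        schema = [TimePointSpec(d["name"], d["dim"], d["order_index"])
                  for d in meta["schema"]]
        params: dict = {"embed": {}, "cycle": {}, "head": {},
                        "layers": [dict() for _ in range(meta["n_layers"])]}
        for key in archive.files:
            if key == "__meta__":
                continue
            parts = key.split("/")[1:]
            if parts[0] == "pos":
                params["pos"] = archive[key]
            elif parts[0] == "layers":
                params["layers"][int(parts[1])][parts[2]] = archive[key]
            else:
                node = params[parts[0]]
                for p in parts[1:-1]:
                    node = node.setdefault(p, {})
                node[parts[-1]] = archive[key]
    return params, config, schema


def prefix_flags(n: int, prefix: str, schema: list[TimePointSpec],
                 config: ModelConfig) -> dict:
    """Observation flags declaring blocks up to ``prefix`` observed, rest not."""
    seq = model_schema(schema, config)
    names = [s.name for s in seq]
    if prefix not in names or prefix == "ft":
        raise ModelError(f"prefix must be one of {names[1:]}, got {prefix!r}")
    cut = names.index(prefix)
    return {name: np.full(n, i <= cut, dtype=bool)
            for i, name in enumerate(names)}


def predict_cohort(params, dataset: CohortDataset, config: ModelConfig,
                   prefix: str | None = None) -> np.ndarray:
    """(n, 3) probabilities for a standardized cohort.

    With ``prefix`` given, blocks beyond it are ignored even if measured
    (dynamic prediction at an earlier time point); otherwise each patient's
    own observation flags drive the imputation.
    """
    blocks = {name: b.values for name, b in dataset.blocks.items()}
    observed = {name: b.observed for name, b in dataset.blocks.items()}
    if prefix is not None:
        # blocks beyond the prefix are masked out; blocks inside the prefix
        # that the patient genuinely lacks stay unobserved (cycle-imputed)
        cut = prefix_flags(dataset.n_patients, prefix, dataset.schema, config)
        observed = {name: (observed[name] & cut[name]) if name in cut
                    else observed[name] for name in observed}
    probs = forward(params, blocks, observed, config, dataset.schema,
                    train=False)
    return np.asarray(probs)
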