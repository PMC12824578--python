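"""MultiStep Transformer forward path: embeddings, cycle prediction,
sequence completion, encoder, heads, and prefix-masked inference."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad

from multistep.cohort import TimePointSpec
from multistep.model import (HEAD_NAMES, ModelConfig, ModelError,
                             complete_sequence, cycle_predict,
                             embed_timepoint, encode, forward, init_params,
                             load_checkpoint, model_schema, predict_cohort,
                             predict_outcomes, prefix_flags, save_checkpoint)
from multistep._optim import tree_leaves

from conftest import TINY_DIMS, tiny_config


def _schema(dims=TINY_DIMS):
    return [TimePointSpec(k, d, i) for i, (k, d) in enumerate(dims.items())]


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig(d_model=8, n_layers=1, n_heads=2, d_ff=16, dropout=0.0,
                       seed=0)


@pytest.fixture(scope="module")
def params(cfg):
    return init_params(_schema(), cfg)


class TestEmbedding:
    def test_zero_input_returns_bias(self, params, cfg):
        params["embed"]["op"]["b"][:] = 1.5
        out = embed_timepoint(np.zeros((2, TINY_DIMS["op"])), "op", params)
        np.testing.assert_allclose(out, 1.5)
        params["embed"]["op"]["b"][:] = 0.0

    def test_all_widths_map_to_d_model(self, params, cfg):
        for name, dim in TINY_DIMS.items():
            if name == "tube":
                continue
            out = embed_timepoint(np.zeros((3, dim)), name, params)
            assert out.shape == (3, cfg.d_model)

    def test_linearity(self, params):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=(2, 2, TINY_DIMS["d1"]))
        lhs = (embed_timepoint(x1 + x2, "d1", params)
               - embed_timepoint(x2, "d1", params))
        rhs = (embed_timepoint(x1, "d1", params)
               - embed_timepoint(np.zeros_like(x1), "d1", params))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_width_mismatch_names_block(self, params):
        with pytest.raises(ModelError, match="d3"):
            embed_timepoint(np.zeros((1, 99)), "d3", params)


class TestCyclePrediction:
    def test_four_cycle_maps_in_default_sequence(self, params):
        assert sorted(params["cycle"]) == ["d1", "d14", "d3", "d7"]

    def test_zero_prefix_returns_bias(self, params):
        params["cycle"]["d1"]["b"][:] = 0.25
        pred = cycle_predict([np.zeros((2, TINY_DIMS["ft"])),
                              np.zeros((2, TINY_DIMS["op"]))], "d1", params)
        np.testing.assert_allclose(pred, 0.25)
        params["cycle"]["d1"]["b"][:] = 0.0

    def test_prefix_gap_detected(self, params):
        with pytest.raises(ModelError, match="prefix"):
            cycle_predict([np.zeros((2, TINY_DIMS["ft"]))], "d1", params)


class TestCompleteSequence:
    def _blocks(self, n=4, seed=0):
        rng = np.random.default_rng(seed)
        return {k: rng.normal(size=(n, d)) for k, d in TINY_DIMS.items()
                if k != "tube"}

    def test_fully_observed_is_identity(self, params, cfg):
        blocks = self._blocks()
        observed = {k: np.ones(4, bool) for k in blocks}
        seq = model_schema(_schema(), cfg)
        used, _, predicted = complete_sequence(blocks, observed, params, seq)
        for k in blocks:
            np.testing.assert_array_equal(np.asarray(used[k]), blocks[k])
        assert not any(p.any() for p in predicted.values())

    def test_ft_op_only_predicts_everything_recursively(self, params, cfg):
        blocks = self._blocks()
        observed = {k: np.full(4, k in ("ft", "op")) for k in blocks}
        seq = model_schema(_schema(), cfg)
        used, xhat, predicted = complete_sequence(blocks, observed, params, seq)
        for t in ("d1", "d3", "d7", "d14"):
            assert predicted[t].all()
            np.testing.assert_array_equal(np.asarray(used[t]),
                                          np.asarray(xhat[t]))

    def test_single_gap_feeds_prediction_into_later_prefix(self, params, cfg):
        """With only d3 missing, d7's cycle input must contain predicted d3."""
        blocks = self._blocks()
        observed = {k: np.ones(4, bool) for k in blocks}
        observed["d3"] = np.zeros(4, bool)
        seq = model_schema(_schema(), cfg)
        used, xhat, predicted = complete_sequence(blocks, observed, params, seq)
        assert predicted["d3"].all()
        assert sum(p.any() for p in predicted.values()) == 1
        # hand-traced recursion: d3hat from observed prefix, then d7hat
        d3hat = cycle_predict([blocks["ft"], blocks["op"], blocks["d1"]],
                              "d3", params)
        np.testing.assert_allclose(np.asarray(used["d3"]), np.asarray(d3hat))
        d7hat = cycle_predict([blocks["ft"], blocks["op"], blocks["d1"],
                               d3hat], "d7", params)
        np.testing.assert_allclose(np.asarray(xhat["d7"]), np.asarray(d7hat))

    def test_unobserved_op_rejected(self, params, cfg):
        blocks = self._blocks()
        observed = {k: np.ones(4, bool) for k in blocks}
        observed["op"] = np.zeros(4, bool)
        with pytest.raises(ModelError, match="op"):
            complete_sequence(blocks, observed, params,
                              model_schema(_schema(), cfg))


class TestEncoder:
    def test_zero_layers_is_identity(self):
        cfg = ModelConfig(d_model=8, n_layers=0, n_heads=2, d_ff=16,
                          dropout=0.0, seed=1)
        params = init_params(_schema(), cfg)
        rng = np.random.default_rng(2)
        blocks = {k: rng.normal(size=(3, d)) for k, d in TINY_DIMS.items()
                  if k != "tube"}
        seq = model_schema(_schema(), cfg)
        H, Z, z_last = encode(blocks, params, cfg, seq)
        np.testing.assert_array_equal(np.asarray(Z), np.asarray(H))
        np.testing.assert_array_equal(np.asarray(z_last), np.asarray(H)[:, -1])

    def test_token_count_and_width_for_arbitrary_schemas(self):
        dims = {"ft": 2, "op": 11, "d1": 7, "d3": 9, "d7": 1, "d14": 4}
        cfg = ModelConfig(d_model=12, n_layers=2, n_heads=3, d_ff=24,
                          dropout=0.0, seed=0)
        schema = _schema(dims)
        params = init_params(schema, cfg)
        rng = np.random.default_rng(1)
        blocks = {k: rng.normal(size=(5, d)) for k, d in dims.items()}
        H, Z, z_last = encode(blocks, params, cfg, model_schema(schema, cfg))
        assert np.asarray(Z).shape == (5, 6, 12)
        assert np.asarray(z_last).shape == (5, 12)


class TestHead:
    def test_zero_parameters_give_half(self, cfg):
        params = {"head": {"W": np.zeros((8, 3)), "b": np.zeros(3)}}
        np.testing.assert_allclose(predict_outcomes(np.zeros((4, 8)), params),
                                   0.5)

    def test_sigmoid_saturation(self):
        params = {"head": {"W": np.eye(3), "b": np.zeros(3)}}
        probs = predict_outcomes(np.array([[20.0, 0.0, -20.0]]), params)
        np.testing.assert_allclose(np.asarray(probs)[0], [1.0, 0.5, 0.0],
                                   atol=1e-8)

    def test_probabilities_bounded(self, params, cfg):
        rng = np.random.default_rng(3)
        probs = np.asarray(predict_outcomes(rng.normal(scale=10, size=(1000, cfg.d_model)),
                                            params))
        assert probs.shape == (1000, 3)
        assert np.all((probs >= 0) & (probs <= 1))


class TestForward:
    def test_prefix_masks_later_blocks_exactly(self, params, cfg):
        rng = np.random.default_rng(4)
        n = 10
        blocks = {k: rng.normal(size=(n, d)) for k, d in TINY_DIMS.items()
                  if k != "tube"}
        schema = _schema()
        observed = prefix_flags(n, "d3", schema, cfg)
        base = np.asarray(forward(params, blocks, observed, cfg, schema))
        tampered = dict(blocks)
        tampered["d7"] = blocks["d7"] + 1e6 * rng.normal(size=blocks["d7"].shape)
        tampered["d14"] = np.full_like(blocks["d14"], -123.0)
        after = np.asarray(forward(params, tampered, observed, cfg, schema))
        assert np.max(np.abs(after - base)) == 0.0

    def test_shortest_and_longest_prefix_both_valid(self, params, cfg):
        rng = np.random.default_rng(5)
        blocks = {k: rng.normal(size=(3, d)) for k, d in TINY_DIMS.items()
                  if k != "tube"}
        schema = _schema()
        for prefix in ("op", "d14"):
            observed = prefix_flags(3, prefix, schema, cfg)
            probs = np.asarray(forward(params, blocks, observed, cfg, schema))
            assert probs.shape == (3, 3)
            assert np.all((probs >= 0) & (probs <= 1))

    def test_deterministic_without_dropout(self, params, cfg):
        rng = np.random.default_rng(6)
        blocks = {k: rng.normal(size=(4, d)) for k, d in TINY_DIMS.items()
                  if k != "tube"}
        schema = _schema()
        observed = prefix_flags(4, "d1", schema, cfg)
        a = np.asarray(forward(params, blocks, observed, cfg, schema))
        b = np.asarray(forward(params, blocks, observed, cfg, schema))
        np.testing.assert_array_equal(a, b)

    def test_gradients_reach_every_embedding_and_cycle_map(self):
        # one attention layer mixes all tokens, so every embedding (not just
        # the final token's) contributes to the head output
        cfg = ModelConfig(d_model=8, n_layers=1, n_heads=2, d_ff=16,
                          dropout=0.0, seed=2)
        schema = _schema()
        params = init_params(schema, cfg)
        rng = np.random.default_rng(7)
        blocks = {k: rng.normal(size=(6, d)) for k, d in TINY_DIMS.items()
                  if k != "tube"}
        observed = {k: np.zeros(6, bool) if k not in ("ft", "op")
                    else np.ones(6, bool) for k in blocks}

        def loss(p):
            probs = forward(p, blocks, observed, cfg, schema)
            return anp.sum(probs ** 2)

        g = grad(loss)(params)
        for name, sub in list(g["embed"].items()) + list(g["cycle"].items()):
            norm = sum(float(np.sum(np.abs(leaf))) for leaf in tree_leaves(sub))
            assert norm > 0, f"dead parameters in {name}"


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, tiny_std_cohort,
                                              tiny_model_cfg, tiny_trained):
        params, _ = tiny_trained
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(path, params, tiny_model_cfg, tiny_std_cohort.schema)
        params2, cfg2, schema2 = load_checkpoint(path)
        assert cfg2 == tiny_model_cfg
        a = predict_cohort(params, tiny_std_cohort, tiny_model_cfg)
        b = predict_cohort(params2, tiny_std_cohort, cfg2)
        np.testing.assert_array_equal(a, b)
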