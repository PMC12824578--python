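"""Losses and the two-phase optimization schedule."""

import numpy as np
import pytest

from multistep.cohort import OutcomeLabels
from multistep.model import HEAD_NAMES, ModelConfig, init_params
from multistep.preprocessing import ClassWeights, compute_class_weights
from multistep.training import (TrainConfig, feature_loss, outcome_loss,
                                train_model)
from multistep._optim import tree_checksum, tree_map

from conftest import make_dataset


UNIT_WEIGHTS = {h: ClassWeights(1.0, 1.0) for h in HEAD_NAMES}


class TestFeatureLoss:
    def test_perfect_prediction_is_zero(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        assert feature_loss(x, x, np.ones(5, bool)) == 0.0

    def test_single_entry_squared_error(self):
        assert feature_loss(np.zeros((1, 1)), np.full((1, 1), 2.0),
                            np.ones(1, bool)) == pytest.approx(4.0)

    def test_mask_restricts_to_observed_rows(self):
        rng = np.random.default_rng(1)
        pred, obs = rng.normal(size=(8, 4)), rng.normal(size=(8, 4))
        mask = np.array([True] * 4 + [False] * 4)
        by_hand = np.mean((pred[:4] - obs[:4]) ** 2)
        assert feature_loss(pred, obs, mask) == pytest.approx(by_hand)

    def test_empty_mask_gives_zero(self):
        assert feature_loss(np.ones((3, 2)), np.zeros((3, 2)),
                            np.zeros(3, bool)) == 0.0


class TestOutcomeLoss:
    def test_half_probabilities_give_log2_per_head(self):
        n = 10
        probs = np.full((n, 3), 0.5)
        labels = np.column_stack([np.arange(n) % 2] * 3)
        loss = outcome_loss(probs, labels, UNIT_WEIGHTS)
        assert loss == pytest.approx(3 * np.log(2))

    def test_confident_correct_predictions_vanish(self):
        labels = np.column_stack([np.ones(4), np.ones(4), np.zeros(4)]).astype(int)
        probs = np.column_stack([np.ones(4), np.ones(4), np.zeros(4)])
        assert outcome_loss(probs, labels, UNIT_WEIGHTS) < 1e-5

    def test_weighted_loss_equals_replication_oracle(self):
        """Balanced class weights n/(2 n_c) reproduce, exactly, the unweighted
        loss on a batch where each minority row is replicated n0/n1 times."""
        rng = np.random.default_rng(2)
        n0, n1 = 60, 20  # integer ratio 3
        y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        labels = np.column_stack([y] * 3)
        probs = rng.uniform(0.05, 0.95, size=(n0 + n1, 3))
        weights = {h: compute_class_weights(y) for h in HEAD_NAMES}
        weighted = outcome_loss(probs, labels, weights)
        reps = np.where(y == 1, n0 // n1, 1)
        idx = np.repeat(np.arange(n0 + n1), reps)
        replicated = outcome_loss(probs[idx], labels[idx], UNIT_WEIGHTS)
        assert weighted == pytest.approx(replicated, abs=1e-12)


def _toy_dataset(n=80, seed=0, signal=2.0):
    rng = np.random.default_rng(seed)
    risk = rng.standard_normal(n)
    dims = {"ft": 2, "op": 4, "d1": 3, "d3": 3, "d7": 2, "d14": 2}
    vals = {k: signal * np.outer(risk, rng.standard_normal(d))
            + rng.standard_normal((n, d)) for k, d in dims.items()}
    y = (risk < 0).astype(int)
    labels = OutcomeLabels(np.ones(n, int), np.maximum(y, y), y)
    return make_dataset(vals, labels)


class TestTrainModel:
    CFG = ModelConfig(d_model=8, n_layers=1, n_heads=2, d_ff=16,
                      dropout=0.1, seed=1)

    def _weights(self, ds):
        y = ds.labels.heal_180
        w = compute_class_weights(y)
        return {"live_30": ClassWeights(1.0, 1.0),
                "live_180": ClassWeights(1.0, 1.0), "heal_180": w}

    def test_outcome_loss_decreases_markedly(self):
        ds = _toy_dataset()
        params, hist = train_model(
            ds, TrainConfig(epochs=40, warmup_epochs=5, seed=0), self.CFG,
            self._weights(ds))
        df = hist.to_frame()
        joint = df[df["phase"] == 2]["outcome_loss"]
        assert joint.iloc[-1] < 0.8 * joint.iloc[0]

    def test_warmup_leaves_encoder_and_head_untouched(self):
        ds = _toy_dataset(seed=3)
        cfg = TrainConfig(epochs=6, warmup_epochs=6, seed=0)
        before = init_params(ds.schema, self.CFG)
        frozen = tree_map(np.copy, {"layers": before["layers"],
                                    "head": before["head"],
                                    "embed": before["embed"],
                                    "pos": before["pos"]})
        params, _ = train_model(ds, cfg, self.CFG, self._weights(ds))
        for key in ("layers", "head", "embed"):
            np.testing.assert_array_equal(tree_checksum(params[key]),
                                          tree_checksum(frozen[key]))
        np.testing.assert_array_equal(params["pos"], frozen["pos"])
        # while the cycle maps did move
        assert tree_checksum(params["cycle"]) != tree_checksum(before["cycle"])

    def test_same_seed_gives_identical_parameters(self):
        ds = _toy_dataset(seed=5)
        cfg = TrainConfig(epochs=8, warmup_epochs=3, seed=11)
        p1, _ = train_model(ds, cfg, self.CFG, self._weights(ds))
        p2, _ = train_model(ds, cfg, self.CFG, self._weights(ds))
        assert tree_checksum(p1) == tree_checksum(p2)

    def test_class_weights_do_not_hurt_minority_recall(self):
        """On a 9:1 task, minority (negative-class) recall with inverse-
        frequency weights is at least as good as without, paired over seeds."""
        from multistep.evaluation import confusion_counts
        from multistep.model import predict_cohort
        rec_w, rec_f = [], []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            n = 120
            risk = rng.standard_normal(n)
            thr = np.quantile(risk, 0.9)
            y = (risk <= thr).astype(int)  # 90% positive
            dims = {"ft": 2, "op": 4, "d1": 3, "d3": 3, "d7": 2, "d14": 2}
            vals = {k: 2.0 * np.outer(risk, rng.standard_normal(d))
                    + rng.standard_normal((n, d)) for k, d in dims.items()}
            ds = make_dataset(vals, OutcomeLabels(np.ones(n, int), y, y))
            t_cfg = TrainConfig(epochs=25, warmup_epochs=5, seed=seed)
            recalls = {}
            for tag, weights in (
                    ("weighted", {h: compute_class_weights(y) if h != "live_30"
                                  else ClassWeights(1.0, 1.0) for h in HEAD_NAMES}),
                    ("flat", UNIT_WEIGHTS)):
                params, _ = train_model(ds, t_cfg, self.CFG, weights)
                probs = predict_cohort(params, ds, self.CFG)
                # minority class is negative: recall of negatives
                c = confusion_counts(1 - probs[:, 2], 1 - y)
                recalls[tag] = c.tp / max(c.tp + c.fn, 1)
            rec_w.append(recalls["weighted"])
            rec_f.append(recalls["flat"])
        assert np.mean(rec_w) >= np.mean(rec_f)

    def test_linear_dynamics_reach_least_squares_floor(self):
        """When day-3 features are an affine map of day-1 features plus small
        noise, phase-1 training should match the least-squares oracle."""
        rng = np.random.default_rng(8)
        n, n_te = 300, 150
        N = n + n_te
        dims = {"ft": 2, "op": 3, "d1": 5, "d3": 4, "d7": 2, "d14": 2}
        vals = {k: rng.standard_normal((N, d)) for k, d in dims.items()}
        A = rng.standard_normal((5, 4)) / np.sqrt(5)
        vals["d3"] = vals["d1"] @ A + 0.1 * rng.standard_normal((N, 4))
        labels = OutcomeLabels(np.ones(N, int), np.ones(N, int),
                               (rng.random(N) < 0.5).astype(int))
        ds = make_dataset(vals, labels)
        tr, te = ds.subset(np.arange(n)), ds.subset(np.arange(n, N))
        params, _ = train_model(
            tr, TrainConfig(epochs=3000, warmup_epochs=3000, seed=0),
            self.CFG, self._weights(tr))
        from multistep.model import cycle_predict
        pred = cycle_predict([te.blocks["ft"].values, te.blocks["op"].values,
                              te.blocks["d1"].values], "d3", params)
        mse = float(np.mean((np.asarray(pred) - te.blocks["d3"].values) ** 2))
        X = np.c_[tr.blocks["ft"].values, tr.blocks["op"].values,
                  tr.blocks["d1"].values, np.ones(n)]
        coef, *_ = np.linalg.lstsq(X, tr.blocks["d3"].values, rcond=None)
        Xte = np.c_[te.blocks["ft"].values, te.blocks["op"].values,
                    te.blocks["d1"].values, np.ones(n_te)]
        floor = float(np.mean((Xte @ coef - te.blocks["d3"].values) ** 2))
        assert mse <= 1.10 * floor
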