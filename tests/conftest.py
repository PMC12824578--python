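import numpy as np
import pytest

from multistep.cohort import (CohortDataset, FeatureBlock, GeneratorConfig,
                              OutcomeLabels, TimePointSpec, simulate)
from multistep.model import HEAD_NAMES, ModelConfig
from multistep.preprocessing import compute_class_weights, fit_standardizer, transform
from multistep.training import TrainConfig, train_model

#: narrow blocks keep model tests fast while exercising every code path
TINY_DIMS = {"ft": 3, "op": 6, "d1": 5, "d3": 5, "d7": 4, "d14": 3, "tube": 2}


def tiny_config(**kw) -> GeneratorConfig:
    base = dict(n_patients=120, dims=dict(TINY_DIMS), signal_strength=2.0,
                seed=7)
    base.update(kw)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort() -> CohortDataset:
    return simulate(tiny_config())


@pytest.fixture(scope="session")
def tiny_std_cohort(tiny_cohort):
    return transform(tiny_cohort, fit_standardizer(tiny_cohort))


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=32,
                       dropout=0.1, seed=3)


@pytest.fixture(scope="session")
def tiny_trained(tiny_std_cohort, tiny_model_cfg):
    """A small trained MultiStep model shared across tests."""
    labels = tiny_std_cohort.labels.as_matrix()
    weights = {h: compute_class_weights(labels[:, j])
               for j, h in enumerate(HEAD_NAMES)}
    t_cfg = TrainConfig(epochs=40, warmup_epochs=10, seed=5)
    params, history = train_model(tiny_std_cohort, t_cfg, tiny_model_cfg,
                                  weights)
    return params, history


def make_dataset(vals: dict, labels: OutcomeLabels,
                 observed: dict | None = None) -> CohortDataset:
    """Hand-built cohort from raw arrays (helper for oracle tests)."""
    n = len(labels)
    schema = [TimePointSpec(k, v.shape[1], i)
              for i, (k, v) in enumerate(vals.items())]
    blocks = {
        s.name: FeatureBlock(
            s, vals[s.name],
            observed.get(s.name, np.ones(n, bool)) if observed
            else np.ones(n, bool))
        for s in schema}
    ids = np.array([f"p{i:04d}" for i in range(n)])
    return CohortDataset(ids, blocks, labels, schema)
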