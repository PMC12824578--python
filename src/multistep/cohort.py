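"""Synthetic postoperative ICH cohorts.

Real cohorts of minimally-invasive-surgery ICH patients record a different set
of covariates at each postoperative time point (day of surgery, days 1, 3, 7,
14, and the day the drainage tube is removed), three hierarchically nested
binary endpoints (30-day survival, 180-day survival, 180-day favorable
functional outcome, mRS 0-3), and block-level missingness that grows at later
time points.  No such cohort is publicly released, so this module generates
seeded surrogates with the same structure:

* one latent risk score per patient drives all three endpoints, which makes
  the hierarchy ``heal_180 <= live_180 <= live_30`` hold by construction;
* every feature loads linearly on the latent risk with per-feature loadings
  drawn once per seed, plus unit Gaussian noise, and block means drift with
  risk over time so the temporal trend itself carries signal;
* block-level observation flags emulate dropout-style missingness concentrated
  at later time points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimePointSpec", "FeatureBlock", "OutcomeLabels", "CohortDataset",
    "GeneratorConfig", "generate_cohort", "apply_missingness",
    "write_cohort", "read_cohort",
    "DEFAULT_DIMS", "TEMPORAL_BLOCKS", "BLOCK_ORDER",
]

#: Canonical block order.  ``ft`` holds fixed patient features (age, sex,
#: history flags); ``op`` the day-of-surgery features; ``d1..d14`` the
#: postoperative days; ``tube`` the drainage-tube-removal-day features, which
#: sit outside the default 6-token model sequence.
BLOCK_ORDER = ("ft", "op", "d1", "d3", "d7", "d14", "tube")
TEMPORAL_BLOCKS = ("d1", "d3", "d7", "d14")

#: Default feature counts per block, matching the reference cohort
#: (48 day-of-surgery features, 47 on days 1 and 3, 46 on day 7, 10 on
#: day 14, 15 on the tube-removal day; fixed-feature width is a choice).
DEFAULT_DIMS = {"ft": 6, "op": 48, "d1": 47, "d3": 47, "d7": 46,
                "d14": 10, "tube": 15}

DEFAULT_PREVALENCES = (0.923, 0.878, 0.523)  # live_30, live_180, heal_180
DEFAULT_MISSING_RATES = {"d1": 0.05, "d3": 0.10, "d7": 0.20, "d14": 0.60,
                         "tube": 0.30}

LABEL_NAMES = ("live_30", "live_180", "heal_180")


class CohortError(ValueError):
    """Configuration or format problem in a cohort."""


@dataclass(frozen=True)
class TimePointSpec:
    name: str
    dim: int
    order_index: int

    def __post_init__(self):
        if self.dim <= 0:
            raise CohortError(f"block {self.name!r}: dim must be positive")


@dataclass
class FeatureBlock:
    spec: TimePointSpec
    values: np.ndarray          # (n_patients, dim)
    observed: np.ndarray        # (n_patients,) bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != self.spec.dim:
            raise CohortError(
                f"block {self.spec.name!r}: values width {self.values.shape} "
                f"does not match spec dim {self.spec.dim}")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise CohortError(
                f"block {self.spec.name!r}: non-finite observed values")


@dataclass
class OutcomeLabels:
    live_30: np.ndarray
    live_180: np.ndarray
    heal_180: np.ndarray

    def __post_init__(self):
        for name in LABEL_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        self.validate()

    def validate(self):
        if not (np.all(self.heal_180 <= self.live_180)
                and np.all(self.live_180 <= self.live_30)):
            raise CohortError(
                "label hierarchy violated: require heal_180 <= live_180 <= live_30")

    def as_matrix(self) -> np.ndarray:
        """(n, 3) int matrix in the fixed head order (live_30, live_180, heal_180)."""
        return np.column_stack([self.live_30, self.live_180, self.heal_180])

    def __len__(self):
        return len(self.live_30)


@dataclass
class CohortDataset:
    patient_ids: np.ndarray
    blocks: dict[str, FeatureBlock]
    labels: OutcomeLabels
    schema: list[TimePointSpec]

    def __post_init__(self):
        n = len(self.patient_ids)
        for b in self.blocks.values():
            if b.values.shape[0] != n or b.observed.shape[0] != n:
                raise CohortError(
                    f"block {b.spec.name!r}: row count differs from cohort size {n}")
        if len(self.labels) != n:
            raise CohortError("label length differs from cohort size")
        names = [s.name for s in self.schema]
        if list(self.blocks) != names:
            raise CohortError("block order does not match schema order")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def block_names(self) -> list[str]:
        return [s.name for s in self.schema]

    def subset(self, idx: np.ndarray) -> "CohortDataset":
        """Row subset (e.g. one cross-validation fold)."""
        blocks = {
            name: FeatureBlock(b.spec, b.values[idx], b.observed[idx])
            for name, b in self.blocks.items()
        }
        labels = OutcomeLabels(self.labels.live_30[idx],
                               self.labels.live_180[idx],
                               self.labels.heal_180[idx])
        return CohortDataset(self.patient_ids[idx], blocks, labels,
                             list(self.schema))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-cohort generator.

    ``prevalences`` are the marginal rates of (live_30, live_180, heal_180);
    they must be non-increasing in that order so the single-latent-risk
    construction can realize the label hierarchy.  ``signal_strength`` scales
    how strongly features load on the latent risk (0 = pure noise).
    """
    n_patients: int = 287
    dims: dict = field(default_factory=lambda: dict(DEFAULT_DIMS))
    prevalences: tuple = DEFAULT_PREVALENCES
    signal_strength: float = 1.0
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    monotone_missingness: bool = True
    include_tube: bool = True
    seed: int = 0

    def __post_init__(self):
        p30, p180, pheal = self.prevalences
        if not (0 < pheal <= p180 <= p30 < 1):
            raise CohortError(
                "prevalences must satisfy 0 < p_heal <= p_live180 <= p_live30 < 1; "
                f"got {self.prevalences}")
        for name, r in self.missing_rates.items():
            if not 0 <= r <= 1:
                raise CohortError(f"missing rate for {name!r} outside [0, 1]")
            if name in ("ft", "op"):
                raise CohortError("ft and op blocks are never missing")
        if self.signal_strength < 0:
            raise CohortError("signal_strength must be nonnegative")

    def schema(self) -> list[TimePointSpec]:
        names = [n for n in BLOCK_ORDER if n != "tube" or self.include_tube]
        return [TimePointSpec(n, int(self.dims[n]), i)
                for i, n in enumerate(names)]


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Draw a fully observed cohort; apply_missingness adds block dropout.

    Deterministic for a given config (seeded); labels derive from one shared
    latent risk score thresholded at the quantiles implied by the configured
    prevalences, so the outcome hierarchy holds for every patient.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    schema = config.schema()

    risk = rng.standard_normal(n)
    # Survival corresponds to LOW risk: patient survives 30 days iff their
    # risk is below the p_live30 quantile of the standard normal, etc.
    thresholds = stats.norm.ppf(config.prevalences)
    live_30 = (risk <= thresholds[0]).astype(int)
    live_180 = (risk <= thresholds[1]).astype(int)
    heal_180 = (risk <= thresholds[2]).astype(int)
    labels = OutcomeLabels(live_30, live_180, heal_180)

    blocks: dict[str, FeatureBlock] = {}
    for spec in schema:
        loadings = rng.standard_normal(spec.dim)
        noise = rng.standard_normal((n, spec.dim))
        drift = 0.1 * spec.order_index  # later blocks track risk more strongly
        values = (config.signal_strength
                  * (np.outer(risk, loadings) + drift * risk[:, None])
                  + noise)
        blocks[spec.name] = FeatureBlock(spec, values, np.ones(n, dtype=bool))

    ids = np.array([f"p{i:05d}" for i in range(n)])
    return CohortDataset(ids, blocks, labels, schema)


def apply_missingness(dataset: CohortDataset,
                      config: GeneratorConfig) -> CohortDataset:
    """Set block-level observation flags for blocks after the day of surgery.

    With ``monotone_missingness`` (default) a single dropout level per patient
    drives all blocks: block t is unobserved iff the patient's uniform draw is
    below that block's rate.  Marginal missingness then matches each
    configured rate exactly in expectation, while patients missing an earlier
    block are never observed at a later block with a higher rate (dropout
    style, e.g. d7 missing implies d14 missing).  With the option off, flags
    are independent Bernoulli per block.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = dataset.n_patients
    blocks = {}
    u_shared = rng.random(n)
    for name, b in dataset.blocks.items():
        rate = config.missing_rates.get(name, 0.0)
        if name in ("ft", "op") or rate == 0.0:
            observed = np.ones(n, dtype=bool)
        elif config.monotone_missingness:
            observed = u_shared >= rate
        else:
            observed = rng.random(n) >= rate
        blocks[name] = FeatureBlock(b.spec, b.values.copy(), observed)
    return CohortDataset(dataset.patient_ids, blocks, dataset.labels,
                         list(dataset.schema))


def simulate(config: GeneratorConfig) -> CohortDataset:
    """generate_cohort followed by apply_missingness."""
    return apply_missingness(generate_cohort(config), config)


# ---------------------------------------------------------------------------
# Plain-text round trip: one CSV per block, a labels CSV, a schema JSON.

def write_cohort(dataset: CohortDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema_doc = [{"name": s.name, "dim": s.dim, "order_index": s.order_index}
                  for s in dataset.schema]
    (directory / "schema.json").write_text(json.dumps(schema_doc, indent=2))

    labels = pd.DataFrame({
        "patient_id": dataset.patient_ids,
        "live_30": dataset.labels.live_30,
        "live_180": dataset.labels.live_180,
        "heal_180": dataset.labels.heal_180,
    })
    labels.to_csv(directory / "labels.csv", index=False)

    for name, b in dataset.blocks.items():
        cols = {f"f{j + 1:03d}": b.values[:, j] for j in range(b.spec.dim)}
        df = pd.DataFrame({"patient_id": dataset.patient_ids,
                           "observed": b.observed.astype(int), **cols})
        df.to_csv(directory / f"block_{name}.csv", index=False)


def read_cohort(directory) -> CohortDataset:
    directory = Path(directory)
    schema_doc = json.loads((directory / "schema.json").read_text())
    schema = [TimePointSpec(d["name"], int(d["dim"]), int(d["order_index"]))
              for d in schema_doc]
    known = set(BLOCK_ORDER)
    for s in schema:
        if s.name not in known:
            raise CohortError(f"unknown block name {s.name!r} in schema")

    labels_df = pd.read_csv(directory / "labels.csv")
    labels = OutcomeLabels(labels_df["live_30"].to_numpy(),
                           labels_df["live_180"].to_numpy(),
                           labels_df["heal_180"].to_numpy())
    ids = labels_df["patient_id"].to_numpy()

    blocks = {}
    for s in schema:
        path = directory / f"block_{s.name}.csv"
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith("f")]
        if len(feat_cols) != s.dim:
            raise CohortError(
                f"block {s.name!r}: schema dim {s.dim} but file has "
                f"{len(feat_cols)} feature columns")
        if not np.array_equal(df["patient_id"].to_numpy(), ids):
            raise CohortError(f"block {s.name!r}: patient order differs from labels")
        blocks[s.name] = FeatureBlock(
            s, df[feat_cols].to_numpy(dtype=float),
            df["observed"].to_numpy().astype(bool))
    return CohortDataset(ids, blocks, labels, schema)
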