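# Methods

This note records the modelling assumptions, the conventions the code pins
down, and the choices made where the design was genuinely open.  It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Patients who undergo minimally invasive evacuation of an intracerebral
hemorrhage are characterized by feature *blocks* recorded at fixed
postoperative time points: a fixed block `ft` (demographics, history), the
day-of-surgery block `op`, and temporal blocks `d1, d3, d7, d14`.  Each
block has its own width (default 6/48/47/47/46/10, matching the feature
counts of the reference cohort), and later blocks are frequently missing at
the *block* level — a day's assessment either happened or it did not.
Cell-level missingness within an observed block is out of scope.  A
drainage-tube-removal block (width 15) is generated and stored but excluded
from the default model sequence, because its timing varies per patient and
it does not belong to the fixed temporal grid; `ModelConfig.include_tube`
appends it as a seventh token with its own embedding and cycle map.

Three binary endpoints are predicted jointly: 30-day survival, 180-day
survival, and 180-day favorable functional outcome (mRS 0–3).  They are
logically nested: a favorable outcome implies 180-day survival, which
implies 30-day survival.

## MultiStep Transformer

* **Cycle prediction.**  `x̂^t = LR_t([x^ft, x^op, …, x^(t−1)])`, one affine
  map per temporal block (four in the default sequence).  The input is the
  concatenation of *all* earlier blocks, not only the immediately preceding
  one: accumulated information is what the recursion is meant to exploit.
  During training, observed blocks enter subsequent prefixes as themselves
  (teacher forcing); predictions substitute only genuinely missing blocks.
* **Embedding.**  Per-time-point affine maps `(W_t, d_t)` to `d_model`.
  A learned positional encoding is added; the time-specific embedding
  parameters already break token symmetry, so the positional term is
  conventional rather than necessary, and can be disabled.
* **Encoder.**  Post-norm transformer layers (multihead self-attention,
  GELU feed-forward, residual + layer normalization).  All six tokens attend
  to all six: predicted tokens participate as if observed, and no causal
  mask is applied.  GELU rather than ReLU keeps the network smooth, which
  the attribution quadrature (below) benefits from.
* **Head.**  The final token's encoding feeds one affine layer with three
  independent sigmoids, output order (live_30, live_180, heal_180).  No
  monotonicity across heads is enforced; the hierarchy is a property of the
  labels, not a constraint on the predictor.
* **Prefix inference.**  `forward` is a function of the declared prefix
  only: blocks beyond it are replaced by cycle predictions regardless of
  any values supplied, which the tests check as exact (bit-level) equality.
  When a prefix is declared for a cohort, blocks *inside* the prefix that a
  patient genuinely lacks remain unobserved and are cycle-imputed rather
  than read as zero-imputed placeholders.

Defaults: `d_model=64, n_layers=2, n_heads=4, d_ff=128, dropout=0.1` —
chosen for a cohort of a few hundred patients where larger encoders
overfit; all exposed in `ModelConfig`.

## Training

Two phases totalling 200 epochs by default (Adam, fixed learning rate
0.001, batch size 32):

1. **Warmup (50 epochs).**  Each cycle map is optimized alone, in temporal
   order, on the MSE of its prediction against patients whose block is
   observed.  The prefix it consumes is recomputed from the current maps
   each epoch but held constant inside the gradient, so no gradient reaches
   earlier maps, and the encoder, embeddings and head are untouched (tested
   as exact equality).
2. **Joint (150 epochs).**  All parameters on
   `outcome_loss + λ · Σ_t feature_loss_t` with `λ = 0.1`.

The exact interleaving of stepwise feature optimization and end-to-end
training is an open design point; a one-time warmup followed by joint
optimization was chosen for simplicity and reproducibility over per-batch
alternation.  The outcome loss is the sum over heads of class-weighted
binary cross-entropy with probabilities clamped to `[1e-7, 1-1e-7]`; the
feature loss is MSE over observed rows (0 if a block is observed for
nobody).  Class weights use the balanced convention `w_c = n/(2 n_c)`,
which makes the weighted loss *exactly* equal to an unweighted loss on a
batch with minority rows replicated by the integer class ratio — the
property the tests pin.

Determinism: parameter initialization draws from `ModelConfig.seed`; batch
order and dropout masks from `TrainConfig.seed`; all generators are
`numpy.random.default_rng`.  With dropout off, repeated forward passes are
bit-identical; two identical pipeline runs produce byte-identical CSVs
(single-threaded numpy).

## Synthetic cohorts

No real cohort is released, so the generator emulates its structure:

* One latent risk `r ~ N(0,1)` per patient.  Labels threshold `r` at the
  standard-normal quantiles of the configured prevalences (defaults
  0.923/0.878/0.523, the reference cohort's observed rates; the 180-day
  survival figure is reported both as 87.8% and 88.8% in different places
  of the source material — the baseline-characteristics value 0.878 is
  used).  A single shared latent guarantees the label hierarchy for every
  patient and induces realistic inter-outcome correlation with one
  parameter.
* Features: `signal_strength · (loading_j · r + 0.1 · order_index · r) +
  N(0,1)`, loadings drawn once per seed.  The drift term makes later blocks
  track risk more strongly, so the temporal trend itself is informative.
  `signal_strength` defaults to 1.0, which yields cross-validated AUROCs in
  the high 0.9s at n≈300 — an idealized, cleanly linear signal; real EHR
  data are noisier, nonlinear and confounded, so passing tests here
  demonstrate mechanics, not clinical performance.
* Missingness: `ft`/`op` always observed.  By default a single per-patient
  uniform draw drives all temporal blocks (block `t` missing iff the draw
  is below its rate), which reproduces each marginal rate exactly in
  expectation while making missingness monotone along the temporal chain
  (dropout behaviour: a patient missing day 7 is also missing day 14).
  Independent per-block Bernoulli flags are available via
  `monotone_missingness=False`.  Default rates 0.05/0.10/0.20/0.60 for
  d1/d3/d7/d14 (0.30 for tube) concentrate absence at later time points.

Not emulated: realistic clinical value ranges for named covariates,
hematoma-volume imaging, real severity-score distributions, informative
(outcome-dependent) missingness.

## Preprocessing conventions

* Standardization statistics come from **observed rows of the fitting split
  only** (sample SD, ddof=1); zero-variance features keep SD 1 rather than
  erroring.  Unobserved blocks are zeroed **after** standardization, so the
  imputed value equals the feature mean on the standardized scale and
  observed-row statistics are uncorrupted.
* Folds are stratified on `heal_180` by default (the closest to balanced
  head); joint stratification over the four feasible label triples is
  available.  Fold-specific standardizers and class weights are refitted
  inside every fold — validation rows never influence them.

## Evaluation conventions

* Confusion threshold 0.5, ties counting positive; zero-denominator
  precision/recall/F1 return 0 and are flagged.
* AUROC by the rank (Mann–Whitney) formulation with average ranks for ties;
  the independent cross-check in the tests is exhaustive pair enumeration
  (and scikit-learn agrees to 1e-12).  Across folds: mean ± 1.96·SD/√k as
  an approximate 95% CI — a convention, not an exact interval.
* Brier score is the plain mean squared error of probabilities; reported
  per fold and pooled (the pooled value corresponds to a single
  cohort-level number).
* Decision curves use the standard net-benefit formulation
  `TP/n − FP/n · p_t/(1−p_t)` with treat-all and treat-none references.
* Calibration uses equal-width bins on [0,1]; empty bins are reported with
  count 0 and omitted from the curve.

## Attributions

Integrated gradients from the all-zero baseline — the model's own
representation of "no information" under zero-imputation — to the patient's
standardized input, on the probability scale by default (logit scale
optional).  The path integral is evaluated with composite Simpson
quadrature over `steps` subintervals; with a smooth (GELU) network this
leaves completeness residuals around 1e-8 at 256 steps, far below what a
midpoint Riemann sum achieves at the same cost.  Gradient×input is
available as a fast approximation.  Raw values of blocks beyond the
inference prefix receive exactly zero attribution, since the forward pass
never reads them.

## Problem sizes in tests and the acceptance script

Unit and property tests run on narrow-block cohorts (widths 2–8) of 60–300
patients with shortened training (6–120 epochs), which exercises every code
path at a fraction of the default cost; the convergence-sensitive checks
use the sizes their property needs (e.g. 4,000 full-batch epochs for the
least-squares-floor comparison, n=500 for signal/null cross-validation,
10,000 patients for prevalence convergence).  The acceptance script uses
the default 287-patient cohort with 60-epoch cross-validation — enough for
the strongly informative synthetic signal to saturate — and n=500 for the
null control so the rare negative classes keep enough members per fold.

## Known limitations

* The networks run on `autograd` over numpy: fine at cohort scale (hundreds
  of patients, 6 tokens), not built for large-scale training.
* Independent sigmoid heads can emit probability triples that violate the
  outcome hierarchy; downstream users wanting coherent triples must
  post-process.
* The two-phase schedule, baseline architectures (sizes matched to the
  MultiStep parameter count within a factor of ~2), DCA formulation, CI
  convention and attribution algorithm are reasonable fixed choices among
  defensible alternatives; all are isolated behind configs or flags.
* Synthetic validation shows the machinery works under its own generative
  assumptions; it says nothing about transportability to real ICH cohorts.
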