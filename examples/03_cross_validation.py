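"""Stratified 5-fold cross-validation of the MultiStep Transformer against
the GRU / TCN / vanilla-transformer comparators.

Every model kind goes through the identical harness: per fold the
standardizer and inverse-frequency class weights are fitted on the training
folds only, then accuracy / precision / recall / F1 / AUROC / Brier are
computed on the held-out fold and aggregated as mean (SD).
"""

from multistep.cohort import GeneratorConfig, simulate
from multistep.evaluation import cross_validate
from multistep.model import ModelConfig
from multistep.training import TrainConfig

dims = {"ft": 4, "op": 12, "d1": 10, "d3": 10, "d7": 8, "d14": 4, "tube": 3}
cohort = simulate(GeneratorConfig(n_patients=250, dims=dims,
                                  signal_strength=1.5, seed=5))
model_cfg = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=32, seed=0)
train_cfg = TrainConfig(epochs=40, warmup_epochs=10, seed=0)

for kind in ("multistep", "gru", "tcn", "transformer"):
    cv = cross_validate(cohort, kind, k=5, seed=2, model_cfg=model_cfg,
                        train_cfg=train_cfg)
    print(f"\n{kind}")
    for _, row in cv.summary.iterrows():
        print(f"  {row['head']:<9} AUROC {row['auroc_mean']:.3f} "
              f"({row['auroc_sd']:.3f})  acc {100 * row['accuracy_mean']:.1f}%"
              f"  F1 {row['f1_mean']:.3f}  Brier {row['brier_mean']:.3f}")

# Mean (SD) across the five validation folds. With informative synthetic
# features every model should beat chance; the MultiStep model additionally
# handles the native block widths and missing blocks without zero-padding.
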