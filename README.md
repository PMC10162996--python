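# survfuse

Multimodal data fusion for cancer survival prediction, with a focus on
**noise resistance**: what happens to a survival model's discrimination and
calibration when uninformative modalities (e.g. additional omics assays) are
added to its input, and how well it can exploit an extremely informative
low-dimensional modality buried among noisy ones.

The package provides, as one testable framework:

* **Eight neural fusion strategies** trained with the Cox partial likelihood
  (Breslow ties): early fusion; intermediate fusion by mean, max,
  concatenation, learned attention, or Embrace (multinomial cell sampling);
  and late fusion by mean or a mixture-of-experts gate — all on a shared
  two-hidden-layer (128/64) skeleton with batch normalization, trained
  full-batch with Adam, plateau scheduling and early stopping.
* **Three statistical baselines**: elastic-net Cox (α = 0.95, CV-selected
  penalty), PriorityLasso (sequential per-block penalized Cox with
  cross-validated unpenalized offsets, priority order from an initial ridge
  step), and an extremely randomized survival forest (scikit-survival
  delegate, group-naive).
* **Survival-function-scale metrics**: Antolini's time-dependent concordance
  and the IPCW integrated Brier score on a truncated grid, with the IBS>1
  replacement rule and Kaplan-Meier fallback for failed models.
* **A benchmark harness**: 5×5 event-stratified cross-validation, paired
  Wilcoxon signed-rank comparisons across datasets with Bonferroni-Holm
  correction, Kaplan-Meier median-risk stratification, and model ranking.
* **A synthetic cohort generator** that emulates multi-omics survival data —
  a mixed-type clinical block, correlated high-dimensional blocks with sparse
  signal, calibrated heavy censoring — plus the two benchmark interventions:
  standard-Gaussian **noise modalities** and the observed-survival-time
  **target leak**.

For every patient, models predict a survival curve S(t|x) = exp(−H0(t)·e^θ)
from a log relative hazard θ and the Breslow baseline cumulative hazard H0.

## Worked example

Train late-mean fusion on a simulated cohort, with and without five
pure-noise modalities:

```python
import numpy as np
from survfuse.simulate import (SimulationConfig, default_blocks,
                               simulate_multiomics_survival, add_noise_modalities)
from survfuse.data import fit_preprocessor, apply_preprocessor
from survfuse.fusion import build_and_train, FusionKind, TrainingConfig, HyperPoint
from survfuse.metrics import antolini_concordance, ibs_time_grid

cfg = SimulationConfig(n=800, blocks=default_blocks(), censoring_rate=0.6, seed=2)
ds = simulate_multiomics_survival(cfg).dataset          # clinical + expression
tr, te = np.arange(300), np.arange(300, 800)

for label, data in [("clinical+gex", ds),
                    ("+5 noise", add_noise_modalities(ds, 5, dim=500, seed=2))]:
    plan = fit_preprocessor(data.subset(tr))
    train, test = apply_preprocessor(plan, data.subset(tr)), apply_preprocessor(plan, data.subset(te))
    model = build_and_train(train, FusionKind.late_mean,
                            TrainingConfig(seed=2), HyperPoint(0.25, 0.01))
    grid = ibs_time_grid(test.outcome)
    c = antolini_concordance(model.predict_survival_curves(test, grid), test.outcome)
    print(f"{label}: Antolini's C = {c:.3f}")
```

```
clinical+gex: Antolini's C = 0.744
+5 noise: Antolini's C = 0.582
```

The held-out concordance drops when five 500-dimensional Gaussian noise
modalities are appended — the noise-resistance failure the framework is built
to measure.  (C = 0.5 is chance level; values in the 0.6–0.75 range are
typical for survival cohorts of this size and censoring.)

The numbered scripts under `analysis/` run the full study at desk scale:
cohort simulation (`01`), the cross-validated model benchmark (`02`), the
noise-resistance sweep over all eight fusion kinds (`03`), the target-leak
experiment (`04`), and Kaplan-Meier risk stratification (`05`); each writes
tidy CSV tables under `results/`.

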