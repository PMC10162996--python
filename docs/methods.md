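# Methods

## Problem setting

`survfuse` studies multimodal integration for right-censored survival
prediction: given M named feature blocks (modalities) X^(m1)…X^(mM) for n
patients and outcomes (T, D) with observed time T and event indicator D, fit
a model of the per-patient log relative hazard θ and evaluate it on the
survival-function scale.  The central scientific question is *noise
resistance*: how a model's discrimination and calibration behave when
uninformative modalities are added to its input, and conversely how well it
exploits an extremely informative low-dimensional modality buried among noisy
ones.

## Survival machinery

All Cox-family models share one likelihood: the negative partial
log-likelihood with the Breslow convention for ties,

    nll(θ) = − Σ_{i: D_i=1} [ θ_i − log Σ_{j: T_j ≥ T_i} exp θ_j ],

with inclusive risk sets (T_j ≥ t) and tied events sharing one denominator.
The implementation max-shifts inside the log-sum-exp; risk sums are floored at
1e−300 so that extreme hazard spreads (the target-leak regime) yield large
finite values rather than overflow.  Survival curves come from the Breslow
baseline estimator H0(t) = Σ_{t_k ≤ t} d_k / Σ_{T_j ≥ t_k} exp θ_j and
S(t|x) = exp(−H0(t) e^θ), evaluated as right-continuous step functions.
Kaplan-Meier estimation (including the censoring-reversed variant used for
IPCW weights) delegates to scikit-survival, as does the two-group log-rank
test.

## Fusion networks

Eight fusion strategies share one skeleton: two hidden layers (128 then 64
units), each linear → batch normalization → ReLU (order chosen; the
alternative BN-after-activation ordering was not explored), and a bias-free
final linear layer emitting θ.  The depth splits as follows: intermediate and
late fusion give each modality a two-layer subnetwork ending in a q = 64
representation (late fusion adds the per-modality hazard head), while early
fusion spends both hidden layers in the single joint network — every variant
has the same total depth and widths.

* mean/max/concat — elementwise mean, elementwise max, or column
  concatenation of the representations;
* attention — one linear scoring unit per modality applied to its
  representation, softmax across modalities, convex combination per sample;
* Embrace — each cell of the fused representation is copied from one
  modality drawn uniformly at random (per sample, per feature); at inference
  the expectation (mean fusion) is used so evaluation is deterministic, and
  seeded sampling remains available;
* late mean — average of per-modality log hazards;
* late mixture-of-experts — weights from one linear gating layer over the
  full concatenated input, softmax across modalities.

Training is full batch with Adam (initial learning rate 0.01, L2 weight decay
folded into the gradient), learning-rate reduction by 10× after 5 epochs
without validation improvement, early stopping with patience 10 on an
event-stratified 10% validation split, at most 100 epochs, and restoration of
the best-validation-loss weights.  The networks are built on a small
reverse-mode autodiff engine over numpy arrays (src/survfuse/nn); the Cox loss
enters the graph as a custom node with an analytic gradient that is verified
against central finite differences in the tests.

Hyperparameters (dropout {0, 0.25, 0.5}; weight decay {0.1, 0.01, 0.001};
optionally modality-level dropout {0, 0.25, 0.5}) are tuned by grid search
over 5 event-stratified folds, scored by the mean held-out partial
log-likelihood, ties resolved toward the earlier grid point.  Modality-level
dropout is inverted dropout applied to a modality's entire tensor (inputs for
early/late fusion, representations for intermediate fusion).  The benchmark
drivers use a fixed middle-of-grid point (dropout 0.25, weight decay 0.01)
instead of the full search to keep desk-scale runtimes; the full search is
available through `tune_hyperparameters`.

## Statistical baselines

The elastic-net Cox model fixes the mixing parameter at α = 0.95 (ridge
fraction 0.05, protecting against perfectly correlated columns) and selects
its penalty by 5-fold cross-validation on the grouped partial-likelihood
deviance (Verweij–van Houwelingen).  The inner solver is a FISTA
proximal-gradient method with backtracking, warm starts along a geometric
path of 50 penalties (minimum ratio 0.01 when p > n, 1e−4 otherwise).  Two
numerical choices matter in the leak regime, where the partial likelihood has
no finite unpenalized optimum: when the CV-deviance minimum lands on the
smallest penalty, the path is extended downward (up to three decades) rather
than accepting a boundary optimum, and path descent stops once the linear
predictor spread exceeds 200 (the likelihood is then saturated and smaller
penalties change nothing measurable).  A model whose selected coefficient
vector is entirely zero raises a failure signal.

PriorityLasso fits the blocks sequentially in a priority order determined by
an initial per-block ridge step (blocks ranked by cross-validated partial
log-likelihood, best first; a failing block ranks last).  Each block's
penalized Cox fit takes the accumulated offset as fixed and unpenalized; the
offset handed to the next block is the *cross-validated* linear predictor —
each sample's offset comes from a refit at the selected penalty that did not
train on it (5 folds) — which stops the offset from overfitting.  The final
log hazard is exactly the sum of the per-block predictors using the directly
fitted coefficients.  Cross-validation folds everywhere in this module are
keyed by a hash of stable sample identifiers, so fold membership (and hence
the fitted model) is invariant to row permutations.

The random survival forest is the group-naive comparator: 2,000 extremely
randomized survival trees delegated to scikit-survival's ExtraSurvivalTrees,
fed unstandardized numerics with indicator-coded categoricals (the installed
delegate has no native factor support).  Block structure is deliberately
ignored.  A block-weighted forest can be plugged in externally through the
same fitted-model contract.

## Preprocessing

Fitted on training rows only and replayed on test rows: numeric columns
missing in more than 10% of training samples (strictly) are dropped; remaining
gaps take the training median; categoricals gain an explicit "missing" level;
expression-like blocks are log(1+x) transformed (the offset accommodates
zero counts; negative values are an error); zero-variance columns are
removed; numerics are standardized with training moments.  Categoricals are
one-hot encoded for the networks, dummy encoded for the linear models, and
indicator-coded without standardization for the forest.  Unseen test levels
encode to all-zero indicators.  The order of operations is screen → impute →
log → standardize.  Optional per-modality PCA (clinical exempt) standardizes,
learns the leading components on the training block and projects test rows
onto them, reducing the component count with a warning when the rank is
insufficient.

## Metrics

Evaluation is on the survival-function scale.  Antolini's time-dependent
concordance compares S_i(T_i) with S_j(T_i) over pairs with T_i < T_j and
D_i = 1, plus equal-time pairs with discordant event status; tied predicted
probabilities earn half credit; equal-time equal-status pairs are
incomparable.  Curve lookups use the nearest grid point at or before the
requested time.  The IPCW (Graf) Brier score uses reverse-Kaplan-Meier
censoring weights — G evaluated at T⁻ for the event term and at t for the
at-risk term — integrated by the trapezoid rule over 100 evenly spaced points
between the minimum and the 0.9 quantile of the test split's observed times,
normalized by the grid span.  Terms with zero censoring survival are dropped
with a warning.  IBS values above one (a numerical pathology of erratic
curves) are replaced by the maximum of the clean splits in the same
(model, dataset) group, flagged and counted; concordance is never touched.
Any model failure (exception, fully sparse fit, non-finite predictions)
replaces that split's predictions with the training-set Kaplan-Meier curve.

## Benchmark protocol and statistics

Each dataset is split by 5×5 event-stratified cross-validation (25 test
splits), seeded and deterministic.  Model comparisons first average each
metric over a dataset's 25 splits, then apply the paired Wilcoxon signed-rank
test across datasets — one-sided for same-model-across-settings and
best-model comparisons, two-sided against the best unimodal model —
with Bonferroni-Holm correction only within the best-model and best-unimodal
families.  IBS sanitization precedes split-mean aggregation.  Kaplan-Meier
stratification sums each patient's five per-repeat predicted survival
probabilities at the grid point nearest the horizon (configurable; synthetic
time units are arbitrary), splits at the median, and reports the log-rank p.

## Synthetic data generator

Each cohort draws per-block features from exchangeable-correlation Gaussians
(correlation ρ within a block), with a sparse coefficient vector
(n_informative entries of magnitude effect_scale, random signs).  The
clinical block additionally carries two 3-level categorical covariates with
their own effects.  Event times follow a proportional-hazards model with
Weibull baseline H0(t) = rate·t^shape; the default shape 2 gives the
increasing hazard typical of cancer overall survival and avoids the extreme
right tail of the exponential, which at high leak coefficients drives the
Breslow survival curves into float saturation (exact ties at 0/1) and
artificially caps concordance — real cohorts with bounded follow-up do not
show this tail.  Censoring times are independent exponentials whose rate is
calibrated by bisection on a resampled Monte-Carlo draw to hit the target
censoring fraction (±0.03 at n = 5,000); a target of 0 disables censoring,
as the leak experiments require.  The two interventions are (i) appending
standard-Gaussian noise modalities — 10,000-dimensional by default,
configurable downward (the tests use 500) — and (ii) appending the observed
survival time to the clinical block; the event indicator is never leaked.

The generator emulates block structure, sparse signal, mixed clinical types
and heavy censoring; it does not emulate the marginal distributions of real
omics (methylation beta values, mutation sparsity) or between-block signal
correlation.  Passing tests therefore certify the framework's mechanics and
the qualitative intervention responses, not performance on any real cohort.
The default suite provides 17 cohort presets over n ∈ {150, 300, 600} and
censoring ∈ {0.6, 0.75, 0.9}.  The generator emits already-log-scale
expression blocks, so they are not flagged for the log transform; the
log-transform path is exercised with nonnegative count data in the tests.

## Problem sizes and numerical choices

The bundled analyses and the acceptance script run at desk scale: noise
modalities of dimension 500, cohorts of 150–1,000 samples, 3–5 seeds per
condition, 300-tree forests in the drivers.  Key tolerances: FISTA
convergence 1e−6 on the max coefficient change (cross-checked against an
independent coordinate-descent solver to ~5e−3 on coefficients of unit
magnitude); Cox gradient verified to 1e−5 against finite differences;
metric implementations verified to 1e−12 (concordance) and 1e−6 (IBS)
against brute-force oracles.  Degenerate inputs raise informative errors:
no comparable pairs, degenerate IBS span, all-IBS>1 groups, single-group
log-rank, all-columns-dropped blocks.

## Known limitations

* The networks run on a bespoke numpy autodiff engine: CPU-only, full batch;
  adequate at benchmark scale but not for very large cohorts.
* The attention and Embrace parameterizations are this package's own
  (declared) readings of fusion strategies whose published descriptions defer
  to external implementations.
* The priority-ordering ridge step's ranking criterion (cross-validated
  partial log-likelihood) is one concrete reading of "initial ridge step";
  alternatives (e.g. in-sample likelihood) would change orderings only when
  blocks are closely matched.
* The multinomial Embrace sampler assumes uniform modality probabilities.
* Whether the log transform precedes or follows the missingness screen is an
  open choice; screen → impute → log → standardize is implemented.
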