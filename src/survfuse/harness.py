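"""The experimental protocol: repeated stratified cross-validation over
experiment settings, metric collection with Kaplan-Meier fallback on model
failure, IBS sanitization, across-dataset Wilcoxon comparisons with
Bonferroni-Holm correction, Kaplan-Meier risk stratification, and model
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .base import ModelFailure
from .data import (
    MultiModalDataset,
    PreprocessConfig,
    SurvivalOutcome,
    apply_preprocessor,
    fit_apply_pca_per_modality,
    fit_preprocessor,
)
from .metrics import (
    MetricRecord,
    antolini_concordance,
    ibs_time_grid,
    integrated_brier_score,
    km_fallback_prediction,
    sanitize_ibs,
)
from .simulate import add_noise_modalities, add_target_leak
from .survival import KaplanMeierCurve, SurvivalCurveSet, kaplan_meier, log_rank_test

__all__ = [
    "ExperimentSetting",
    "SplitPlan",
    "ModelSpec",
    "ComparisonResult",
    "make_splits",
    "run_benchmark",
    "aggregate_and_compare",
    "km_stratification",
    "rank_models",
    "records_frame",
]


@dataclass(frozen=True)
class ExperimentSetting:
    """A deterministic modality-selection/augmentation recipe.

    ``blocks=None`` keeps every block; ``noise_count`` appends standard-Gaussian
    noise modalities; ``leak`` appends the observed survival time to the
    clinical block; ``pca_k`` applies per-modality PCA (clinical exempt).
    """

    name: str
    blocks: tuple[str, ...] | None = None
    noise_count: int = 0
    noise_dim: int = 10_000
    leak: bool = False
    pca_k: int | None = None

    def apply(self, data: MultiModalDataset, seed: int = 0) -> MultiModalDataset:
        out = data if self.blocks is None else data.select_blocks(self.blocks)
        if self.leak:
            out = add_target_leak(out)
        if self.noise_count > 0:
            out = add_noise_modalities(out, self.noise_count, self.noise_dim, seed)
        return out


def standard_settings(noise_dim: int = 10_000) -> dict[str, ExperimentSetting]:
    """The named experiment recipes of the benchmark design.

    clinical_gex — the two most informative modalities only; all_modalities —
    everything; noise_k — clinical+gex plus k Gaussian noise modalities;
    leak / leak_plus_noise_k — the survival-time leak, optionally with noise;
    unimodal_<block> and pca_k are constructed on demand via ExperimentSetting.
    """
    base = ("clinical", "gex")
    out = {
        "clinical_gex": ExperimentSetting("clinical_gex", blocks=base),
        "all_modalities": ExperimentSetting("all_modalities"),
        "leak": ExperimentSetting("leak", blocks=base, leak=True),
    }
    for k in (1, 3, 5):
        out[f"noise_{k}"] = ExperimentSetting(
            f"noise_{k}", blocks=base, noise_count=k, noise_dim=noise_dim
        )
        out[f"leak_plus_noise_{k}"] = ExperimentSetting(
            f"leak_plus_noise_{k}", blocks=base, leak=True,
            noise_count=k, noise_dim=noise_dim,
        )
    for k in (32, 64):
        out[f"pca_{k}"] = ExperimentSetting(f"pca_{k}", blocks=base, pca_k=k)
    return out


@dataclass(frozen=True)
class SplitPlan:
    """repeats x folds event-stratified (train, test) index pairs."""

    repeats: int
    folds: int
    pairs: tuple  # ((repeat, fold, train_idx, test_idx), ...)

    def __iter__(self):
        return iter(self.pairs)


def make_splits(
    outcome: SurvivalOutcome, repeats: int = 5, folds: int = 5, seed: int = 0
) -> SplitPlan:
    """Event-stratified repeated k-fold; deterministic under the seed."""
    from sklearn.model_selection import StratifiedKFold

    event = outcome.event.astype(int)
    if event.sum() < folds or (1 - event).sum() < folds:
        raise ValueError(
            f"need at least {folds} events and {folds} censored samples "
            f"(have {event.sum()} / {(1 - event).sum()})"
        )
    pairs = []
    for r in range(repeats):
        repeat_seed = int(np.random.default_rng([seed, r]).integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=repeat_seed)
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(event)), event)):
            pairs.append((r, f, tr, te))
    return SplitPlan(repeats, folds, tuple(pairs))


@dataclass(frozen=True)
class ModelSpec:
    """How the harness prepares data for and fits one model.

    ``fit`` maps a preprocessed training MultiModalDataset (+ seed) to a
    fitted model exposing predict_survival_curves.
    """

    name: str
    fit: callable
    preprocessing: PreprocessConfig = PreprocessConfig()


def _evaluate_split(model_spec, setting, train_raw, test_raw, seed):
    """Fit + score one split; ModelFailure (or any model error) -> KM fallback."""
    plan = fit_preprocessor(train_raw, model_spec.preprocessing)
    train = apply_preprocessor(plan, train_raw)
    test = apply_preprocessor(plan, test_raw)
    if setting.pca_k is not None:
        train, test = fit_apply_pca_per_modality(train, test, setting.pca_k)
    grid = ibs_time_grid(test.outcome)
    failed = False
    try:
        fitted = model_spec.fit(train, seed)
        curves = fitted.predict_survival_curves(test, grid)
        if not np.all(np.isfinite(curves.surv)):
            raise ModelFailure("non-finite survival predictions")
    except (ModelFailure, FloatingPointError, np.linalg.LinAlgError, ValueError):
        failed = True
        curves = km_fallback_prediction(train.outcome, grid, test.n)
    c = antolini_concordance(curves, test.outcome)
    try:
        ibs = integrated_brier_score(curves, test.outcome, censoring_from=train.outcome,
                                     grid=grid)
    except ValueError:
        ibs = None
    return c, ibs, failed, curves


def run_benchmark(
    datasets: dict[str, MultiModalDataset],
    models: dict[str, ModelSpec],
    settings: list[ExperimentSetting],
    seed: int = 0,
    repeats: int = 5,
    folds: int = 5,
    collect_curves: bool = False,
) -> list[MetricRecord] | tuple[list[MetricRecord], dict]:
    """Full protocol: per (dataset, setting, model, split) fit -> predict ->
    score; failures become flagged KM-fallback records; IBS sanitized per
    (model, dataset) group at the end."""
    records: list[MetricRecord] = []
    curves_store: dict = {}
    for ds_name, raw in datasets.items():
        plan = make_splits(raw.outcome, repeats, folds, seed)
        for setting in settings:
            staged = setting.apply(raw, seed=seed)
            for model_name, spec in models.items():
                for r, f, tr, te in plan:
                    c, ibs, failed, curves = _evaluate_split(
                        spec, setting, staged.subset(tr), staged.subset(te),
                        seed * 100 + r * 10 + f,
                    )
                    records.append(
                        MetricRecord(
                            dataset_id=f"{ds_name}|{setting.name}",
                            model_id=model_name,
                            split_id=f"r{r}f{f}",
                            antolini_c=c,
                            ibs=ibs,
                            model_failed=failed,
                        )
                    )
                    if collect_curves:
                        curves_store[(ds_name, setting.name, model_name, r, f)] = (
                            curves, te,
                        )
    records = sanitize_ibs(records)
    return (records, curves_store) if collect_curves else records


def records_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


@dataclass(frozen=True)
class ComparisonResult:
    model: str
    reference: str
    metric: str
    statistic: float
    p_raw: float
    p_adjusted: float
    sidedness: str
    n_datasets: int


def _paired_wilcoxon(x, y, alternative):
    d = np.asarray(x) - np.asarray(y)
    if np.all(d == 0):
        return 0.0, 1.0
    stat, p = wilcoxon(x, y, alternative=alternative)
    return float(stat), float(p)


def aggregate_and_compare(
    records: list[MetricRecord],
    reference_model: str,
    metric: str = "antolini_c",
    alternative: str = "less",
    holm: bool = True,
) -> list[ComparisonResult]:
    """Dataset-mean aggregation then paired Wilcoxon signed-rank per model
    against the reference; Holm adjustment within the returned family when
    requested (the best-model / best-unimodal comparisons), raw p otherwise.
    """
    df = records_frame(records)
    if metric == "ibs":
        df = df[df["ibs"].notna()]
    means = df.groupby(["model_id", "dataset_id"])[metric].mean().unstack()
    if reference_model not in means.index:
        raise ValueError(f"reference model {reference_model!r} absent from records")
    ref = means.loc[reference_model]
    results = []
    for model in means.index:
        if model == reference_model:
            continue
        both = pd.concat([means.loc[model], ref], axis=1).dropna()
        if both.empty:
            raise ValueError(f"no overlapping datasets for {model!r}")
        stat, p = _paired_wilcoxon(both.iloc[:, 0], both.iloc[:, 1], alternative)
        results.append(
            ComparisonResult(model, reference_model, metric, stat, p, p,
                             alternative, len(both))
        )
    if holm and results:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([r.p_raw for r in results], method="holm")
        results = [
            ComparisonResult(r.model, r.reference, r.metric, r.statistic, r.p_raw,
                             float(pa), r.sidedness, r.n_datasets)
            for r, pa in zip(results, p_adj)
        ]
    return results


def km_stratification(
    per_repeat_curves: list[SurvivalCurveSet],
    outcome: SurvivalOutcome,
    horizon: float = 5.0,
) -> dict:
    """Median split on summed predicted survival at the nearest-to-horizon
    grid point, Kaplan-Meier per group and a log-rank test between them.

    Each element of ``per_repeat_curves`` must cover every patient (one
    prediction per patient per repeat, assembled from that repeat's test folds).
    """
    n = len(outcome)
    totals = np.zeros(n)
    for curves in per_repeat_curves:
        if curves.n != n:
            raise ValueError("each repeat must predict every patient exactly once")
        t_idx = int(np.argmin(np.abs(curves.grid - horizon)))
        totals += curves.surv[:, t_idx]
    median = np.median(totals)
    if np.all(totals == totals[0]):
        raise ValueError("all summed predictions identical; cannot stratify")
    above = totals > median
    stat, p = log_rank_test(outcome, above.astype(int))
    km_above = kaplan_meier(outcome.subset(np.flatnonzero(above)))
    km_below = kaplan_meier(outcome.subset(np.flatnonzero(~above)))
    return {
        "above_median": km_above,
        "below_median": km_below,
        "statistic": stat,
        "p_value": p,
        "totals": totals,
    }


def rank_models(records: list[MetricRecord], metric: str = "antolini_c") -> pd.DataFrame:
    """Per-dataset model ranks of split-mean metrics (average ranks on ties).

    Lower rank is better: concordance ranks descend, IBS ranks ascend.
    """
    df = records_frame(records)
    if metric == "ibs":
        df = df[df["ibs"].notna()]
    means = df.groupby(["dataset_id", "model_id"])[metric].mean().unstack()
    ascending = metric == "ibs"
    return means.rank(axis=1, ascending=ascending if ascending else False, method="average")
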