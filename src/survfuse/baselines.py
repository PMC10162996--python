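"""Statistical comparators: elastic-net Cox, the PriorityLasso sequential-offset
procedure, and a random-survival-forest delegation.

The elastic net fixes the ridge fraction at 0.05 (mixing parameter alpha =
0.95) and selects its penalty by 5-fold cross-validated deviance over the
solver's default path.  PriorityLasso fits one penalized Cox model per block
in a priority order (chosen by an initial per-block ridge step), feeding each
block the accumulated cross-validated linear predictor of the previous blocks
as an unpenalized offset; the final log hazard is exactly the sum of the block
predictors.  The forest is the group-naive comparator: 2,000 extremely
randomized survival trees, delegated to scikit-survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import ModelFailure
from .coxnet import cv_select, hash_folds
from .data import MultiModalDataset
from .survival import (
    BaselineHazard,
    SurvivalCurveSet,
    breslow_baseline,
    predict_survival,
)

__all__ = [
    "PriorityOrder",
    "FittedLinearCoxModel",
    "BlockwiseLinearModel",
    "FittedForestModel",
    "fit_elastic_net_cox",
    "determine_priority_order",
    "fit_priority_lasso",
    "fit_random_survival_forest",
]

ALPHA = 0.95  # elastic-net mixing parameter; ridge fraction fixed at 0.05


@dataclass(frozen=True)
class PriorityOrder:
    """Permutation of block names, highest priority first."""

    names: tuple[str, ...]

    def validate(self, data: MultiModalDataset):
        if sorted(self.names) != sorted(data.block_names):
            raise ValueError("priority order is not a permutation of the blocks")


@dataclass
class FittedLinearCoxModel:
    """A single penalized Cox fit over the stacked feature matrix."""

    beta: np.ndarray
    lambda_: float
    baseline: BaselineHazard
    feature_names: list[str]

    def predict_theta(self, data: MultiModalDataset) -> np.ndarray:
        return data.stacked() @ self.beta

    def predict_survival_curves(self, data: MultiModalDataset, grid) -> SurvivalCurveSet:
        return predict_survival(self.predict_theta(data), self.baseline, grid)


def fit_elastic_net_cox(
    data: MultiModalDataset, seed: int = 0, n_lambda: int = 50
) -> FittedLinearCoxModel:
    """Elastic-net Cox (alpha = 0.95) with the penalty chosen by 5-fold CV.

    A fully sparse selected model is a failure signal: the harness replaces it
    with the Kaplan-Meier fallback.
    """
    if data.outcome.n_events < 2:
        raise ValueError("need at least 2 events")
    X = data.stacked()
    folds = hash_folds(data.sample_ids, 5, data.outcome.event, seed)
    res = cv_select(X, data.outcome, folds, alpha=ALPHA, n_lambda=n_lambda)
    beta = res.best_beta
    if not np.any(beta):
        raise ModelFailure("elastic net selected the empty model")
    theta = X @ beta
    names = [f"{b.name}:{c}" for b in data.blocks for c in b.frame.columns]
    return FittedLinearCoxModel(beta, res.best_lambda, breslow_baseline(theta, data.outcome), names)


def determine_priority_order(
    data: MultiModalDataset, seed: int = 0, n_lambda: int = 30
) -> PriorityOrder:
    """Initial ridge step: rank blocks by their cross-validated partial
    log-likelihood under a per-block ridge Cox fit (best first; failed blocks last)."""
    folds = hash_folds(data.sample_ids, 5, data.outcome.event, seed)
    scores = []
    for block in data.blocks:
        try:
            res = cv_select(block.matrix(), data.outcome, folds, alpha=0.0,
                            n_lambda=n_lambda)
            # grouped deviance = -2 * CV partial log-likelihood (up to constants)
            scores.append((-0.5 * res.cv_deviance[res.best_index], block.name))
        except Exception:
            scores.append((-np.inf, block.name))
    scores.sort(key=lambda s: -s[0])
    return PriorityOrder(tuple(name for _, name in scores))


@dataclass
class BlockwiseLinearModel:
    """Sequential-offset model: theta is exactly the sum of block predictors."""

    order: PriorityOrder
    block_betas: dict[str, np.ndarray]
    block_lambdas: dict[str, float]
    baseline: BaselineHazard
    train_theta: np.ndarray = field(repr=False, default=None)

    def block_predictors(self, data: MultiModalDataset) -> dict[str, np.ndarray]:
        return {
            name: data.block(name).matrix() @ self.block_betas[name]
            for name in self.order.names
        }

    def predict_theta(self, data: MultiModalDataset) -> np.ndarray:
        preds = self.block_predictors(data)
        return sum(preds[name] for name in self.order.names)

    def predict_survival_curves(self, data: MultiModalDataset, grid) -> SurvivalCurveSet:
        return predict_survival(self.predict_theta(data), self.baseline, grid)


def fit_priority_lasso(
    data: MultiModalDataset,
    order: PriorityOrder | None = None,
    seed: int = 0,
    n_lambda: int = 50,
) -> BlockwiseLinearModel:
    """Sequential penalized Cox over blocks with cross-validated offsets.

    For each block in priority order: select the penalty by 5-fold CV with the
    accumulated offset held fixed and unpenalized; the offset handed to the
    next block is the cross-validated linear predictor (each sample's offset
    produced by a refit not trained on it), which prevents the offset from
    overfitting the training data.  Prediction on new data uses the directly
    fitted coefficients.
    """
    if order is None:
        order = determine_priority_order(data, seed)
    order.validate(data)
    if data.outcome.n_events < 2:
        raise ValueError("need at least 2 events")
    folds = hash_folds(data.sample_ids, 5, data.outcome.event, seed)
    n = data.n
    offset = np.zeros(n)
    block_betas: dict[str, np.ndarray] = {}
    block_lambdas: dict[str, float] = {}

    from .coxnet import fit_path

    for name in order.names:
        X = data.block(name).matrix()
        res = cv_select(X, data.outcome, folds, offset=offset, alpha=ALPHA,
                        n_lambda=n_lambda)
        beta = res.best_beta
        lam = res.best_lambda
        block_betas[name] = beta
        block_lambdas[name] = lam
        # cross-validated offsets at the selected penalty
        cv_pred = np.zeros(n)
        for f in np.unique(folds):
            tr = folds != f
            te = ~tr
            sub = fit_path(X[tr], data.outcome.subset(tr), offset[tr],
                           alpha=ALPHA, lambdas=np.array([lam]))
            cv_pred[te] = X[te] @ sub.betas[0]
        offset = offset + cv_pred

    if not any(np.any(b) for b in block_betas.values()):
        raise ModelFailure("PriorityLasso selected the empty model in every block")

    theta = sum(data.block(nm).matrix() @ block_betas[nm] for nm in order.names)
    baseline = breslow_baseline(theta, data.outcome)
    return BlockwiseLinearModel(order, block_betas, block_lambdas, baseline, theta)


@dataclass
class FittedForestModel:
    """Wrapper over the scikit-survival extra-trees survival forest delegate."""

    forest: object
    train_max_time: float

    def predict_theta(self, data: MultiModalDataset) -> np.ndarray:
        # forests have no log-hazard scale; expected cumulative hazard is the
        # conventional risk surrogate
        return np.log1p(self.forest.predict(data.stacked()))

    def predict_survival_curves(self, data: MultiModalDataset, grid) -> SurvivalCurveSet:
        grid = np.asarray(grid, dtype=float)
        fns = self.forest.predict_survival_function(data.stacked(), return_array=False)
        surv = np.empty((len(fns), len(grid)))
        for i, fn in enumerate(fns):
            idx = np.searchsorted(fn.x, grid, side="right") - 1
            surv[i] = np.where(idx >= 0, fn.y[np.maximum(idx, 0)], 1.0)
        surv = np.minimum.accumulate(surv, axis=1)
        return SurvivalCurveSet(grid, surv)


def fit_random_survival_forest(
    data: MultiModalDataset, seed: int = 0, n_trees: int = 2000
) -> FittedForestModel:
    """Extremely randomized survival forest, group structure deliberately ignored.

    Expects unstandardized numerics with indicator-coded categoricals.
    """
    from sksurv.ensemble import ExtraSurvivalTrees

    X = data.stacked()
    try:
        forest = ExtraSurvivalTrees(n_estimators=n_trees, random_state=seed)
        forest.fit(X, data.outcome.to_structured())
    except Exception as exc:  # delegate failure becomes a failure signal
        raise ModelFailure(f"survival forest delegate failed: {exc}") from exc
    return FittedForestModel(forest, float(data.outcome.time.max()))
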