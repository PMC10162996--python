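"""Shared model contract, failure signalling and stratified splitting helpers."""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .data import MultiModalDataset
from .survival import SurvivalCurveSet

__all__ = ["ModelFailure", "FittedModel", "stratified_folds", "stratified_holdout"]


class ModelFailure(RuntimeError):
    """A model could not produce usable predictions (divergence, full sparsity,
    delegate error).  The benchmark harness converts this into the training-set
    Kaplan-Meier fallback rather than propagating it."""


@runtime_checkable
class FittedModel(Protocol):
    """Any trained predictor usable by the harness."""

    def predict_theta(self, data: MultiModalDataset) -> np.ndarray: ...

    def predict_survival_curves(self, data: MultiModalDataset, grid) -> SurvivalCurveSet: ...


def stratified_folds(event: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Event-stratified fold assignment; returns an int array of fold ids.

    Within each stratum, samples are shuffled and dealt round-robin, so fold
    event counts differ by at most one from proportional.
    """
    event = np.asarray(event).astype(bool)
    fold = np.empty(len(event), dtype=int)
    for value in (True, False):
        idx = np.flatnonzero(event == value)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def stratified_holdout(event: np.ndarray, frac: float, rng: np.random.Generator):
    """Event-stratified train/holdout index split (holdout gets ~frac samples)."""
    event = np.asarray(event).astype(bool)
    hold = np.zeros(len(event), dtype=bool)
    for value in (True, False):
        idx = np.flatnonzero(event == value)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(frac * len(idx)))) if len(idx) else 0
        hold[idx[:k]] = True
    return np.flatnonzero(~hold), np.flatnonzero(hold)
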