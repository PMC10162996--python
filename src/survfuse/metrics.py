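"""Survival-function-scale evaluation: Antolini's time-dependent concordance,
the IPCW (Graf) Brier score integrated over a truncated grid, the IBS>1
sanitization rule, and the Kaplan-Meier fallback for failed models.

Antolini's C compares predicted survival probabilities evaluated at the
earlier subject's event time: pair (i, j) is comparable when T_i < T_j and
subject i had an event (plus equal-time pairs with discordant event status),
and concordant when S_i(T_i) < S_j(T_i).  Tied predictions earn half credit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data import SurvivalOutcome
from .survival import KaplanMeierCurve, SurvivalCurveSet, kaplan_meier

__all__ = [
    "MetricRecord",
    "antolini_concordance",
    "ibs_time_grid",
    "integrated_brier_score",
    "sanitize_ibs",
    "km_fallback_prediction",
]


@dataclass(frozen=True)
class MetricRecord:
    """One (dataset, model, split) evaluation with sanitization/failure flags."""

    dataset_id: str
    model_id: str
    split_id: str
    antolini_c: float
    ibs: float | None
    ibs_replaced: bool = False
    model_failed: bool = False


def antolini_concordance(curves: SurvivalCurveSet, outcome: SurvivalOutcome) -> float:
    """Time-dependent concordance of predicted survival curves.

    Raises if no comparable pair exists (e.g. everything censored).
    """
    if curves.n != len(outcome):
        raise ValueError("curves and outcome lengths differ")
    t, d = outcome.time, outcome.event
    S_at = curves.at(t)  # S_at[k, l] = S_k(T_l)
    diag = np.diag(S_at)
    ti, tj = t[:, None], t[None, :]
    di, dj = d[:, None], d[None, :]
    comparable = ((ti < tj) & di) | ((ti == tj) & di & ~dj)
    np.fill_diagonal(comparable, False)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (0 usable pairs)")
    other = S_at.T  # other[i, j] = S_j(T_i)
    own = diag[:, None]
    credit = np.where(own < other, 1.0, np.where(own == other, 0.5, 0.0))
    return float(credit[comparable].sum() / n_comp)


def ibs_time_grid(outcome: SurvivalOutcome, points: int = 100) -> np.ndarray:
    """Evenly spaced times from min(T) to the 0.9 quantile of observed times."""
    if points < 2:
        raise ValueError("need at least 2 grid points")
    t = outcome.time
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct observed times")
    lo, hi = float(t.min()), float(np.quantile(t, 0.9))
    if hi <= lo:
        raise ValueError("degenerate time span: 0.9 quantile equals the minimum")
    return np.linspace(lo, hi, points)


def _km_left(curve: KaplanMeierCurve, times) -> np.ndarray:
    """Left-limit evaluation G(t-): value just before each time."""
    times = np.asarray(times, dtype=float)
    idx = np.searchsorted(curve.times, times, side="left") - 1
    return np.where(idx >= 0, curve.survival[np.maximum(idx, 0)], 1.0)


def integrated_brier_score(
    curves: SurvivalCurveSet,
    outcome: SurvivalOutcome,
    censoring_from: SurvivalOutcome | None = None,
    grid: np.ndarray | None = None,
) -> float:
    """IPCW Brier score integrated (trapezoid) over the grid, divided by its span.

    BS(t) = n^-1 sum_i [ S_i(t)^2 1{T_i <= t, D_i = 1} / G(T_i-)
                         + (1 - S_i(t))^2 1{T_i > t} / G(t) ]

    ``censoring_from`` supplies the sample for the reverse-Kaplan-Meier
    censoring model G (defaults to the evaluation outcome itself).  Terms whose
    weight 1/G is undefined (G = 0) are dropped with a warning.
    """
    if grid is None:
        grid = curves.grid
    grid = np.asarray(grid, dtype=float)
    if censoring_from is None:
        censoring_from = outcome
    G = kaplan_meier(censoring_from, reverse=True)
    t, d = outcome.time, outcome.event
    n = len(t)

    S = curves.at(grid)  # n x g
    G_at_T = _km_left(G, t)  # G(T_i-)
    G_at_grid = G.at(grid)  # G(t)

    had_event = (t[:, None] <= grid[None, :]) & d[:, None]
    still_alive = t[:, None] > grid[None, :]

    g = len(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_event = np.broadcast_to(
            np.where(G_at_T[:, None] > 0, 1.0 / G_at_T[:, None], np.nan), (n, g)
        )
        w_alive = np.broadcast_to(
            np.where(G_at_grid[None, :] > 0, 1.0 / G_at_grid[None, :], np.nan), (n, g)
        )
    dropped = int(np.isnan(w_event[had_event]).sum() + np.isnan(w_alive[still_alive]).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} IPCW terms with zero censoring survival")

    term_event = np.where(had_event, S**2 * np.nan_to_num(w_event), 0.0)
    term_alive = np.where(still_alive, (1.0 - S) ** 2 * np.nan_to_num(w_alive), 0.0)
    bs = (term_event + term_alive).sum(axis=0) / n
    span = grid[-1] - grid[0]
    if span <= 0:
        raise ValueError("degenerate grid span")
    return float(np.trapezoid(bs, grid) / span)


def sanitize_ibs(records: list[MetricRecord]) -> list[MetricRecord]:
    """Replace IBS values above one by the max of the clean splits in their
    (model, dataset) group; flag each replacement.  A group whose every split
    exceeds one has no defined replacement and raises.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault((r.model_id, r.dataset_id), []).append(i)
    out = list(records)
    for key, idxs in groups.items():
        vals = [records[i].ibs for i in idxs]
        if any(v is None for v in vals):
            continue
        bad = [i for i, v in zip(idxs, vals) if v > 1.0]
        if not bad:
            continue
        clean = [v for v in vals if v <= 1.0]
        if not clean:
            raise ValueError(
                f"every split of group {key} has IBS > 1; replacement undefined"
            )
        repl = max(clean)
        for i in bad:
            out[i] = replace(records[i], ibs=repl, ibs_replaced=True)
    return out


def km_fallback_prediction(
    train_outcome: SurvivalOutcome, grid, n_test: int
) -> SurvivalCurveSet:
    """Every test sample receives the training Kaplan-Meier curve."""
    km = kaplan_meier(train_outcome)
    row = km.at(np.asarray(grid, dtype=float))
    return SurvivalCurveSet(np.asarray(grid, dtype=float), np.tile(row, (n_test, 1)))
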