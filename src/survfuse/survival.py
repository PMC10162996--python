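"""Cox partial likelihood (Breslow ties), Breslow baseline hazard, Kaplan-Meier
and the log-rank test — the machinery shared by every model and metric.

The negative partial log-likelihood implemented here,

    nll(theta) = - sum_{i: D_i = 1} [ theta_i - log sum_{j: T_j >= T_i} exp(theta_j) ],

uses the Breslow convention for tied event times: all events sharing a time
share one risk-set denominator, counted once per tied event.  Risk sets are
inclusive (T_j >= t).  All curves follow right-continuous step conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sksurv.compare import compare_survival
from sksurv.nonparametric import kaplan_meier_estimator

from .data import SurvivalOutcome

__all__ = [
    "BaselineHazard",
    "SurvivalCurveSet",
    "KaplanMeierCurve",
    "cox_nll_breslow",
    "cox_nll_breslow_grad",
    "breslow_baseline",
    "predict_survival",
    "kaplan_meier",
    "log_rank_test",
    "step_lookup",
]


def _check_theta(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float).ravel()
    if not np.all(np.isfinite(theta)):
        raise ValueError("log hazards must be finite")
    return theta


def _sorted_parts(theta: np.ndarray, outcome: SurvivalOutcome):
    """Sort by time; return pieces shared by the likelihood and the baseline.

    risk[i] is the (max-shifted) risk-set sum over {j: T_j >= T_i}; tied times
    map to the same suffix index so tied events share one denominator.
    """
    order = np.argsort(outcome.time, kind="stable")
    t = outcome.time[order]
    d = outcome.event[order]
    th = theta[order]
    shift = th.max()
    e = np.exp(th - shift)
    suffix = np.cumsum(e[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    risk = suffix[first]
    return order, t, d, th, e, risk, shift


def cox_nll_breslow(theta, outcome: SurvivalOutcome) -> float:
    """Negative Cox partial log-likelihood with the Breslow tie convention."""
    theta = _check_theta(theta)
    if len(theta) != len(outcome):
        raise ValueError("theta and outcome lengths differ")
    if outcome.n_events == 0:
        warnings.warn("no events: partial likelihood is vacuous, returning 0.0")
        return 0.0
    _, t, d, th, e, risk, shift = _sorted_parts(theta, outcome)
    log_risk = np.log(np.maximum(risk, 1e-300)) + shift
    return float(-(th[d] - log_risk[d]).sum())


def cox_nll_breslow_grad(theta, outcome: SurvivalOutcome) -> np.ndarray:
    """Gradient of cox_nll_breslow with respect to theta (original sample order)."""
    theta = _check_theta(theta)
    if outcome.n_events == 0:
        return np.zeros_like(theta)
    order, t, d, th, e, risk, shift = _sorted_parts(theta, outcome)
    contrib = np.where(d, 1.0 / np.maximum(risk, 1e-300), 0.0)
    prefix = np.cumsum(contrib)
    last = np.searchsorted(t, t, side="right") - 1
    grad_sorted = -d.astype(float) + e * prefix[last]
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return grad


@dataclass(frozen=True)
class BaselineHazard:
    """Breslow cumulative baseline hazard: a step function over event times."""

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def __post_init__(self):
        et = np.asarray(self.event_times, dtype=float)
        ch = np.asarray(self.cumulative_hazard, dtype=float)
        if len(et) != len(ch):
            raise ValueError("length mismatch")
        if len(et) and (np.any(np.diff(et) <= 0) or np.any(et <= 0)):
            raise ValueError("event times must be strictly increasing and positive")
        if np.any(np.diff(ch) < 0) or np.any(ch < 0):
            raise ValueError("cumulative hazard must be nonnegative nondecreasing")
        object.__setattr__(self, "event_times", et)
        object.__setattr__(self, "cumulative_hazard", ch)

    def at(self, times) -> np.ndarray:
        """H0 evaluated as a right-continuous step function (0 before first event)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.event_times, times, side="right") - 1
        out = np.where(idx >= 0, self.cumulative_hazard[np.maximum(idx, 0)], 0.0)
        return out


def breslow_baseline(theta, outcome: SurvivalOutcome) -> BaselineHazard:
    """Breslow estimate H0(t) = sum_{event times t_k <= t} d_k / sum_{T_j >= t_k} exp(theta_j)."""
    theta = _check_theta(theta)
    if outcome.n_events == 0:
        raise ValueError("at least one event is required")
    _, t, d, th, e, risk, shift = _sorted_parts(theta, outcome)
    event_t = t[d]
    uniq, counts = np.unique(event_t, return_counts=True)
    # risk-set sum at each unique event time (scaled back)
    pos = np.searchsorted(t, uniq, side="left")
    suffix = np.cumsum(e[::-1])[::-1]
    denom = suffix[pos] * np.exp(shift)
    increments = counts / denom
    return BaselineHazard(uniq, np.cumsum(increments))


@dataclass(frozen=True)
class SurvivalCurveSet:
    """Per-sample survival probabilities on a shared increasing time grid."""

    grid: np.ndarray
    surv: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        surv = np.asarray(self.surv, dtype=float)
        if surv.ndim != 2 or surv.shape[1] != len(grid):
            raise ValueError("surv must be n x len(grid)")
        if len(grid) > 1 and np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(surv < -1e-12) or np.any(surv > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(surv, axis=1) > 1e-9):
            raise ValueError("survival curves must be nonincreasing in time")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "surv", np.clip(surv, 0.0, 1.0))

    @property
    def n(self) -> int:
        return self.surv.shape[0]

    def at(self, times) -> np.ndarray:
        """n x len(times) step-function evaluation (nearest-left grid point).

        Times before the first grid point take the first grid value.
        """
        return self.surv[:, step_lookup(self.grid, times)]


def step_lookup(grid: np.ndarray, times) -> np.ndarray:
    """Index of the nearest grid point at or before each time (clamped to 0)."""
    times = np.asarray(times, dtype=float)
    idx = np.searchsorted(grid, times, side="right") - 1
    return np.maximum(idx, 0)


def predict_survival(theta, baseline: BaselineHazard, grid) -> SurvivalCurveSet:
    """S(t | x_i) = exp(-H0(t) * exp(theta_i)) on the given grid."""
    theta = _check_theta(theta)
    H = baseline.at(grid)  # len(grid)
    surv = np.exp(-np.outer(np.exp(theta), H))
    return SurvivalCurveSet(np.asarray(grid, dtype=float), surv)


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit estimate with at-risk/event counts at each drop time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, times) -> np.ndarray:
        """Right-continuous step evaluation; 1 before the first drop."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.times, times, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)


def kaplan_meier(outcome: SurvivalOutcome, reverse: bool = False) -> KaplanMeierCurve:
    """Kaplan-Meier estimate of the survival (or, reversed, censoring) distribution.

    ``reverse=True`` estimates the censoring survival function G used for IPCW
    weights, with the convention that events precede censorings at tied times.
    """
    event, time = outcome.event, outcome.time
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uniq_times, probs = kaplan_meier_estimator(event, time, reverse=reverse)
    order = np.argsort(time, kind="stable")
    t_sorted = np.sort(time)
    first = np.searchsorted(t_sorted, uniq_times, side="left")
    at_risk = len(time) - first
    flag = ~event if reverse else event
    n_ev = np.array([int(flag[time == u].sum()) for u in uniq_times])
    return KaplanMeierCurve(uniq_times, probs, at_risk, n_ev)


def log_rank_test(outcome: SurvivalOutcome, group) -> tuple[float, float]:
    """Two-group log-rank chi-square test (1 df); returns (statistic, p)."""
    group = np.asarray(group)
    if len(np.unique(group)) != 2:
        raise ValueError("exactly two non-empty groups are required")
    chisq, p = compare_survival(outcome.to_structured(), group)
    return float(chisq), float(p)
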