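"""Block-structured multi-omics survival data generator.

Emulates the structure of per-cancer multi-omics cohorts: a low-dimensional
mixed-type clinical block, high-dimensional correlated continuous blocks with
sparse signal, heavy right censoring, and the two benchmark interventions —
pure-noise Gaussian modalities and the observed-survival-time target leak.

Event times follow a proportional-hazards model with an exponential or Weibull
baseline; censoring times are independent exponentials whose rate is calibrated
by bisection on a Monte-Carlo sample to hit a target censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    CATEGORICAL,
    NUMERIC,
    ModalityBlock,
    MultiModalDataset,
    SurvivalOutcome,
)

__all__ = [
    "BlockSpec",
    "SimulationConfig",
    "GeneratedDataset",
    "simulate_multiomics_survival",
    "add_noise_modalities",
    "add_target_leak",
    "default_benchmark_suite",
]

LEAK_COLUMN = "observed_time"


@dataclass(frozen=True)
class BlockSpec:
    """One simulated modality: dimension, sparsity and effect structure."""

    name: str
    dim: int
    n_informative: int
    effect_scale: float
    rho: float = 0.0
    role_tag: str = "omics"

    def __post_init__(self):
        if not 0 <= self.n_informative <= self.dim:
            raise ValueError("n_informative must lie in [0, dim]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("within-block correlation must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``censoring_rate`` is the target fraction of censored samples; 0.0 disables
    censoring entirely (used by the target-leak experiments).  The baseline
    cumulative hazard is Weibull, H0(t) = rate * t^shape; the default shape of
    2 gives the increasing hazard typical of cancer overall survival and keeps
    the time distribution's tail comparable to cohorts with bounded follow-up
    (shape 1 recovers the exponential).
    """

    n: int
    blocks: tuple[BlockSpec, ...]
    censoring_rate: float
    seed: int
    baseline_rate: float = 0.1
    weibull_shape: float = 2.0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")


@dataclass
class GeneratedDataset:
    """A simulated cohort plus its generating truth."""

    dataset: MultiModalDataset
    true_linear_predictor: np.ndarray
    true_coefficients: dict[str, np.ndarray]
    categorical_effects: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def _exchangeable_gaussian(rng, n, dim, rho):
    z = rng.standard_normal((n, dim))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z
    return z


def _event_times(rng, eta, rate, shape):
    u = rng.uniform(size=len(eta))
    # inverse of H(t) * exp(eta) = -log U with H(t) = rate * t^shape
    base = -np.log(u) / (rate * np.exp(eta))
    return np.power(base, 1.0 / shape)


def _calibrate_censoring_rate(rng, eta, rate, shape, target, n_mc=100_000):
    """Bisection on the exponential censoring rate to hit a target censored fraction."""
    eta_mc = rng.choice(eta, size=n_mc, replace=True)
    t_mc = _event_times(rng, eta_mc, rate, shape)
    u = rng.uniform(size=n_mc)

    def censored_fraction(c_rate):
        c_mc = -np.log(u) / c_rate
        return np.mean(c_mc < t_mc)

    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_fraction(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-10:
            break
    return np.sqrt(lo * hi)


def simulate_multiomics_survival(config: SimulationConfig) -> GeneratedDataset:
    """Draw one cohort under the proportional-hazards generating model."""
    for attempt in range(10):
        rng = np.random.default_rng([config.seed, attempt])
        gen = _simulate_once(config, rng)
        if gen.dataset.outcome.n_events > 0:
            return gen
    raise RuntimeError("no events after 10 regeneration attempts; lower censoring")


def _simulate_once(config: SimulationConfig, rng) -> GeneratedDataset:
    n = config.n
    blocks: list[ModalityBlock] = []
    coefs: dict[str, np.ndarray] = {}
    cat_effects: dict[str, dict[str, np.ndarray]] = {}
    eta = np.zeros(n)

    for spec in config.blocks:
        X = _exchangeable_gaussian(rng, n, spec.dim, spec.rho)
        beta = np.zeros(spec.dim)
        if spec.n_informative > 0:
            idx = rng.choice(spec.dim, size=spec.n_informative, replace=False)
            signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
            beta[idx] = signs * spec.effect_scale
        eta += X @ beta
        coefs[spec.name] = beta
        cols = [f"{spec.name}_f{j+1}" for j in range(spec.dim)]
        frame = pd.DataFrame(X, columns=cols)
        kinds = [NUMERIC] * spec.dim
        if spec.role_tag == "clinical":
            # two 3-level categorical covariates with their own effects
            effects = {}
            for c in range(2):
                col = f"{spec.name}_cat{c+1}"
                levels = rng.integers(0, 3, size=n)
                level_eff = np.array([-1.0, 0.0, 1.0]) * spec.effect_scale
                eta += level_eff[levels]
                frame[col] = pd.Series([f"L{v}" for v in levels])
                kinds.append(CATEGORICAL)
                effects[col] = level_eff
            cat_effects[spec.name] = effects
        blocks.append(ModalityBlock(spec.name, frame, kinds, spec.role_tag))

    t_event = _event_times(rng, eta, config.baseline_rate, config.weibull_shape)
    if config.censoring_rate > 0:
        c_rate = _calibrate_censoring_rate(
            rng, eta, config.baseline_rate, config.weibull_shape, config.censoring_rate
        )
        t_cens = -np.log(rng.uniform(size=n)) / c_rate
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-12)

    dataset = MultiModalDataset(blocks, SurvivalOutcome(time, event))
    return GeneratedDataset(dataset, eta, coefs, cat_effects)


def add_noise_modalities(
    data: MultiModalDataset, count: int, dim: int = 10_000, seed: int = 0
) -> MultiModalDataset:
    """Append ``count`` blocks of i.i.d. standard-Gaussian noise of width ``dim``."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng([seed, 7919])
    existing = set(data.block_names)
    new_blocks = list(data.blocks)
    for k in range(1, count + 1):
        name = f"noise_{k}"
        if name in existing:
            raise ValueError(f"block name collision: {name!r} already present")
        X = rng.standard_normal((data.n, dim))
        cols = [f"{name}_f{j+1}" for j in range(dim)]
        new_blocks.append(
            ModalityBlock(name, pd.DataFrame(X, columns=cols), [NUMERIC] * dim, "noise")
        )
    return MultiModalDataset(new_blocks, data.outcome, data.sample_ids)


def add_target_leak(data: MultiModalDataset) -> MultiModalDataset:
    """Append the observed survival time to the clinical block.

    The event indicator is never added; censored samples leak their censoring
    time, which is exactly what makes the leak a noisy but extremely strong
    predictor.
    """
    clinical = [b for b in data.blocks if b.role_tag == "clinical"]
    if len(clinical) != 1:
        raise ValueError("exactly one clinical-tagged block is required")
    block = clinical[0]
    if LEAK_COLUMN in block.frame.columns:
        raise ValueError(f"clinical block already carries {LEAK_COLUMN!r}")
    frame = block.frame.copy()
    frame[LEAK_COLUMN] = data.outcome.time
    new_block = ModalityBlock(
        block.name, frame, list(block.kinds) + [NUMERIC], block.role_tag,
        block.expression_like,
    )
    return MultiModalDataset(
        [new_block if b.name == block.name else b for b in data.blocks],
        data.outcome,
        data.sample_ids,
    )


def default_blocks(
    clinical_effect: float = 0.5,
    gex_dim: int = 200,
    gex_informative: int = 10,
    gex_effect: float = 0.35,
    gex_rho: float = 0.3,
) -> tuple[BlockSpec, ...]:
    """Clinical + expression-like block pair used across the benchmark presets."""
    return (
        BlockSpec("clinical", 5, 3, clinical_effect, 0.0, "clinical"),
        BlockSpec("gex", gex_dim, gex_informative, gex_effect, gex_rho, "omics"),
    )


def default_benchmark_suite(base_seed: int = 0) -> list[SimulationConfig]:
    """Seventeen cohort presets over n in {150, 300, 600} x censoring in {0.6, 0.75, 0.9}."""
    grid = [(n, c) for n in (150, 300, 600) for c in (0.6, 0.75, 0.9)]
    configs = []
    for i in range(17):
        n, c = grid[i % len(grid)]
        configs.append(
            SimulationConfig(
                n=n, blocks=default_blocks(), censoring_rate=c,
                seed=base_seed * 1000 + i,
            )
        )
    return configs
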