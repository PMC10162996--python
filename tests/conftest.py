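import numpy as np
import pandas as pd
import pytest

from survfuse.data import ModalityBlock, MultiModalDataset, SurvivalOutcome
from survfuse.simulate import (
    BlockSpec,
    SimulationConfig,
    default_blocks,
    simulate_multiomics_survival,
)


def random_outcome(rng, n, censor_frac=0.3, with_ties=False):
    """Small random right-censored outcome for oracle comparisons."""
    if with_ties:
        time = rng.integers(1, max(3, n // 2), size=n).astype(float)
    else:
        time = rng.uniform(0.5, 10.0, size=n)
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return SurvivalOutcome(time, event)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_dataset():
    """60-sample two-block dataset with a clinical block (mixed types)."""
    cfg = SimulationConfig(
        n=60,
        blocks=(
            BlockSpec("clinical", 4, 2, 0.5, 0.0, "clinical"),
            BlockSpec("gex", 20, 4, 0.4, 0.2, "omics"),
        ),
        censoring_rate=0.3,
        seed=7,
    )
    return simulate_multiomics_survival(cfg).dataset


@pytest.fixture
def medium_generated():
    """Signal-bearing cohort used by model-level tests."""
    cfg = SimulationConfig(
        n=300, blocks=default_blocks(gex_dim=60, gex_informative=8),
        censoring_rate=0.4, seed=11,
    )
    return simulate_multiomics_survival(cfg)


def make_block(name, frame, kinds=None, role="omics", expr=False):
    if kinds is None:
        kinds = ["numeric"] * frame.shape[1]
    return ModalityBlock(name, frame, kinds, role, expr)


def dataset_from_arrays(arrays_by_name, outcome, roles=None):
    roles = roles or {}
    blocks = [
        make_block(
            name,
            pd.DataFrame(arr, columns=[f"{name}_c{j}" for j in range(arr.shape[1])]),
            role=roles.get(name, "omics"),
        )
        for name, arr in arrays_by_name.items()
    ]
    return MultiModalDataset(blocks, outcome)
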