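"""Containers for block-structured (multi-omics) survival data and train-time preprocessing.

A dataset is an ordered list of named feature blocks (modalities) sharing rows
with a right-censored outcome.  Preprocessing is always fitted on training rows
only and replayed on test rows: missingness screening, median imputation,
missing-category encoding, log(1+x) for expression-like blocks, zero-variance
removal, one-hot/dummy encoding against the training vocabulary (unseen test
levels encode to all zeros) and standardization with training moments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalOutcome",
    "ModalityBlock",
    "MultiModalDataset",
    "PreprocessConfig",
    "PreprocessingPlan",
    "DegenerateBlockError",
    "SchemaError",
    "fit_preprocessor",
    "apply_preprocessor",
    "fit_apply_pca_per_modality",
]

NUMERIC = "numeric"
CATEGORICAL = "categorical"
MISSING_CATEGORY = "missing"


class DegenerateBlockError(ValueError):
    """Raised when preprocessing would leave a block without any columns."""


class SchemaError(ValueError):
    """Raised when data does not match the schema a plan was fitted on."""


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival outcome: observed time and event indicator."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or event.ndim != 1 or len(time) != len(event):
            raise ValueError("time and event must be 1-D arrays of equal length")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival times must be finite and strictly positive")
        if not np.all(np.isin(event, (0, 1))):
            raise ValueError("event indicator must be binary (1=event, 0=censored)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(bool))

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx])

    def to_structured(self) -> np.ndarray:
        """Structured array in the (event, time) layout used by scikit-survival."""
        return np.array(
            list(zip(self.event, self.time)),
            dtype=[("event", "?"), ("time", "<f8")],
        )


@dataclass
class ModalityBlock:
    """One named modality: an n x p feature table with per-column kinds.

    ``role_tag`` distinguishes the low-dimensional clinical block (exempt from
    PCA, target of the survival-time leak), ordinary omics blocks, and injected
    noise blocks.  ``expression_like`` flags blocks whose values should be
    log(1+x) transformed during preprocessing.
    """

    name: str
    frame: pd.DataFrame
    kinds: list[str]
    role_tag: str = "omics"
    expression_like: bool = False

    def __post_init__(self):
        if self.frame.shape[1] == 0:
            raise ValueError(f"block {self.name!r} has no columns")
        if len(self.kinds) != self.frame.shape[1]:
            raise ValueError(f"block {self.name!r}: kinds length != column count")
        if self.frame.columns.duplicated().any():
            raise ValueError(f"block {self.name!r} has duplicated column names")
        bad = set(self.kinds) - {NUMERIC, CATEGORICAL}
        if bad:
            raise ValueError(f"unknown column kinds {bad}")
        if self.role_tag not in ("clinical", "omics", "noise"):
            raise ValueError(f"unknown role_tag {self.role_tag!r}")

    @property
    def n(self) -> int:
        return self.frame.shape[0]

    @property
    def width(self) -> int:
        return self.frame.shape[1]

    def matrix(self) -> np.ndarray:
        """Float view; only valid once all columns are numeric."""
        if CATEGORICAL in self.kinds:
            raise ValueError(f"block {self.name!r} still holds categorical columns")
        return self.frame.to_numpy(dtype=float)

    def subset(self, idx) -> "ModalityBlock":
        return ModalityBlock(
            self.name,
            self.frame.iloc[np.asarray(idx)].reset_index(drop=True),
            list(self.kinds),
            self.role_tag,
            self.expression_like,
        )


@dataclass
class MultiModalDataset:
    """Ordered modality blocks aligned row-wise to one survival outcome."""

    blocks: list[ModalityBlock]
    outcome: SurvivalOutcome
    sample_ids: np.ndarray | None = None

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("at least one modality block is required")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("block names must be unique")
        n = len(self.outcome)
        for b in self.blocks:
            if b.n != n:
                raise ValueError(f"block {b.name!r} has {b.n} rows, outcome has {n}")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:06d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def block(self, name: str) -> ModalityBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def subset(self, idx) -> "MultiModalDataset":
        idx = np.asarray(idx)
        return MultiModalDataset(
            [b.subset(idx) for b in self.blocks],
            self.outcome.subset(idx),
            self.sample_ids[idx],
        )

    def select_blocks(self, names) -> "MultiModalDataset":
        return MultiModalDataset(
            [self.block(n) for n in names], self.outcome, self.sample_ids
        )

    def matrices(self) -> list[np.ndarray]:
        return [b.matrix() for b in self.blocks]

    def stacked(self) -> np.ndarray:
        return np.hstack(self.matrices())


@dataclass(frozen=True)
class PreprocessConfig:
    """Options for fit_preprocessor.

    encoding: "onehot" (one indicator per level; neural models), "dummy"
    (first level dropped; linear models) or "onehot_raw" (indicators but no
    standardization; forests).
    """

    encoding: str = "onehot"
    standardize: bool = True
    missing_threshold: float = 0.10

    def __post_init__(self):
        if self.encoding not in ("onehot", "dummy", "onehot_raw"):
            raise ValueError(f"unknown encoding {self.encoding!r}")


@dataclass
class _ColumnPlan:
    kind: str
    dropped: bool = False
    drop_reason: str | None = None
    median: float | None = None
    mean: float | None = None
    sd: float | None = None
    log1p: bool = False
    vocabulary: list[str] | None = None  # categorical levels seen in train


@dataclass
class PreprocessingPlan:
    """Train-fitted per-column statistics; applying it never consults outcomes."""

    config: PreprocessConfig
    columns: dict[str, dict[str, _ColumnPlan]] = field(default_factory=dict)
    block_meta: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": vars(self.config),
            "block_meta": self.block_meta,
            "columns": {
                blk: {col: vars(cp) for col, cp in cols.items()}
                for blk, cols in self.columns.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessingPlan":
        payload = json.loads(text)
        plan = cls(PreprocessConfig(**payload["config"]))
        plan.block_meta = payload["block_meta"]
        plan.columns = {
            blk: {col: _ColumnPlan(**cp) for col, cp in cols.items()}
            for blk, cols in payload["columns"].items()
        }
        return plan


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna()


def fit_preprocessor(
    train: MultiModalDataset, config: PreprocessConfig = PreprocessConfig()
) -> PreprocessingPlan:
    """Fit preprocessing statistics on training rows only.

    Order of operations: missingness screen (> threshold drops the column,
    strict) -> median imputation -> log(1+x) on expression-like blocks ->
    zero-variance removal -> standardization moments.
    """
    if train.n < 2:
        raise ValueError("need at least 2 training samples")
    if train.outcome.n_events < 1:
        raise ValueError("need at least one observed event to fit models downstream")

    plan = PreprocessingPlan(config)
    for block in train.blocks:
        cols: dict[str, _ColumnPlan] = {}
        for j, col in enumerate(block.frame.columns):
            kind = block.kinds[j]
            cp = _ColumnPlan(kind=kind)
            s = block.frame[col]
            if kind == NUMERIC:
                miss = _is_missing(s)
                if miss.mean() > config.missing_threshold:
                    cp.dropped, cp.drop_reason = True, "missing"
                    cols[col] = cp
                    continue
                vals = s[~miss].astype(float)
                cp.median = float(vals.median()) if miss.any() else None
                filled = s.astype(float).fillna(cp.median if cp.median is not None else 0.0)
                if block.expression_like:
                    if (filled < 0).any():
                        raise ValueError(
                            f"log-transform requested but column {col!r} in block "
                            f"{block.name!r} has negative values"
                        )
                    cp.log1p = True
                    filled = np.log1p(filled)
                sd = float(filled.std(ddof=0))
                if sd == 0.0:
                    cp.dropped, cp.drop_reason = True, "zero_variance"
                    cols[col] = cp
                    continue
                cp.mean, cp.sd = float(filled.mean()), sd
            else:
                levels = s.astype("object").where(~_is_missing(s), MISSING_CATEGORY)
                vocab = sorted(map(str, pd.unique(levels)))
                if len(vocab) < 2:
                    cp.dropped, cp.drop_reason = True, "zero_variance"
                    cols[col] = cp
                    continue
                cp.vocabulary = vocab
            cols[col] = cp
        if all(cp.dropped for cp in cols.values()):
            raise DegenerateBlockError(
                f"preprocessing drops every column of block {block.name!r}"
            )
        plan.columns[block.name] = cols
        plan.block_meta[block.name] = {
            "role_tag": block.role_tag,
            "expression_like": block.expression_like,
            "order": list(map(str, block.frame.columns)),
        }
    return plan


def _encode_categorical(
    s: pd.Series, vocab: list[str], col: str, encoding: str
) -> pd.DataFrame:
    levels = s.astype("object").where(~_is_missing(s), MISSING_CATEGORY).astype(str)
    use = vocab[1:] if encoding == "dummy" else vocab
    out = {}
    for lev in use:
        out[f"{col}={lev}"] = (levels == lev).astype(float).to_numpy()
    # unseen levels match nothing -> all-zero row, by construction
    return pd.DataFrame(out)


def apply_preprocessor(
    plan: PreprocessingPlan, data: MultiModalDataset
) -> MultiModalDataset:
    """Replay a fitted plan on data with the same schema (train or test)."""
    cfg = plan.config
    new_blocks = []
    if set(b.name for b in data.blocks) != set(plan.columns):
        raise SchemaError(
            f"block names {data.block_names} do not match plan {list(plan.columns)}"
        )
    for block in data.blocks:
        cols = plan.columns[block.name]
        expected = plan.block_meta[block.name]["order"]
        have = list(map(str, block.frame.columns))
        if have != expected:
            raise SchemaError(
                f"block {block.name!r}: columns {have} != fitted schema {expected}"
            )
        pieces: list[pd.DataFrame] = []
        for j, col in enumerate(block.frame.columns):
            cp = cols[str(col)]
            if cp.dropped:
                continue
            s = block.frame[col]
            if cp.kind == NUMERIC:
                v = s.astype(float)
                if v.isna().any():
                    fill = cp.median if cp.median is not None else cp.mean
                    v = v.fillna(fill)
                arr = v.to_numpy()
                if cp.log1p:
                    if (arr < 0).any():
                        raise ValueError(
                            f"negative values in log-flagged column {col!r}"
                        )
                    arr = np.log1p(arr)
                if cfg.standardize:
                    arr = (arr - cp.mean) / cp.sd
                pieces.append(pd.DataFrame({str(col): arr}))
            else:
                pieces.append(
                    _encode_categorical(
                        s, cp.vocabulary, str(col),
                        "onehot" if cfg.encoding == "onehot_raw" else cfg.encoding,
                    )
                )
        frame = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=range(block.n))
        new_blocks.append(
            ModalityBlock(
                block.name,
                frame.reset_index(drop=True),
                [NUMERIC] * frame.shape[1],
                block.role_tag,
                block.expression_like,
            )
        )
    return MultiModalDataset(new_blocks, data.outcome, data.sample_ids)


def fit_apply_pca_per_modality(
    train: MultiModalDataset, test: MultiModalDataset, k: int
) -> tuple[MultiModalDataset, MultiModalDataset]:
    """Replace each non-clinical block by its leading principal-component scores.

    Components are learned on the (standardized) training block only and test
    rows are projected onto them; the clinical block passes through untouched.
    If ``k`` exceeds the feasible rank for a block it is reduced with a warning.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    if k < 1:
        raise ValueError("k must be >= 1")

    def transform(blocks_tr, blocks_te):
        out_tr, out_te = [], []
        for btr, bte in zip(blocks_tr, blocks_te):
            if btr.role_tag == "clinical":
                out_tr.append(btr)
                out_te.append(bte)
                continue
            Xtr, Xte = btr.matrix(), bte.matrix()
            scaler = StandardScaler()
            sd = Xtr.std(axis=0)
            keep = sd > 0
            Xtr_s = scaler.fit_transform(Xtr[:, keep])
            Xte_s = scaler.transform(Xte[:, keep])
            feasible = min(k, Xtr_s.shape[0] - 1, Xtr_s.shape[1])
            rank = np.linalg.matrix_rank(Xtr_s) if min(Xtr_s.shape) <= 200 else feasible
            feasible = min(feasible, max(rank, 1))
            if feasible < k:
                warnings.warn(
                    f"block {btr.name!r}: reducing PCA components {k} -> {feasible}"
                )
            pca = PCA(n_components=feasible, svd_solver="auto", random_state=0)
            Str = pca.fit_transform(Xtr_s)
            Ste = pca.transform(Xte_s)
            cols = [f"{btr.name}_pc{i+1}" for i in range(feasible)]
            out_tr.append(
                ModalityBlock(btr.name, pd.DataFrame(Str, columns=cols),
                              [NUMERIC] * feasible, btr.role_tag, False)
            )
            out_te.append(
                ModalityBlock(bte.name, pd.DataFrame(Ste, columns=cols),
                              [NUMERIC] * feasible, bte.role_tag, False)
            )
        return out_tr, out_te

    tr_blocks, te_blocks = transform(train.blocks, test.blocks)
    return (
        MultiModalDataset(tr_blocks, train.outcome, train.sample_ids),
        MultiModalDataset(te_blocks, test.outcome, test.sample_ids),
    )
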