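"""The eight neural fusion strategies for multimodal Cox-loss survival models.

Fusion families
---------------
* early      — concatenate raw blocks, one joint network.
* intermediate — one subnetwork per modality producing an n x q representation,
  aggregated by mean / max / concatenation / learned attention / Embrace
  (multinomial cell sampling), then a linear hazard head.
* late       — one full network per modality producing a per-modality log
  hazard, combined by a fixed mean or a learned mixture-of-experts gate.

All networks share the same skeleton: two hidden layers of 128 and 64 units
with batch normalization and ReLU, a bias-free final linear layer emitting the
log hazard, trained full-batch with Adam (initial learning rate 0.01, plateau
factor 0.1 / patience 5), early stopping with patience 10 on a 10%
event-stratified validation split, for at most 100 epochs, under the Breslow
negative partial log-likelihood.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .base import FittedModel, ModelFailure, stratified_folds, stratified_holdout
from .data import MultiModalDataset, SurvivalOutcome
from .nn import autograd as ag
from .nn.layers import Adam, HiddenBlock, Linear
from .survival import (
    BaselineHazard,
    SurvivalCurveSet,
    breslow_baseline,
    cox_nll_breslow,
    predict_survival,
)

__all__ = [
    "FusionKind",
    "TrainingConfig",
    "HyperPoint",
    "HyperparameterGrid",
    "fuse_early",
    "fuse_mean",
    "fuse_max",
    "fuse_concat",
    "fuse_attention",
    "fuse_embrace",
    "fuse_late",
    "multimodal_dropout",
    "build_and_train",
    "tune_hyperparameters",
    "FittedFusionModel",
]

HIDDEN1, HIDDEN2 = 128, 64  # shared widths; q = HIDDEN2


class FusionKind(str, Enum):
    early = "early"
    intermediate_mean = "intermediate_mean"
    intermediate_max = "intermediate_max"
    intermediate_concat = "intermediate_concat"
    intermediate_attention = "intermediate_attention"
    intermediate_embrace = "intermediate_embrace"
    late_mean = "late_mean"
    late_moe = "late_moe"


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    max_epochs: int = 100
    early_stopping_patience: int = 10
    validation_fraction: float = 0.10
    seed: int = 0


@dataclass(frozen=True)
class HyperPoint:
    dropout: float = 0.0
    weight_decay: float = 0.01
    multimodal_dropout: float = 0.0


@dataclass(frozen=True)
class HyperparameterGrid:
    dropout: tuple = (0.0, 0.25, 0.5)
    weight_decay: tuple = (0.1, 0.01, 0.001)
    multimodal_dropout: tuple = (0.0,)  # extend to (0.0, 0.25, 0.5) to tune it

    def points(self) -> list[HyperPoint]:
        return [
            HyperPoint(d, w, m)
            for d, w, m in itertools.product(
                self.dropout, self.weight_decay, self.multimodal_dropout
            )
        ]


# ---------------------------------------------------------------------------
# Fusion operators (pure numpy; the in-graph versions mirror these exactly)
# ---------------------------------------------------------------------------

def _check_equal_shapes(reps):
    shapes = {r.shape for r in reps}
    if len(shapes) != 1:
        raise ValueError(f"representations disagree in shape: {shapes}")


def fuse_early(blocks: list[np.ndarray]) -> np.ndarray:
    """Column-wise concatenation of raw modality matrices."""
    rows = {b.shape[0] for b in blocks}
    if len(rows) != 1:
        raise ValueError(f"row counts disagree: {rows}")
    return np.hstack(blocks)


def fuse_mean(reps: list[np.ndarray]) -> np.ndarray:
    _check_equal_shapes(reps)
    return np.mean(reps, axis=0)


def fuse_max(reps: list[np.ndarray]) -> np.ndarray:
    _check_equal_shapes(reps)
    return np.max(reps, axis=0)


def fuse_concat(reps: list[np.ndarray]) -> np.ndarray:
    return fuse_early(reps)


def fuse_attention(reps: list[np.ndarray], A: np.ndarray) -> np.ndarray:
    """Per-sample convex combination: sum_i A[:, i] * reps[i]."""
    _check_equal_shapes(reps)
    A = np.asarray(A, dtype=float)
    if A.shape != (reps[0].shape[0], len(reps)):
        raise ValueError("A must be n x M")
    if np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("attention rows must be nonnegative and sum to 1")
    return sum(A[:, i : i + 1] * reps[i] for i in range(len(reps)))


def fuse_embrace(
    reps: list[np.ndarray], seed: int | np.random.Generator = 0, training: bool = True
) -> np.ndarray:
    """Multinomial cell sampling across modalities; expectation (mean) at inference."""
    _check_equal_shapes(reps)
    if not training or len(reps) == 1:
        return reps[0].copy() if len(reps) == 1 else fuse_mean(reps)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(reps), size=reps[0].shape)
    return np.take_along_axis(np.stack(reps), idx[None], axis=0)[0]


def fuse_late(per_modality_theta: list[np.ndarray], W: np.ndarray) -> np.ndarray:
    """theta = sum_i W[:, i] * f_i; rows of W are convex weights."""
    thetas = [np.asarray(t, dtype=float).ravel() for t in per_modality_theta]
    lengths = {len(t) for t in thetas}
    if len(lengths) != 1:
        raise ValueError("per-modality hazards disagree in length")
    W = np.asarray(W, dtype=float)
    if W.shape != (len(thetas[0]), len(thetas)):
        raise ValueError("W must be n x M")
    if np.any(W < 0) or not np.allclose(W.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("W rows must be nonnegative and sum to 1")
    return sum(W[:, i] * thetas[i] for i in range(len(thetas)))


def multimodal_dropout(
    tensors: list[np.ndarray],
    p: float,
    training: bool = True,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Inverted dropout at the modality level: each modality's whole tensor is
    zeroed with probability p during training, survivors scaled by 1/(1-p)."""
    if not 0.0 <= p < 1.0:
        raise ValueError("multimodal dropout probability must lie in [0, 1)")
    if not training or p == 0.0:
        return [np.asarray(t, dtype=float) for t in tensors]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = rng.uniform(size=len(tensors)) >= p
    return [
        np.asarray(t, dtype=float) * (k / (1.0 - p)) for t, k in zip(tensors, keep)
    ]


def _modality_dropout_masks(M: int, p: float, rng: np.random.Generator):
    if p == 0.0:
        return np.ones(M)
    return (rng.uniform(size=M) >= p) / (1.0 - p)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class _FusionNet:
    """One fusion network; forward maps a list of block matrices to (n, 1) theta."""

    def __init__(self, kind: FusionKind, dims: list[int], hp: HyperPoint,
                 rng: np.random.Generator):
        self.kind = kind
        self.dims = dims
        self.hp = hp
        M = len(dims)
        if kind == FusionKind.early:
            p = sum(dims)
            self.block1 = HiddenBlock(p, HIDDEN1, rng, hp.dropout)
            self.block2 = HiddenBlock(HIDDEN1, HIDDEN2, rng, hp.dropout)
            self.head = Linear(HIDDEN2, 1, rng, bias=False)
        elif kind in (FusionKind.late_mean, FusionKind.late_moe):
            self.subnets = [
                (
                    HiddenBlock(d, HIDDEN1, rng, hp.dropout),
                    HiddenBlock(HIDDEN1, HIDDEN2, rng, hp.dropout),
                    Linear(HIDDEN2, 1, rng, bias=False),
                )
                for d in dims
            ]
            if kind == FusionKind.late_moe:
                self.gate = Linear(sum(dims), M, rng)
        else:  # intermediate family
            self.subnets = [
                (
                    HiddenBlock(d, HIDDEN1, rng, hp.dropout),
                    HiddenBlock(HIDDEN1, HIDDEN2, rng, hp.dropout),
                )
                for d in dims
            ]
            head_in = HIDDEN2 * M if kind == FusionKind.intermediate_concat else HIDDEN2
            self.head = Linear(head_in, 1, rng, bias=False)
            if kind == FusionKind.intermediate_attention:
                self.scores = [Linear(HIDDEN2, 1, rng) for _ in range(M)]

    def parameters(self):
        params = []
        if self.kind == FusionKind.early:
            params += self.block1.parameters() + self.block2.parameters()
            params += self.head.parameters()
        elif self.kind in (FusionKind.late_mean, FusionKind.late_moe):
            for parts in self.subnets:
                for part in parts:
                    params += part.parameters()
            if self.kind == FusionKind.late_moe:
                params += self.gate.parameters()
        else:
            for parts in self.subnets:
                for part in parts:
                    params += part.parameters()
            params += self.head.parameters()
            if self.kind == FusionKind.intermediate_attention:
                for s in self.scores:
                    params += s.parameters()
        return params

    def forward(self, blocks: list[np.ndarray], training: bool,
                rng: np.random.Generator) -> ag.Tensor:
        kind = self.kind
        M = len(blocks)
        mm_p = self.hp.multimodal_dropout if training else 0.0

        if kind == FusionKind.early:
            masks = _modality_dropout_masks(M, mm_p, rng) if training else np.ones(M)
            X = np.hstack([b * m for b, m in zip(blocks, masks)])
            h = self.block1(ag.Tensor(X), training, rng)
            h = self.block2(h, training, rng)
            return self.head(h)

        if kind in (FusionKind.late_mean, FusionKind.late_moe):
            masks = _modality_dropout_masks(M, mm_p, rng) if training else np.ones(M)
            thetas = []
            for (b1, b2, out), X, m in zip(self.subnets, blocks, masks):
                h = b1(ag.Tensor(X * m), training, rng)
                h = b2(h, training, rng)
                thetas.append(out(h))
            if kind == FusionKind.late_mean:
                return ag.mean_stack(thetas)
            W = ag.softmax_rows(self.gate(ag.Tensor(np.hstack(blocks))))
            return ag.weighted_sum(thetas, W)

        # intermediate family: subnet representations, modality dropout on reps
        reps = []
        for (b1, b2), X in zip(self.subnets, blocks):
            h = b1(ag.Tensor(X), training, rng)
            reps.append(b2(h, training, rng))
        if mm_p > 0.0:
            masks = _modality_dropout_masks(M, mm_p, rng)
            reps = [ag.scale(r, m) for r, m in zip(reps, masks)]

        if kind == FusionKind.intermediate_mean:
            fused = ag.mean_stack(reps)
        elif kind == FusionKind.intermediate_max:
            fused = ag.max_stack(reps)
        elif kind == FusionKind.intermediate_concat:
            fused = ag.concat(reps, axis=1)
        elif kind == FusionKind.intermediate_attention:
            score_cols = [self.scores[i](reps[i]) for i in range(M)]
            A = ag.softmax_rows(ag.concat(score_cols, axis=1))
            fused = ag.weighted_sum(reps, A)
        elif kind == FusionKind.intermediate_embrace:
            if training and M > 1:
                idx = rng.integers(0, M, size=reps[0].data.shape)
                fused = ag.select_stack(reps, idx)
            else:
                fused = ag.mean_stack(reps)
        else:  # pragma: no cover
            raise ValueError(kind)
        return self.head(fused)


@dataclass
class FittedFusionModel:
    """Trained fusion network exposing log hazards and Breslow survival curves."""

    net: _FusionNet
    baseline: BaselineHazard
    validation_losses: list[float] = field(default_factory=list)

    def predict_theta(self, data: MultiModalDataset) -> np.ndarray:
        rng = np.random.default_rng(0)  # inference path draws nothing
        theta = self.net.forward(data.matrices(), training=False, rng=rng)
        return theta.data.ravel()

    def predict_survival_curves(self, data: MultiModalDataset, grid) -> SurvivalCurveSet:
        theta = self.predict_theta(data)
        if not np.all(np.isfinite(theta)):
            raise ModelFailure("non-finite log hazards at prediction time")
        return predict_survival(theta, self.baseline, grid)

    def save(self, path) -> None:
        """Persist weights, batch-norm state and the Breslow baseline together."""
        import json

        meta = {"kind": self.net.kind.value, "dims": list(self.net.dims),
                "hp": vars(self.net.hp)}
        arrays = {f"p{i}": p.data for i, p in enumerate(self.net.parameters())}
        for i, bn in enumerate(_bn_layers(self.net)):
            arrays[f"bn{i}_mean"] = bn.running_mean
            arrays[f"bn{i}_var"] = bn.running_var
        arrays["baseline_times"] = self.baseline.event_times
        arrays["baseline_chaz"] = self.baseline.cumulative_hazard
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FittedFusionModel":
        import json

        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        net = _FusionNet(FusionKind(meta["kind"]), meta["dims"],
                         HyperPoint(**meta["hp"]), np.random.default_rng(0))
        for i, p in enumerate(net.parameters()):
            p.data = data[f"p{i}"]
        for i, bn in enumerate(_bn_layers(net)):
            bn.running_mean = data[f"bn{i}_mean"]
            bn.running_var = data[f"bn{i}_var"]
        baseline = BaselineHazard(data["baseline_times"], data["baseline_chaz"])
        return cls(net, baseline)


def build_and_train(
    data: MultiModalDataset,
    kind: FusionKind,
    config: TrainingConfig = TrainingConfig(),
    hp: HyperPoint = HyperPoint(),
) -> FittedFusionModel:
    """Train one fusion network under the full protocol on preprocessed data."""
    kind = FusionKind(kind)
    rng = np.random.default_rng([config.seed, 11])
    event = data.outcome.event
    if event.sum() < 2:
        raise ValueError("need at least 2 events in the training data")
    tr_idx, val_idx = stratified_holdout(event, config.validation_fraction, rng)
    train_ds, val_ds = data.subset(tr_idx), data.subset(val_idx)
    if train_ds.outcome.n_events < 2:
        raise ValueError("need at least 2 events in the 90% training portion")

    net = _FusionNet(kind, [b.width for b in data.blocks], hp, rng)
    params = net.parameters()
    opt = Adam(params, lr=config.learning_rate, weight_decay=hp.weight_decay)

    train_blocks = train_ds.matrices()
    val_blocks = val_ds.matrices()
    best_val = np.inf
    best_snapshot = None
    val_trajectory: list[float] = []
    epochs_since_best = 0
    epochs_since_plateau = 0

    for epoch in range(config.max_epochs):
        theta = net.forward(train_blocks, training=True, rng=rng)
        loss = ag.cox_loss(theta, train_ds.outcome)
        if not np.isfinite(loss.data):
            raise ModelFailure(f"training loss diverged at epoch {epoch}")
        loss.backward()
        opt.step()

        theta_val = net.forward(val_blocks, training=False, rng=rng)
        val_loss = cox_nll_breslow(theta_val.data.ravel(), val_ds.outcome)
        val_trajectory.append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snapshot = [p.data.copy() for p in params]
            best_bn = _bn_state(net)
            epochs_since_best = 0
            epochs_since_plateau = 0
        else:
            epochs_since_best += 1
            epochs_since_plateau += 1
        if epochs_since_plateau > config.plateau_patience:
            opt.lr *= config.plateau_factor
            epochs_since_plateau = 0
        if epochs_since_best > config.early_stopping_patience:
            break

    if best_snapshot is None:
        raise ModelFailure("validation loss never became finite")
    for p, s in zip(params, best_snapshot):
        p.data = s
    _restore_bn(net, best_bn)

    theta_full = net.forward(train_ds.matrices(), training=False,
                             rng=np.random.default_rng(0)).data.ravel()
    if not np.all(np.isfinite(theta_full)):
        raise ModelFailure("non-finite training log hazards")
    baseline = breslow_baseline(theta_full, train_ds.outcome)
    return FittedFusionModel(net, baseline, val_trajectory)


def _bn_layers(net: _FusionNet):
    layers = []
    if net.kind == FusionKind.early:
        layers = [net.block1.bn, net.block2.bn]
    else:
        for parts in net.subnets:
            for part in parts:
                if isinstance(part, HiddenBlock):
                    layers.append(part.bn)
    return layers


def _bn_state(net):
    return [(bn.running_mean.copy(), bn.running_var.copy()) for bn in _bn_layers(net)]


def _restore_bn(net, state):
    for bn, (m, v) in zip(_bn_layers(net), state):
        bn.running_mean, bn.running_var = m.copy(), v.copy()


def tune_hyperparameters(
    data: MultiModalDataset,
    kind: FusionKind,
    config: TrainingConfig = TrainingConfig(),
    grid: HyperparameterGrid = HyperparameterGrid(),
) -> HyperPoint:
    """Grid search scored by mean held-out partial log-likelihood over 5
    event-stratified folds; ties break toward the earlier grid point."""
    points = grid.points()
    if not points:
        raise ValueError("empty hyperparameter grid")
    if len(points) == 1:
        return points[0]
    rng = np.random.default_rng([config.seed, 23])
    fold = stratified_folds(data.outcome.event, 5, rng)
    best_score, best_point = -np.inf, points[0]
    for point in points:
        scores = []
        for f in range(5):
            tr, te = np.flatnonzero(fold != f), np.flatnonzero(fold == f)
            try:
                model = build_and_train(data.subset(tr), kind, config, point)
                theta = model.predict_theta(data.subset(te))
                scores.append(-cox_nll_breslow(theta, data.subset(te).outcome))
            except (ModelFailure, ValueError):
                continue
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best_point = score, point
    return best_point
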