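"""Fusion operator algebra, multimodal dropout semantics, the autodiff engine,
and the end-to-end training protocol of the fusion networks."""

import numpy as np
import pytest

from survfuse.base import stratified_holdout
from survfuse.data import SurvivalOutcome, apply_preprocessor, fit_preprocessor
from survfuse.fusion import (
    FusionKind,
    HyperparameterGrid,
    HyperPoint,
    TrainingConfig,
    build_and_train,
    fuse_attention,
    fuse_concat,
    fuse_early,
    fuse_embrace,
    fuse_late,
    fuse_max,
    fuse_mean,
    multimodal_dropout,
    tune_hyperparameters,
)
from survfuse.metrics import antolini_concordance, ibs_time_grid
from survfuse.nn import autograd as ag
from survfuse.nn.layers import BatchNorm1d, Linear


@pytest.fixture
def reps(rng):
    return [rng.standard_normal((6, 4)) for _ in range(3)]


class TestFusionAlgebra:
    def test_early_concat_widths_and_order(self, rng):
        a, b = rng.standard_normal((5, 3)), rng.standard_normal((5, 2))
        out = fuse_early([a, b])
        assert out.shape == (5, 5)
        np.testing.assert_array_equal(out[:, :3], a)
        np.testing.assert_array_equal(fuse_early([a]), a)

    def test_early_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_early([rng.standard_normal((5, 2)), rng.standard_normal((4, 2))])

    def test_mean_of_copies_is_identity(self, rng):
        r = rng.standard_normal((4, 3))
        np.testing.assert_allclose(fuse_mean([r, r, r]), r)

    def test_mean_matches_explicit_sum(self, reps):
        np.testing.assert_allclose(fuse_mean(reps), sum(reps) / 3, atol=1e-12)

    def test_max_dominates_mean_and_matches_oracle(self, reps):
        fused = fuse_max(reps)
        assert np.all(fused >= fuse_mean(reps) - 1e-12)
        oracle = np.maximum(np.maximum(reps[0], reps[1]), reps[2])
        np.testing.assert_array_equal(fused, oracle)

    def test_concat_is_block_columnwise(self, reps):
        out = fuse_concat(reps)
        assert out.shape == (6, 12)
        np.testing.assert_array_equal(out[:, 4:8], reps[1])

    def test_attention_onehot_selects_modality(self, reps):
        A = np.zeros((6, 3))
        A[:, 1] = 1.0
        np.testing.assert_allclose(fuse_attention(reps, A), reps[1])

    def test_attention_uniform_equals_mean(self, reps):
        A = np.full((6, 3), 1 / 3)
        np.testing.assert_allclose(fuse_attention(reps, A), fuse_mean(reps), atol=1e-12)

    def test_attention_random_matches_weighted_sum(self, reps, rng):
        raw = rng.uniform(size=(6, 3))
        A = raw / raw.sum(1, keepdims=True)
        oracle = sum(A[:, [i]] * reps[i] for i in range(3))
        np.testing.assert_allclose(fuse_attention(reps, A), oracle, atol=1e-12)

    def test_attention_rowsum_violation_rejected(self, reps):
        with pytest.raises(ValueError):
            fuse_attention(reps, np.full((6, 3), 0.5))

    def test_embrace_single_modality_is_identity(self, rng):
        r = rng.standard_normal((5, 4))
        np.testing.assert_array_equal(fuse_embrace([r], seed=0), r)

    def test_embrace_cells_copied_from_some_modality(self, reps):
        fused = fuse_embrace(reps, seed=3)
        stacked = np.stack(reps)
        assert np.all((fused[None] == stacked).any(axis=0))

    def test_embrace_inference_is_mean(self, reps):
        np.testing.assert_allclose(
            fuse_embrace(reps, seed=0, training=False), fuse_mean(reps)
        )

    def test_embrace_monte_carlo_mean_converges_to_mean_fusion(self, reps):
        rng = np.random.default_rng(0)
        draws = np.mean([fuse_embrace(reps, seed=rng) for _ in range(10_000)], axis=0)
        spread = np.stack(reps).std(axis=0)
        se = spread / np.sqrt(10_000) * np.sqrt(3)  # between-modality variance
        assert np.all(np.abs(draws - fuse_mean(reps)) < 3 * se + 1e-3)

    def test_late_equal_hazards_ignore_weights(self, rng):
        f = rng.standard_normal(7)
        W = rng.dirichlet(np.ones(3), size=7)
        np.testing.assert_allclose(fuse_late([f, f, f], W), f, atol=1e-12)

    def test_late_mean_two_modalities(self):
        out = fuse_late([np.array([1.0]), np.array([-1.0])], np.full((1, 2), 0.5))
        assert out[0] == pytest.approx(0.0)

    def test_late_random_weights_match_oracle(self, rng):
        fs = [rng.standard_normal(5) for _ in range(3)]
        W = rng.dirichlet(np.ones(3), size=5)
        oracle = sum(W[:, i] * fs[i] for i in range(3))
        np.testing.assert_allclose(fuse_late(fs, W), oracle, atol=1e-12)


class TestMultimodalDropout:
    def test_p_zero_is_identity(self, reps):
        out = multimodal_dropout(reps, 0.0, training=True, seed=0)
        for a, b in zip(out, reps):
            np.testing.assert_array_equal(a, b)

    def test_inference_identity_for_any_p(self, reps):
        out = multimodal_dropout(reps, 0.9, training=False, seed=0)
        for a, b in zip(out, reps):
            np.testing.assert_array_equal(a, b)

    def test_p_one_rejected(self, reps):
        with pytest.raises(ValueError):
            multimodal_dropout(reps, 1.0)

    def test_inverted_dropout_is_unbiased(self, rng):
        x = [np.ones((1, 1)), np.full((1, 1), 2.0)]
        acc = np.zeros(2)
        n = 10_000
        for _ in range(n):
            out = multimodal_dropout(x, 0.5, training=True, seed=rng)
            acc += [out[0][0, 0], out[1][0, 0]]
        np.testing.assert_allclose(acc / n, [1.0, 2.0], atol=0.1)


class TestAutogradEngine:
    def test_mlp_gradients_match_finite_differences(self, rng):
        x = rng.standard_normal((8, 5))
        lin = Linear(5, 3, rng)
        bn = BatchNorm1d(3)
        head = Linear(3, 1, rng, bias=False)
        o = SurvivalOutcome(rng.uniform(1, 5, 8), np.ones(8))

        def loss_val():
            h = ag.relu(bn(lin(ag.Tensor(x)), training=True))
            return ag.cox_loss(head(h), o)

        loss = loss_val()
        loss.backward()
        params = lin.parameters() + bn.parameters() + head.parameters()
        grads = [p.grad.copy() for p in params]
        eps = 1e-6
        for p, g in zip(params, grads):
            flat = p.data.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 4)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_val().data
                flat[idx] = orig - eps
                dn = loss_val().data
                flat[idx] = orig
                assert g.ravel()[idx] == pytest.approx((up - dn) / (2 * eps), abs=2e-4)

    def test_softmax_rows_sum_to_one_and_grad_flows(self, rng):
        x = ag.Tensor(rng.standard_normal((4, 3)))
        y = ag.softmax_rows(x)
        np.testing.assert_allclose(y.data.sum(1), 1.0, atol=1e-12)
        s = ag.mul(y, ag.Tensor(np.ones((4, 3))))
        loss = ag.cox_loss(
            ag.matmul(s, ag.Tensor(np.ones((3, 1)))),
            SurvivalOutcome([1.0, 2, 3, 4], [1, 1, 1, 1]),
        )
        loss.backward()
        # softmax rows sum to one, so a row-constant downstream gradient
        # must cancel exactly
        np.testing.assert_allclose(x.grad, 0.0, atol=1e-12)


def _split_train_test(gen, n_train):
    ds = gen.dataset
    tr, te = np.arange(n_train), np.arange(n_train, ds.n)
    plan = fit_preprocessor(ds.subset(tr))
    return apply_preprocessor(plan, ds.subset(tr)), apply_preprocessor(plan, ds.subset(te))


class TestTraining:
    @pytest.mark.parametrize("kind", list(FusionKind))
    def test_predictions_are_valid_curves(self, kind, medium_generated):
        train, test = _split_train_test(medium_generated, 200)
        model = build_and_train(
            train, kind, TrainingConfig(max_epochs=25, seed=1), HyperPoint()
        )
        grid = ibs_time_grid(test.outcome)
        curves = model.predict_survival_curves(test, grid)
        assert curves.surv.shape == (test.n, len(grid))
        assert np.all((curves.surv >= 0) & (curves.surv <= 1))
        assert np.all(np.diff(curves.surv, axis=1) <= 1e-12)

    def test_fixed_seed_reproduces_validation_trajectory(self, medium_generated):
        train, _ = _split_train_test(medium_generated, 200)
        cfg = TrainingConfig(max_epochs=15, seed=5)
        m1 = build_and_train(train, FusionKind.intermediate_mean, cfg, HyperPoint(0.25))
        m2 = build_and_train(train, FusionKind.intermediate_mean, cfg, HyperPoint(0.25))
        assert m1.validation_losses == m2.validation_losses

    def test_pure_noise_training_stays_near_chance(self):
        from survfuse.simulate import BlockSpec, SimulationConfig, simulate_multiomics_survival

        cs = []
        for seed in range(3):
            cfg = SimulationConfig(
                n=400,
                blocks=(
                    BlockSpec("clinical", 4, 0, 0.0, 0.0, "clinical"),
                    BlockSpec("omics", 30, 0, 0.0),
                ),
                censoring_rate=0.3,
                seed=seed,
            )
            gen = simulate_multiomics_survival(cfg)
            train, test = _split_train_test(gen, 300)
            model = build_and_train(
                train, FusionKind.late_mean, TrainingConfig(seed=seed), HyperPoint()
            )
            grid = ibs_time_grid(test.outcome)
            cs.append(
                antolini_concordance(model.predict_survival_curves(test, grid), test.outcome)
            )
        assert 0.4 <= np.mean(cs) <= 0.6

    def test_signal_is_learned_above_chance(self, medium_generated):
        train, test = _split_train_test(medium_generated, 200)
        model = build_and_train(
            train, FusionKind.intermediate_concat, TrainingConfig(seed=2), HyperPoint()
        )
        grid = ibs_time_grid(test.outcome)
        c = antolini_concordance(model.predict_survival_curves(test, grid), test.outcome)
        assert c > 0.6


class TestTuning:
    def test_singleton_grid_returned_without_search(self, medium_generated):
        train, _ = _split_train_test(medium_generated, 200)
        grid = HyperparameterGrid((0.25,), (0.01,), (0.0,))
        best = tune_hyperparameters(train, FusionKind.early, TrainingConfig(seed=0), grid)
        assert best == HyperPoint(0.25, 0.01, 0.0)

    def test_grid_accounting_nine_points_forty_five_fits(self, monkeypatch, medium_generated):
        train, _ = _split_train_test(medium_generated, 120)
        calls = []
        import survfuse.fusion as fusion_mod

        real = fusion_mod.build_and_train

        def counting(data, kind, config, hp):
            calls.append(hp)
            return real(data, kind, TrainingConfig(max_epochs=1, seed=config.seed), hp)

        monkeypatch.setattr(fusion_mod, "build_and_train", counting)
        grid = HyperparameterGrid((0.0, 0.25, 0.5), (0.1, 0.01, 0.001), (0.0,))
        tune_hyperparameters(train, FusionKind.early, TrainingConfig(seed=0), grid)
        assert len(calls) == 45  # 9 grid points x 5 folds

    def test_dominating_point_is_selected(self, monkeypatch, medium_generated):
        # plant a grid point whose held-out likelihood dominates every fold
        train, _ = _split_train_test(medium_generated, 120)
        import survfuse.fusion as fusion_mod

        class Planted:
            def __init__(self, good):
                self.good = good

            def predict_theta(self, data):
                # an oracle ranking beats the flat predictor on every fold
                if self.good:
                    return -np.log(data.outcome.time)
                return np.zeros(data.n)

        def fake_fit(data, kind, config, hp):
            return Planted(hp.weight_decay == 0.001)

        monkeypatch.setattr(fusion_mod, "build_and_train", fake_fit)
        grid = HyperparameterGrid((0.0,), (0.1, 0.01, 0.001), (0.0,))
        best = tune_hyperparameters(train, FusionKind.early, TrainingConfig(seed=0), grid)
        assert best.weight_decay == 0.001

    def test_grid_order_breaks_ties_first_wins(self, monkeypatch, medium_generated):
        train, _ = _split_train_test(medium_generated, 120)
        import survfuse.fusion as fusion_mod

        class Stub:
            def predict_theta(self, data):
                return np.zeros(data.n)

        monkeypatch.setattr(fusion_mod, "build_and_train", lambda *a, **k: Stub())
        grid = HyperparameterGrid((0.0, 0.5), (0.1, 0.001), (0.0,))
        best = tune_hyperparameters(train, FusionKind.early, TrainingConfig(seed=0), grid)
        assert best == grid.points()[0]


class TestValidationSplit:
    def test_holdout_is_event_stratified(self, rng):
        event = np.r_[np.ones(40), np.zeros(60)].astype(bool)
        tr, hold = stratified_holdout(event, 0.10, rng)
        assert len(hold) == 10
        assert event[hold].sum() == 4
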