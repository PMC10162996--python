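"""Split accounting, failure fallback semantics, determinism, the statistics
layer (Wilcoxon + Holm) and Kaplan-Meier risk stratification."""

import numpy as np
import pytest

from survfuse.base import ModelFailure
from survfuse.data import PreprocessConfig, SurvivalOutcome
from survfuse.harness import (
    ExperimentSetting,
    ModelSpec,
    aggregate_and_compare,
    km_stratification,
    make_splits,
    rank_models,
    records_frame,
    run_benchmark,
)
from survfuse.metrics import MetricRecord
from survfuse.simulate import SimulationConfig, default_blocks, simulate_multiomics_survival
from survfuse.survival import SurvivalCurveSet, breslow_baseline, predict_survival
from .conftest import random_outcome


@pytest.fixture(scope="module")
def two_datasets():
    out = {}
    for i, seed in enumerate((31, 32)):
        cfg = SimulationConfig(
            n=120, blocks=default_blocks(gex_dim=10, gex_informative=3),
            censoring_rate=0.4, seed=seed,
        )
        out[f"cohort_{i}"] = simulate_multiomics_survival(cfg).dataset
    return out


class _ThetaModel:
    """Cheap deterministic stand-in model: theta = first-column value."""

    def __init__(self, train, seed):
        self.baseline = breslow_baseline(self._theta(train), train.outcome)

    @staticmethod
    def _theta(data):
        return data.blocks[0].matrix()[:, 0]

    def predict_theta(self, data):
        return self._theta(data)

    def predict_survival_curves(self, data, grid):
        return predict_survival(self._theta(data), self.baseline, grid)


def _theta_spec(name="linear"):
    return ModelSpec(name, lambda train, seed: _ThetaModel(train, seed))


def _failing_spec(name="broken"):
    def fit(train, seed):
        raise ModelFailure("always fails")

    return ModelSpec(name, fit)


class TestMakeSplits:
    def test_event_counts_proportional_within_one(self):
        rng = np.random.default_rng(0)
        o = SurvivalOutcome(rng.uniform(1, 10, 100), np.r_[np.ones(40), np.zeros(60)])
        plan = make_splits(o, seed=1)
        for _, _, tr, te in plan:
            assert o.event[te].sum() == 8

    def test_folds_partition_each_repeat(self):
        rng = np.random.default_rng(1)
        o = random_outcome(rng, 83)
        plan = make_splits(o, repeats=5, folds=5, seed=2)
        assert len(plan.pairs) == 25
        for r in range(5):
            tests = [te for rr, _, _, te in plan if rr == r]
            allidx = np.sort(np.concatenate(tests))
            np.testing.assert_array_equal(allidx, np.arange(83))

    def test_same_seed_identical_plans(self):
        rng = np.random.default_rng(2)
        o = random_outcome(rng, 60)
        p1 = make_splits(o, seed=7)
        p2 = make_splits(o, seed=7)
        for (r1, f1, a1, b1), (r2, f2, a2, b2) in zip(p1, p2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)

    def test_too_few_events_raises(self):
        o = SurvivalOutcome([1.0, 2, 3, 4, 5, 6], [1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            make_splits(o)


class TestRunBenchmark:
    def test_record_accounting(self, two_datasets):
        settings = [ExperimentSetting("base", blocks=("clinical", "gex"))]
        models = {"linear": _theta_spec()}
        records = run_benchmark(two_datasets, models, settings, seed=1)
        assert len(records) == 2 * 1 * 1 * 25
        df = records_frame(records)
        assert set(df.groupby("dataset_id").size()) == {25}

    def test_always_failing_model_yields_flagged_km_fallback(self, two_datasets):
        one = {"cohort_0": two_datasets["cohort_0"]}
        records = run_benchmark(one, {"broken": _failing_spec()},
                                [ExperimentSetting("base")], seed=1)
        assert len(records) == 25
        assert all(r.model_failed for r in records)
        assert all(r.antolini_c == 0.5 for r in records)

    def test_identical_seed_identical_record_stream(self, two_datasets):
        one = {"cohort_0": two_datasets["cohort_0"]}
        args = (one, {"linear": _theta_spec()}, [ExperimentSetting("base")])
        r1 = run_benchmark(*args, seed=3)
        r2 = run_benchmark(*args, seed=3)
        assert r1 == r2

    def test_no_information_leak_from_test_outcomes(self, two_datasets):
        # randomizing test-fold outcomes must leave fitted predictions unchanged
        ds = two_datasets["cohort_0"]
        plan = make_splits(ds.outcome, seed=5)
        _, _, tr, te = plan.pairs[0]
        from survfuse.data import apply_preprocessor, fit_preprocessor

        pre_plan = fit_preprocessor(ds.subset(tr))
        model = _ThetaModel(apply_preprocessor(pre_plan, ds.subset(tr)), 0)
        test = ds.subset(te)
        rng = np.random.default_rng(0)
        scrambled = test.subset(rng.permutation(test.n))
        t1 = model.predict_theta(apply_preprocessor(pre_plan, test))
        t2 = model.predict_theta(apply_preprocessor(pre_plan, scrambled))
        np.testing.assert_allclose(np.sort(t1), np.sort(t2))


class TestStatisticsLayer:
    @staticmethod
    def records_for(model, values):
        return [
            MetricRecord(f"d{i}", model, "s0", v, 0.1) for i, v in enumerate(values)
        ]

    def test_self_comparison_gives_p_one(self):
        vals = list(np.linspace(0.5, 0.7, 17))
        recs = self.records_for("a", vals) + self.records_for("b", vals)
        res = aggregate_and_compare(recs, "a", holm=False)
        assert res[0].p_raw == 1.0

    def test_wilcoxon_matches_scipy_on_17_datasets(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.5, 0.7, 17)
        b = a + rng.normal(0.01, 0.02, 17)
        recs = self.records_for("a", a) + self.records_for("b", b)
        res = aggregate_and_compare(recs, "a", alternative="less", holm=False)
        from scipy.stats import wilcoxon

        stat, p = wilcoxon(b, a, alternative="less")
        assert res[0].statistic == pytest.approx(stat)
        assert res[0].p_raw == pytest.approx(p)

    def test_wilcoxon_statistic_matches_hand_rank_tabulation(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0.5, 0.7, 17)
        d = rng.normal(0.0, 0.02, 17)
        b = a + d
        # brute-force signed-rank sum of positive differences
        diffs = b - a
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_pos = ranks[diffs > 0].sum()
        w_neg = ranks[diffs < 0].sum()
        recs = self.records_for("a", a) + self.records_for("b", b)
        res = aggregate_and_compare(recs, "a", alternative="two-sided", holm=False)
        assert res[0].statistic == pytest.approx(min(w_pos, w_neg))

    def test_holm_stepdown_closed_form(self):
        recs = (
            self.records_for("ref", np.linspace(0.5, 0.6, 8))
            + self.records_for("m1", np.linspace(0.52, 0.62, 8))
            + self.records_for("m2", np.linspace(0.45, 0.55, 8))
        )
        res = aggregate_and_compare(recs, "ref", alternative="two-sided", holm=True)
        raw = sorted(r.p_raw for r in res)
        adj = {r.p_raw: r.p_adjusted for r in res}
        assert adj[raw[0]] == pytest.approx(min(1.0, 2 * raw[0]))
        assert adj[raw[1]] == pytest.approx(min(1.0, max(2 * raw[0], raw[1])))
        assert all(r.p_adjusted >= r.p_raw for r in res)

    def test_missing_reference_raises(self):
        recs = self.records_for("a", [0.6] * 3)
        with pytest.raises(ValueError):
            aggregate_and_compare(recs, "nope")


class TestRankModels:
    @staticmethod
    def rec(d, m, c):
        return MetricRecord(d, m, "s0", c, 0.1)

    def test_distinct_means_rank_one_two_three(self):
        recs = [self.rec("d0", m, c) for m, c in [("a", 0.7), ("b", 0.6), ("c", 0.5)]]
        table = rank_models(recs)
        assert list(table.loc["d0", ["a", "b", "c"]]) == [1.0, 2.0, 3.0]

    def test_ties_get_average_rank(self):
        recs = [self.rec("d0", m, c) for m, c in [("a", 0.7), ("b", 0.7), ("c", 0.5)]]
        table = rank_models(recs)
        assert table.loc["d0", "a"] == 1.5
        assert table.loc["d0", "b"] == 1.5

    def test_row_sums_constant(self):
        rng = np.random.default_rng(3)
        recs = [
            self.rec(f"d{i}", m, rng.uniform(0.4, 0.8))
            for i in range(4)
            for m in "abc"
        ]
        table = rank_models(recs)
        np.testing.assert_allclose(table.sum(axis=1), 6.0)

    def test_ibs_ranks_ascending(self):
        recs = [
            MetricRecord("d0", m, "s0", 0.6, v) for m, v in [("a", 0.1), ("b", 0.3)]
        ]
        table = rank_models(recs, metric="ibs")
        assert table.loc["d0", "a"] == 1.0


class TestKMStratification:
    def test_oracle_predictions_separate_groups(self):
        rng = np.random.default_rng(12)
        n = 300
        eta = rng.normal(0, 1.2, n)
        T = (-np.log(rng.uniform(size=n)) / (0.1 * np.exp(eta))) ** 0.5
        o = SurvivalOutcome(T, np.ones(n))
        grid = np.linspace(T.min(), np.quantile(T, 0.95), 80)
        base = breslow_baseline(eta, o)
        per_repeat = [predict_survival(eta, base, grid) for _ in range(5)]
        result = km_stratification(per_repeat, o, horizon=float(np.median(T)))
        assert result["p_value"] < 0.01
        # below-median predicted survival = worse prognosis = earlier events
        below, above = result["below_median"], result["above_median"]
        mid = np.median(T)
        assert below.at([mid])[0] < above.at([mid])[0]

    def test_null_predictions_give_uniform_p(self):
        # under random predictions the log-rank p across simulations is uniform
        from scipy.stats import kstest

        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            n = 60
            o = SurvivalOutcome(rng.uniform(1, 10, n), np.ones(n))
            grid = np.linspace(1, 9, 30)
            surv = np.minimum.accumulate(
                np.clip(rng.uniform(0.4, 1.0, (n, 30)), 0, 1), axis=1
            )
            curves = SurvivalCurveSet(grid, surv)
            ps.append(km_stratification([curves], o, horizon=5.0)["p_value"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_median_split_sizes(self):
        rng = np.random.default_rng(8)
        n = 31
        o = SurvivalOutcome(rng.uniform(1, 10, n), np.ones(n))
        grid = np.linspace(1, 9, 20)
        surv = np.minimum.accumulate(rng.uniform(0.2, 1.0, (n, 20)), axis=1)
        result = km_stratification([SurvivalCurveSet(grid, surv)], o, horizon=5.0)
        sizes = {int((result["totals"] > np.median(result["totals"])).sum()),
                 int((result["totals"] <= np.median(result["totals"])).sum())}
        assert sizes == {n // 2, n - n // 2}

    def test_identical_totals_raise(self):
        o = SurvivalOutcome([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        grid = np.array([1.0, 2.0])
        curves = SurvivalCurveSet(grid, np.full((4, 2), 0.5))
        with pytest.raises(ValueError):
            km_stratification([curves], o, horizon=1.5)


class TestStandardSettings:
    def test_named_recipes_cover_the_design(self):
        from survfuse.harness import standard_settings

        s = standard_settings(noise_dim=100)
        assert {"clinical_gex", "all_modalities", "leak", "noise_1", "noise_3",
                "noise_5", "leak_plus_noise_5", "pca_32", "pca_64"} <= set(s)
        assert s["noise_3"].noise_count == 3
        assert s["leak_plus_noise_1"].leak

    def test_recipes_apply_deterministically(self, two_datasets):
        from survfuse.harness import standard_settings

        s = standard_settings(noise_dim=20)
        ds = two_datasets["cohort_0"]
        a = s["noise_1"].apply(ds, seed=3)
        b = s["noise_1"].apply(ds, seed=3)
        np.testing.assert_array_equal(
            a.block("noise_1").matrix(), b.block("noise_1").matrix()
        )
        leaked = s["leak"].apply(ds, seed=0)
        assert "observed_time" in leaked.block("clinical").frame.columns
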