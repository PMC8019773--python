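import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hfpef_risk.config import GAConfig, PipelineConfig, SynthConfig
from hfpef_risk.evaluation import (
    auc_rank,
    confusion_metrics,
    dunnett_compare,
    repeated_evaluation,
    split_indices,
)


class TestConfusionMetrics:
    def test_youden_identity_on_table2_means(self):
        # Youden = Se + Sp - 1 recomputed from published mean Se/Sp
        assert 0.925 + 0.984 - 1 == pytest.approx(0.909, abs=5e-4)
        assert 0.469 + 1.000 - 1 == pytest.approx(0.469, abs=5e-4)

    def test_perfect_predictions_all_ones(self):
        y = np.array([0, 1, 0, 1, 1])
        m = confusion_metrics(y, y, y.astype(float))
        for v in m.as_dict().values():
            assert v == pytest.approx(1.0)

    def test_hand_computed_confusion_table(self):
        # TP=3 FN=1 TN=5 FP=1
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        lab = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 1])
        m = confusion_metrics(y, lab, lab.astype(float))
        assert m.se == pytest.approx(0.75)
        assert m.sp == pytest.approx(5 / 6, abs=1e-4)
        assert m.acc == pytest.approx(0.8)
        assert m.mcc == pytest.approx(14 / 24, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.ones(4), np.ones(4), np.ones(4))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=4, max_size=40))
    def test_metric_identities_hold_everywhere(self, rows):
        y = np.array([r[0] for r in rows])
        if y.min() == y.max():
            return
        lab = np.array([r[1] for r in rows])
        s = np.array([r[2] for r in rows])
        m = confusion_metrics(y, lab, s)
        assert m.youden == pytest.approx(m.se + m.sp - 1.0, abs=1e-12)
        assert m.g_means == pytest.approx(np.sqrt(m.se * m.sp), abs=1e-12)
        assert -1.0 <= m.mcc <= 1.0
        assert 0.0 <= m.auc <= 1.0


class TestAucRank:
    def test_perfect_separation(self):
        assert auc_rank([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_rank([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_pair_enumeration_example(self):
        # pairs: (0.9,0.8)+, (0.9,0.1)+, (0.7,0.8)-, (0.7,0.1)+ -> 3/4
        assert auc_rank([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert auc_rank(y, s) == pytest.approx(auc_rank(y, np.exp(s)), abs=1e-12)


class TestSplitIndices:
    def test_cohort_sizes_match_published_protocol(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 42 + [0] * 107)
        tr, te = split_indices(149, 0.8, rng, y=y)
        assert (len(tr), len(te)) == (120, 29)

    def test_small_n(self):
        rng = np.random.default_rng(0)
        tr, te = split_indices(10, 0.8, rng)
        assert (len(tr), len(te)) == (8, 2)

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 37)
        y[:4] = [0, 0, 1, 1]
        tr, te = split_indices(37, 0.8, rng, y=y)
        assert sorted(np.concatenate([tr, te])) == list(range(37))
        assert len(set(tr) & set(te)) == 0

    def test_stratification_balances_classes(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 42 + [0] * 107)
        tr, te = split_indices(149, 0.8, rng, y=y)
        assert y[te].sum() in (8, 9)  # 42 * 0.2 = 8.4

    def test_tiny_class_rejected(self):
        rng = np.random.default_rng(3)
        y = np.array([1] + [0] * 9)
        with pytest.raises(ValueError):
            split_indices(10, 0.8, rng, y=y)


SMOKE_CFG = dict(
    n_repeats=4,
    models=["ga_kpls", "logit"],
    ga=GAConfig(population_size=6, n_generations=4, patience=3, cv_folds=3),
    synth=SynthConfig(n_samples=80, n_genes=60, n_de_genes=10, effect_size=1.5, seed=0),
)


class TestRepeatedEvaluation:
    def _run(self, seed=5):
        cfg = PipelineConfig(seed=seed, **SMOKE_CFG)
        X, pheno, _ = __import__("hfpef_risk.simulate", fromlist=["generate_cohort"]).generate_cohort(cfg.synth)
        y = pheno["outcome"].to_numpy()
        return repeated_evaluation(X.to_numpy().T, y, list(cfg.models), cfg)

    def test_reproducible_and_right_shape(self):
        t1 = self._run()
        t2 = self._run()
        pd.testing.assert_frame_equal(t1.per_repeat, t2.per_repeat)
        assert t1.per_repeat.shape == (4 * 2, 8)

    def test_mean_youden_identity_of_means(self):
        t = self._run()
        s = t.summary()
        np.testing.assert_allclose(s["youden"], s["se"] + s["sp"] - 1.0, atol=1e-12)

    def test_constant_score_model_has_half_auc(self):
        y = np.array([0, 1] * 10)
        assert auc_rank(y, np.full(20, 0.3)) == 0.5


class TestDunnett:
    def test_identical_columns_no_evidence(self):
        col = np.full(10, 0.8)
        m = pd.DataFrame({"ga_kpls": col, "svm": col, "rf": col})
        res = dunnett_compare(m, "ga_kpls", seed=0)
        assert res["anova_F"] == 0.0
        assert all(p == 1.0 for p in res["adjusted_p"].values())

    def test_two_groups_reduces_to_t_test(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.5, 1.0, 30)
        m = pd.DataFrame({"ctrl": a, "other": b})
        res = dunnett_compare(m, "ctrl", n_draws=400_000, seed=1)
        from scipy import stats

        t_p = stats.ttest_ind(b, a, equal_var=True).pvalue
        assert res["adjusted_p"]["other"] == pytest.approx(t_p, abs=0.005)

    def test_huge_shift_detected(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 0.01, 20)
        m = pd.DataFrame({
            "ctrl": base + 10.0, "m1": rng.normal(0, 0.01, 20),
            "m2": rng.normal(0, 0.01, 20),
        })
        res = dunnett_compare(m, "ctrl", seed=2)
        assert all(p < 1e-5 for p in res["adjusted_p"].values())

    def test_matches_scipy_dunnett_oracle(self):
        # independent implementation check on a 4-group balanced design
        from scipy import stats

        rng = np.random.default_rng(6)
        ctrl = rng.normal(0.0, 1.0, 25)
        groups = [rng.normal(mu, 1.0, 25) for mu in (0.2, 0.6, 1.0)]
        m = pd.DataFrame({"ctrl": ctrl, "a": groups[0], "b": groups[1], "c": groups[2]})
        mine = dunnett_compare(m, "ctrl", n_draws=400_000, seed=3)
        ref = stats.dunnett(*groups, control=ctrl)
        for name, p_ref in zip(["a", "b", "c"], ref.pvalue):
            assert mine["adjusted_p"][name] == pytest.approx(p_ref, abs=0.01)

    def test_adjusted_p_at_least_unadjusted(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        m = pd.DataFrame({n: rng.normal(0, 1, 15) for n in ["ctrl", "x", "y", "z"]})
        res = dunnett_compare(m, "ctrl", seed=4)
        for name in ["x", "y", "z"]:
            raw = stats.ttest_ind(m[name], m["ctrl"], equal_var=True).pvalue
            assert res["adjusted_p"][name] >= raw - 0.01

    def test_missing_control_rejected(self):
        m = pd.DataFrame({"a": np.zeros(5), "b": np.zeros(5)})
        with pytest.raises(ValueError, match="control"):
            dunnett_compare(m, "nope")
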