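import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lafat import (ancova, bonferroni, compare_metric, compare_table, describe,
                   is_normal, make_cohort, omnibus_test, posthoc_pairwise)
from lafat.cohort_stats import StatisticsError
from lafat.synthetic_phantom import null_cohort_spec


class TestDescribe:
    def test_median_and_iqr(self):
        s = describe(np.array([1.0, 2, 3, 4, 5]), normal=False)
        assert s["median"] == 3.0 and s["iqr"] == (2.0, 4.0)

    def test_constant_group_has_zero_sd(self):
        s = describe(np.full(10, 4.2), normal=True)
        assert s["sd"] == pytest.approx(0.0, abs=1e-12)
        assert s["mean"] == pytest.approx(4.2)

    def test_lognormal_sample_flagged_non_normal(self):
        rng = np.random.default_rng(1)
        assert not is_normal(rng.lognormal(0.0, 0.8, size=500))
        assert is_normal(rng.normal(0.0, 1.0, size=500))

    def test_empty_group_rejected(self):
        with pytest.raises(StatisticsError):
            describe(np.array([]))


class TestOmnibus:
    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([1.0, 2, 3, 4])
        f, p = omnibus_test([g, g.copy(), g.copy()], "anova")
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_kruskal_wallis_matches_rank_formula_oracle(self):
        # no ties: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 with group
        # mean ranks 2, 5, 8 of N=9 -> H = 12/90 * 3*(9+0+9) = 7.2
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        h, _ = omnibus_test(groups, "kruskal_wallis")
        assert h == pytest.approx(7.2)

    def test_extreme_contingency_table_is_significant(self):
        _, p = omnibus_test([[10, 0], [0, 10]], "chi_squared")
        assert p < 0.05

    def test_chi_squared_on_continuous_data_rejected(self):
        with pytest.raises(StatisticsError):
            omnibus_test([[0.5, 1.7], [2.2, 0.1]], "chi_squared")

    def test_kruskal_wallis_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(i, 1.0, 25) for i in range(3)]
        h1, _ = omnibus_test(groups, "kruskal_wallis")
        h2, _ = omnibus_test([np.exp(g) for g in groups], "kruskal_wallis")
        assert h1 == pytest.approx(h2)


class TestPosthoc:
    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 3) == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.integers(min_value=1, max_value=10))
    def test_bonferroni_caps_and_scales(self, p, k):
        adj = bonferroni(p, k)
        assert adj == min(1.0, p * k)
        assert 0.0 <= adj <= 1.0

    def test_three_pairs_with_family_consistency(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(i, 1, 30) for i, g in
                  enumerate(("control", "paroxysmal", "persistent"))}
        out = posthoc_pairwise(groups, "kruskal_wallis")
        assert len(out) == 3
        for r in out.values():
            assert r["p_adjusted"] == pytest.approx(min(1.0, 3 * r["p_raw"]))

    def test_persistent_vs_control_shift_detected_in_majority_of_seeds(self):
        # simulated dense-inFAT contrast at the study group sizes
        hits = 0
        n_rep = 60
        for s in range(n_rep):
            df = make_cohort(n_per_group=(30, 30, 20), seed=20_000 + s)
            groups = {g: df.loc[df.group == g, "dense_ml"].to_numpy()
                      for g in ("persistent", "control")}
            out = posthoc_pairwise(groups, "kruskal_wallis")
            hits += out[("control", "persistent")]["p_adjusted"] < 0.05
        assert hits > n_rep / 2

    def test_single_group_rejected(self):
        with pytest.raises(StatisticsError):
            posthoc_pairwise({"a": np.arange(5.0)}, "anova")


class TestAncova:
    def test_matches_normal_equations_oracle_on_six_rows(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 1.5, 3.0, 3.5, 4.0],
            "group": ["a", "a", "a", "b", "b", "b"],
            "bmi": [22.0, 25.0, 24.0, 23.0, 27.0, 26.0],
        })
        res = ancova(df, "y", covariates=("bmi",))
        # oracle: F = ((RSS_reduced - RSS_full)/q) / (RSS_full/(n-p)) via lstsq
        g = (df.group == "b").to_numpy(float)
        x_full = np.column_stack([np.ones(6), g, df.bmi])
        x_red = np.column_stack([np.ones(6), df.bmi])
        y = df.y.to_numpy()

        def rss(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return float(((y - x @ beta) ** 2).sum())

        f_oracle = (rss(x_red) - rss(x_full)) / (rss(x_full) / (6 - 3))
        assert res["F"] == pytest.approx(f_oracle, rel=1e-10)

    def test_constant_covariate_reduces_to_anova(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 60) + np.repeat([0.0, 0.4, 0.9], 20),
            "group": np.repeat(["a", "b", "c"], 20),
            "bmi": np.full(60, 25.0),
        })
        res = ancova(df, "y")
        groups = [df.y[df.group == g].to_numpy() for g in ("a", "b", "c")]
        f, p = omnibus_test(groups, "anova")
        assert res["F"] == pytest.approx(f, rel=1e-9)
        assert res["p"] == pytest.approx(p, rel=1e-9)

    def test_group_effect_mediated_by_bmi_vanishes_after_adjustment(self):
        rng = np.random.default_rng(4)
        bmi = np.concatenate([rng.normal(24, 1.2, 60), rng.normal(28, 1.2, 60)])
        df = pd.DataFrame({
            "y": 0.5 * bmi + rng.normal(0, 0.3, 120),
            "group": np.repeat(["a", "b"], 60),
            "bmi": bmi,
        })
        unadjusted = omnibus_test([df.y[:60].to_numpy(), df.y[60:].to_numpy()],
                                  "anova")[1]
        adjusted = ancova(df, "y")["p"]
        assert unadjusted < 1e-6
        assert adjusted > 10 * unadjusted

    def test_collinear_covariate_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "group": ["a", "a", "b", "b"],
                           "bmi": [20.0, 21, 22, 23], "bmi2": [40.0, 42, 44, 46]})
        with pytest.raises(StatisticsError):
            ancova(df, "y", covariates=("bmi", "bmi2"))


class TestCompareTable:
    def test_report_has_omnibus_pairwise_and_ancova_columns(self):
        df = make_cohort(seed=7)
        rep = compare_table(df, ["infat_ml", "dense_ml"])
        assert {"metric", "p", "ancova_p", "p_control_vs_persistent"} <= set(rep.columns)
        assert len(rep) == 2
        assert ((rep.p >= 0) & (rep.p <= 1)).all()

    def test_single_patient_group_surfaces_clean_error(self):
        df = make_cohort(seed=7)
        df = df[~((df.group == "control") & (df.index > df.index[df.group == "control"][0]))]
        with pytest.raises(StatisticsError, match="fewer than 2"):
            compare_metric(df, "infat_ml")

    def test_missing_group_rejected(self):
        df = make_cohort(seed=7)
        with pytest.raises(StatisticsError):
            compare_table(df[df.group != "control"], ["infat_ml"])

    def test_null_cohort_rarely_significant(self):
        spec = null_cohort_spec()
        flagged = 0
        for s in range(40):
            df = make_cohort(effect_spec=spec, seed=30_000 + s)
            _, p = omnibus_test([df.loc[df.group == g, "infat_ml"].to_numpy()
                                 for g in ("paroxysmal", "persistent", "control")],
                                "kruskal_wallis")
            flagged += p < 0.05
        assert flagged <= 6  # ~5% expected under the null
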