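"""Statistics: HWE, split-plot ANOVA vs independent oracles, post hocs."""

import numpy as np
import pandas as pd
import pytest

import faflab as fl
from _oracles import oracle_mixed_anova, random_split_plot_dataset


class TestHWE:
    def test_study_sample(self):
        chi2, p = fl.hwe_chisq(fl.GenotypeCounts(55, 71, 24))
        assert chi2 == pytest.approx(0.018, abs=0.001)
        assert p == pytest.approx(0.892, abs=0.002)

    def test_exact_equilibrium_proportions(self):
        chi2, _ = fl.hwe_chisq(fl.GenotypeCounts(25, 50, 25))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # p_hat = 0.5; expected (7.5, 15, 7.5) -> chi2 = 10/3
        chi2, _ = fl.hwe_chisq(fl.GenotypeCounts(10, 10, 10))
        assert chi2 == pytest.approx(3.3333, abs=0.001)

    @pytest.mark.parametrize("counts", [(49, 63, 21), (80, 15, 5), (1, 2, 1)])
    def test_nonnegative_and_zero_iff_expected(self, counts):
        chi2, _ = fl.hwe_chisq(fl.GenotypeCounts(*counts))
        assert chi2 >= 0.0
        n = sum(counts)
        p = (2 * counts[0] + counts[1]) / (2 * n)
        expected = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2)
        if np.allclose(counts, expected):
            assert chi2 == pytest.approx(0.0, abs=1e-12)
        else:
            assert chi2 > 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fl.GenotypeCounts(0, 0, 0)


class TestMixedAnova:
    def crafted_2x2(self):
        """Six subjects, two groups, two within levels, hand-enterable."""
        rows = []
        data = {("g1", "s1"): (10.0, 14.0), ("g1", "s2"): (12.0, 18.0),
                ("g1", "s3"): (11.0, 15.0), ("g2", "s4"): (9.0, 10.0),
                ("g2", "s5"): (11.0, 11.5), ("g2", "s6"): (10.0, 10.5)}
        for (g, s), (a, b) in data.items():
            rows += [dict(subject=s, group=g, w=0, value=a),
                     dict(subject=s, group=g, w=1, value=b)]
        return pd.DataFrame(rows)

    def test_crafted_dataset_matches_oracle(self):
        df = self.crafted_2x2()
        mine = fl.mixed_rm_anova(df, "value", "w", "group", "subject").set_index("effect")
        orac = oracle_mixed_anova(df, "value", "w", "group", "subject").set_index("effect")
        for eff in orac.index:
            assert mine.loc[eff, "F"] == pytest.approx(orac.loc[eff, "F"], abs=1e-8)
            assert mine.loc[eff, "df1"] == orac.loc[eff, "df1"]
            assert mine.loc[eff, "df2"] == orac.loc[eff, "df2"]
            assert mine.loc[eff, "p_unc"] == pytest.approx(orac.loc[eff, "p_unc"], abs=1e-10)

    def test_random_designs_match_oracle(self):
        rng = np.random.default_rng(0)
        for i in range(25):
            df = random_split_plot_dataset(rng, two_within=(i % 2 == 1))
            within = ["w1", "w2"] if i % 2 == 1 else "w1"
            mine = fl.mixed_rm_anova(df, "value", within, "group", "subject").set_index("effect")
            orac = oracle_mixed_anova(df, "value", within, "group", "subject").set_index("effect")
            for eff in orac.index:
                assert mine.loc[eff, "F"] == pytest.approx(orac.loc[eff, "F"], abs=1e-8)

    def test_identical_profiles_zero_within_f(self):
        df = self.crafted_2x2()
        df["value"] = df.groupby("subject")["value"].transform("mean")
        tab = fl.mixed_rm_anova(df, "value", "w", "group", "subject").set_index("effect")
        assert tab.loc["w", "F"] == pytest.approx(0.0, abs=1e-10)
        assert tab.loc["w * group", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_two_level_factor_epsilon_is_one(self):
        tab = fl.mixed_rm_anova(self.crafted_2x2(), "value", "w", "group", "subject")
        assert (tab["eps_gg"] == 1.0).all()

    def test_affine_invariance_of_f(self):
        rng = np.random.default_rng(5)
        df = random_split_plot_dataset(rng, two_within=True)
        t1 = fl.mixed_rm_anova(df, "value", ["w1", "w2"], "group", "subject")
        df2 = df.assign(value=3.7 * df["value"] - 11.0)
        t2 = fl.mixed_rm_anova(df2, "value", ["w1", "w2"], "group", "subject")
        assert np.allclose(t1["F"], t2["F"], atol=1e-8)
        assert np.allclose(t1["eps_gg"], t2["eps_gg"], atol=1e-10)

    def test_matches_pingouin_balanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        rows = []
        for gi, g in enumerate(["A", "B", "C"]):
            for s in range(6):
                for w in range(3):
                    rows.append(dict(subject=f"{g}{s}", group=g, w=w,
                                     value=rng.normal() + 0.5 * w + 0.3 * gi))
        df = pd.DataFrame(rows)
        mine = fl.mixed_rm_anova(df, "value", "w", "group", "subject").set_index("effect")
        aov = pg.mixed_anova(data=df, dv="value", within="w", subject="subject",
                             between="group").set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(aov.loc["group", "F"], abs=1e-8)
        assert mine.loc["w", "F"] == pytest.approx(aov.loc["w", "F"], abs=1e-8)
        assert mine.loc["w * group", "F"] == pytest.approx(
            aov.loc["Interaction", "F"], abs=1e-8)
        assert mine.loc["w", "partial_eta_sq"] == pytest.approx(
            aov.loc["w", "np2"], abs=1e-8)

    def test_epsilon_matches_pingouin_on_residualised_data(self):
        """GG epsilon agrees with pingouin once group means are removed."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = []
        for g in ["A", "B"]:
            for s in range(8):
                base = rng.normal(scale=2)
                for w in range(4):
                    rows.append(dict(subject=f"{g}{s}", group=g, w=w,
                                     value=base + rng.normal() * (1 + w)))
        df = pd.DataFrame(rows)
        mine = fl.mixed_rm_anova(df, "value", "w", "group", "subject").set_index("effect")
        wide = df.pivot(index="subject", columns="w", values="value")
        groups = df.groupby("subject")["group"].first()
        resid = wide - wide.groupby(groups).transform("mean")
        assert mine.loc["w", "eps_gg"] == pytest.approx(
            float(pg.epsilon(resid, correction="gg")), abs=1e-6)

    def test_missing_cell_lists_subject(self):
        df = self.crafted_2x2().iloc[:-1]
        with pytest.raises(ValueError, match="s6"):
            fl.mixed_rm_anova(df, "value", "w", "group", "subject")


class TestBonferroni:
    def test_adjustment_and_cap(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(size=10) for g in ("a", "b", "c")}
        out = fl.bonferroni_pairwise(groups)
        assert len(out) == 3
        assert np.allclose(out["p_adj"], np.minimum(1.0, 3 * out["p_unc"]))
        assert (out["p_adj"] <= 1.0).all()

    def test_known_multiplication(self):
        # construct a pair with p ~ 0.02 and check 3x scaling before the cap
        rng = np.random.default_rng(2)
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(1, 1, 20),
                  "c": rng.normal(0.5, 1, 20)}
        out = fl.bonferroni_pairwise(groups).set_index(["group_a", "group_b"])
        row = out.loc[("a", "b")]
        assert row["p_adj"] == pytest.approx(min(1.0, 3 * row["p_unc"]))

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fl.bonferroni_pairwise({"a": [1.0], "b": [1.0, 2.0]})


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = fl.pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed(self):
        res = fl.pearson_correlation([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_degenerate(self):
        res = fl.pearson_correlation([1, 1, 1], [1, 2, 3])
        assert res.degenerate and np.isnan(res.r)

    def test_null_p_uniform(self, rng):
        """Permutation null: the t-based p value is uniform (KS at 0.01)."""
        from scipy import stats as sps
        n, sims = 20, 2000
        x = rng.normal(size=n)
        ps = np.empty(sims)
        for i in range(sims):
            ps[i] = fl.pearson_correlation(x, rng.permutation(n)).p
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestContingency:
    def test_proportional_table_zero(self):
        chi2, df, _ = fl.contingency_chisq([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_hand_expanded_value(self):
        # [[10,10],[10,20]]: expected [[8,12],[12,18]] -> 25/18
        chi2, df, _ = fl.contingency_chisq([[10, 10], [10, 20]])
        assert chi2 == pytest.approx(25 / 18, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            fl.contingency_chisq([[0, 0], [5, 5]])


class TestStudyBattery:
    def test_battery_structure_and_df(self, small_cohort):
        vs = fl.vocal_summary(small_cohort)
        es, _ = fl.erp_summary(small_cohort)
        res = fl.replicate_study_analyses(vs, es, small_cohort.genotype_table())
        assert set(res) >= {"hwe", "vocal_magnitude_anova", "vocal_latency_anova",
                            "vocal_posthoc_largest_shift",
                            "compensation_vs_variability",
                            "n1_amplitude_anova", "p2_amplitude_anova"}
        tab = res["p2_amplitude_anova"].set_index("effect")
        n = 11  # subjects in the small cohort
        assert tab.loc["shift", "df2"] == n - 3
        assert tab.loc["electrode", "df1"] == 9
        assert tab.loc["electrode", "df2"] == 9 * (n - 3)
        assert tab.loc["shift * electrode * genotype", "df1"] == 18
        assert ((tab["partial_eta_sq"] >= 0) & (tab["partial_eta_sq"] <= 1)).all()
        assert ((tab["eps_gg"] > 0) & (tab["eps_gg"] <= 1)).all()

    def test_missing_vocal_input_named(self, small_cohort):
        with pytest.raises(ValueError, match="vocal"):
            fl.replicate_study_analyses(pd.DataFrame(), None,
                                        small_cohort.genotype_table())
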