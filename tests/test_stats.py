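import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from loyscan.calling import call_loy_zero_rule
from loyscan.celltypes import MarkerPanel, assign_cell_types, score_markers
from loyscan.stats import (
    AliasingError,
    build_design,
    fit_glm,
    loy_fraction_table,
    theil_sen_regression,
    treg_abundance_analysis,
    type3_tests,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(d, alternative):
    """Enumerate all 2^n sign assignments of the rank sum."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = total = 0
    for signs in itertools.product((1, -1), repeat=len(d)):
        w = ranks[np.array(signs) > 0].sum()
        ge += w >= w_obs
        le += w <= w_obs
        total += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge / total, le / total))


class TestWilcoxon:
    def test_all_positive_n5_one_sided(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], alternative="greater")
        assert res.p_value == pytest.approx(1 / 32)
        assert res.method["exact"]

    def test_degenerate_all_zero_differences(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0
        assert res.method["degenerate"]

    def test_too_few_nonzero_pairs(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            wilcoxon_signed_rank([1.0, 5.0], [1.0, 2.0])

    def test_worked_mixed_sign_example_matches_enumeration(self):
        d = [1, -2, 3, -4, 5, 6]
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d, "two-sided"))

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_equals_enumeration_random(self, alternative):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = rng.integers(2, 11)
            d = np.round(rng.normal(size=n) * 5, 2)
            d = d[d != 0]
            if len(np.unique(np.abs(d))) != len(d) or len(d) < 2:
                continue
            res = wilcoxon_signed_rank(d, alternative=alternative)
            assert res.p_value == pytest.approx(
                brute_force_wilcoxon_p(d, alternative), abs=1e-12
            )

    def test_approximate_path_close_to_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1.0, size=60)
        res = wilcoxon_signed_rank(x)
        ref = sps.wilcoxon(x, correction=True, mode="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)
        assert not res.method["exact"]


class TestTheilSen:
    def test_collinear_points(self):
        fit = theil_sen_regression([1, 2, 3], [1, 2, 3])
        assert fit.slope == 1.0 and fit.intercept == 0.0

    def test_three_point_median_example(self):
        # pairwise slopes {1, 0, -1} -> slope 0, intercept 0
        fit = theil_sen_regression([0, 1, 2], [0, 1, 0])
        assert fit.slope == 0.0 and fit.intercept == 0.0

    def test_equal_x_pairs_excluded(self):
        # pairs with identical x contribute no slope
        fit = theil_sen_regression([0, 0, 1, 2], [5, -5, 1, 2])
        finite_slopes = [
            (y2 - y1) / (x2 - x1)
            for (x1, y1), (x2, y2) in itertools.combinations(
                zip([0, 0, 1, 2], [5, -5, 1, 2]), 2
            )
            if x2 != x1
        ]
        assert fit.slope == pytest.approx(np.median(finite_slopes))

    def test_all_x_equal_is_error(self):
        with pytest.raises(ValueError, match="identical"):
            theil_sen_regression([1, 1, 1], [1, 2, 3])

    def test_matches_brute_force_median_random(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = 1.5 * x + rng.normal(size=n)
            fit = theil_sen_regression(x, y)
            slopes = [
                (y[j] - y[i]) / (x[j] - x[i])
                for i in range(n)
                for j in range(i + 1, n)
                if x[j] != x[i]
            ]
            assert fit.slope == pytest.approx(np.median(slopes))
            assert fit.intercept == pytest.approx(np.median(y - fit.slope * x))

    def test_matches_scipy_theilslopes(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        y = -2.0 * x + rng.normal(size=80)
        fit = theil_sen_regression(x, y)
        ref = sps.theilslopes(y, x)
        assert fit.slope == pytest.approx(ref.slope)

    def test_siegel_variant_matches_scipy_siegelslopes(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        fit = theil_sen_regression(x, y, method="siegel")
        ref = sps.siegelslopes(y, x)
        assert fit.slope == pytest.approx(ref.slope)


class TestDesignAndGLM:
    def test_sum_contrast_columns_sum_to_zero_over_levels(self):
        data = pd.DataFrame({"g": ["a", "b", "c", "a", "b", "c"]})
        X, names, slices = build_design(data, ["g"])
        block = X[:, slices["g"]]
        # each level's row pattern summed over all levels is zero
        patterns = {lvl: block[np.asarray(data["g"]) == lvl][0] for lvl in "abc"}
        assert sum(patterns.values()).tolist() == pytest.approx([0.0, 0.0])

    def test_aliased_design_raises(self):
        data = pd.DataFrame({"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"]})
        with pytest.raises(AliasingError):
            build_design(data, ["a", "b"])

    def test_saturated_binomial_reproduces_observed_proportions(self):
        data = pd.DataFrame({"g": ["a", "b"]})
        fit = fit_glm("binomial", np.array([2, 5]), data, ["g"],
                      trials=np.array([10, 10]))
        assert fit.mu == pytest.approx([0.2, 0.5])
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    def test_nb_with_huge_theta_matches_poisson_irls(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=400)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        data = pd.DataFrame({"x": x})
        nb = fit_glm("negative_binomial", y, data, ["x"], theta=1e6)
        import statsmodels.api as sm

        pois = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        assert np.asarray(nb.coef) == pytest.approx(np.asarray(pois.params), abs=1e-4)

    def test_nb_theta_estimate_matches_statsmodels_ml(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=600)
        mu = np.exp(1.2 + 0.4 * x)
        theta_true = 3.0
        y = rng.negative_binomial(theta_true, theta_true / (theta_true + mu))
        fit = fit_glm("negative_binomial", y, pd.DataFrame({"x": x}), ["x"])
        import statsmodels.api as sm
        from statsmodels.discrete.discrete_model import NegativeBinomial

        ref = NegativeBinomial(y, sm.add_constant(x)).fit(disp=0)
        assert fit.theta == pytest.approx(1.0 / ref.params[-1], rel=1e-3)
        assert np.asarray(fit.coef) == pytest.approx(ref.params[:2], abs=1e-3)

    def test_separation_flags_warning(self):
        data = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
        y = np.array([0] * 10 + [10] * 10)
        fit = fit_glm("binomial", y, data, ["g"], trials=np.full(20, 10))
        assert any("separation" in w for w in fit.warnings_)

    def test_binomial_coefficients_match_statsmodels(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame({"g": rng.choice(["a", "b", "c"], size=90),
                             "x": rng.normal(size=90)})
        p = 1 / (1 + np.exp(-(0.2 + 0.5 * data["x"])))
        y = rng.binomial(15, p)
        fit = fit_glm("binomial", y, data, ["g", "x"], trials=np.full(90, 15))
        import statsmodels.api as sm

        X, _, _ = build_design(data, ["g", "x"])
        ref = sm.GLM(np.c_[y, 15 - y], X, family=sm.families.Binomial()).fit()
        assert np.asarray(fit.coef) == pytest.approx(np.asarray(ref.params), abs=1e-6)
        assert np.asarray(fit.se) == pytest.approx(np.asarray(ref.bse), rel=1e-4)


class TestType3:
    def test_single_factor_equals_ordinary_lr(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame({"g": ["a"] * 15 + ["b"] * 15})
        y = rng.binomial(20, np.r_[[0.3] * 15, [0.5] * 15])
        t3 = type3_tests("binomial", y, data, ["g"], trials=np.full(30, 20))
        full = fit_glm("binomial", y, data, ["g"], trials=np.full(30, 20))
        import statsmodels.api as sm

        null = sm.GLM(np.c_[y, 20 - y], np.ones((30, 1)),
                      family=sm.families.Binomial()).fit()
        assert t3.loc[0, "LR"] == pytest.approx(null.deviance - full.deviance, rel=1e-6)
        assert t3.loc[0, "Df"] == 1

    def test_quasibinomial_lr_is_binomial_lr_over_dispersion(self):
        rng = np.random.default_rng(10)
        data = pd.DataFrame({"g": rng.choice(["a", "b"], size=40)})
        # overdispersed: mixture of success probabilities
        p = np.where(data["g"] == "a", 0.3, 0.45) + rng.normal(0, 0.1, 40)
        y = rng.binomial(30, np.clip(p, 0.01, 0.99))
        trials = np.full(40, 30)
        t3q = type3_tests("quasibinomial", y, data, ["g"], trials=trials)
        t3b = type3_tests("binomial", y, data, ["g"], trials=trials)
        phi = fit_glm("quasibinomial", y, data, ["g"], trials=trials).dispersion
        assert phi > 1.0
        assert t3q.loc[0, "LR"] == pytest.approx(t3b.loc[0, "LR"] / phi)

    def test_invariant_to_level_order_and_term_order(self):
        rng = np.random.default_rng(11)
        g1 = rng.choice(["a", "b", "c"], size=120)
        g2 = rng.choice(["u", "v"], size=120)
        y = rng.binomial(25, 0.3 + 0.1 * (g1 == "a") + 0.05 * (g2 == "u"))
        trials = np.full(120, 25)
        data = pd.DataFrame({"f1": g1, "f2": g2})
        relabel = {"a": "z_a", "b": "m_b", "c": "a_c"}
        data2 = pd.DataFrame({"f1": [relabel[v] for v in g1], "f2": g2})
        t_ref = type3_tests("binomial", y, data, ["f1", "f2", "f1:f2"], trials=trials)
        t_lvl = type3_tests("binomial", y, data2, ["f1", "f2", "f1:f2"], trials=trials)
        t_ord = type3_tests("binomial", y, data, ["f2", "f1", "f1:f2"], trials=trials)
        ref = t_ref.set_index("term")["LR"]
        assert t_lvl.set_index("term")["LR"].to_dict() == pytest.approx(ref.to_dict())
        assert t_ord.set_index("term")["LR"].to_dict() == pytest.approx(ref.to_dict())

    def test_interaction_term_kept_when_main_effect_dropped(self):
        rng = np.random.default_rng(12)
        g1 = rng.choice(["a", "b"], size=80)
        g2 = rng.choice(["u", "v"], size=80)
        y = rng.binomial(20, 0.4)
        data = pd.DataFrame({"f1": g1, "f2": g2})
        t3 = type3_tests("binomial", y, data, ["f1", "f2", "f1:f2"],
                         trials=np.full(80, 20))
        assert set(t3["term"]) == {"f1", "f2", "f1:f2"}
        assert (t3["Df"] == 1).all()


class TestFractionTable:
    def _calls_and_meta(self, default_sim):
        (bundle, meta, ann, truth), _ = default_sim
        calls = call_loy_zero_rule(bundle, ann, meta)
        panel = MarkerPanel.default()
        typing = assign_cell_types(score_markers(bundle, meta, panel), panel)
        return calls, meta, typing, truth

    def test_percentages_and_conservation(self, default_sim):
        calls, meta, typing, _ = self._calls_and_meta(default_sim)
        frac = loy_fraction_table(calls, meta, typing)
        assert ((frac["n_loy"] >= 0) & (frac["n_loy"] <= frac["n_cells"])).all()
        expect = 100.0 * frac["n_loy"] / frac["n_cells"]
        assert frac["pct_loy"].to_numpy() == pytest.approx(expect.to_numpy())
        # conservation: per-sample sums match total LOY calls in that sample
        merged = calls.table.merge(meta.table.reset_index(drop=True), on="barcode")
        male_loy = merged[merged["status"] == "LOY"].groupby("sample_id").size()
        table_loy = frac.groupby("sample_id")["n_loy"].sum()
        for sample, count in male_loy.items():
            assert table_loy.loc[sample] == count

    def test_only_male_assessed_cells_in_denominators(self, default_sim):
        calls, meta, typing, _ = self._calls_and_meta(default_sim)
        frac = loy_fraction_table(calls, meta, typing)
        n_male = (meta.table["sex"] == "male").sum()
        assert frac["n_cells"].sum() == n_male

    def test_simple_count_example(self):
        from loyscan.calling import LOYCallTable
        from .conftest import make_metadata

        calls = LOYCallTable(
            table=pd.DataFrame(
                {
                    "barcode": [f"c{i}" for i in range(10)],
                    "status": ["LOY"] * 2 + ["normal"] * 8,
                    "rule": "zero_rule",
                    "total_msy": 0,
                    "n_msy_genes_expressed": 0,
                }
            ),
            rule="zero_rule",
        )
        meta = make_metadata([(f"c{i}", "s1", "male", "C0") for i in range(10)])
        typing = pd.DataFrame({"cluster": ["C0"], "cell_type": ["Treg CTLA4+"]})
        frac = loy_fraction_table(calls, meta, typing)
        assert len(frac) == 1
        assert frac.loc[0, "pct_loy"] == pytest.approx(20.0)


class TestTregAbundance:
    def test_positive_coupling_recovered(self, default_sim):
        calls, meta, typing, _ = TestFractionTable()._calls_and_meta(default_sim)
        frac = loy_fraction_table(calls, meta, typing)
        res = treg_abundance_analysis(frac)
        assert res["regression"].slope > 0
        assert res["wilcoxon"].p_value < 0.01
        glm = res["glm_type3"].set_index("term")
        assert glm.loc["treg_loy_pct", "p_value"] < 0.05

    def test_null_cohort_shows_no_directional_bias(self):
        """With equal LOY fractions in all cell types and no Treg-share
        coupling, the paired Wilcoxon holds its 5% level and the Theil-Sen
        slope has no preferred sign across replicates.  (The signed-rank
        p-value on pairwise slopes is anticonservative under the null —
        pairwise slopes are dependent — so the slope is checked by a sign
        test across replicates rather than by its own p-value.)"""
        from loyscan.simulate import SimParams, simulate_dataset

        null_loy = {t: 0.05 for t in SimParams().loy_fraction_by_type}
        panel = MarkerPanel.default()
        wilcoxon_rejections = 0
        positive_slopes = 0
        n_rep = 60
        for rep in range(n_rep):
            params = SimParams(
                n_samples_male=10, n_samples_female=0, cells_per_sample=300,
                loy_fraction_by_type=null_loy, treg_coupling=0.0,
                loy_between_sample_sd=0.0, seed=5000 + rep,
            )
            bundle, meta, ann, _ = simulate_dataset(params)
            calls = call_loy_zero_rule(bundle, ann, meta)
            typing = assign_cell_types(score_markers(bundle, meta, panel), panel)
            res = treg_abundance_analysis(loy_fraction_table(calls, meta, typing))
            wilcoxon_rejections += res["wilcoxon"].p_value < 0.05
            positive_slopes += res["regression"].slope > 0
        assert wilcoxon_rejections <= 0.10 * n_rep
        sign_p = sps.binomtest(positive_slopes, n_rep, 0.5).pvalue
        assert sign_p > 0.05

    def test_single_sample_is_error(self):
        frac = pd.DataFrame(
            {
                "sample_id": ["s1"] * 2,
                "cell_type": ["Treg CTLA4+", "Helper T"],
                "n_cells": [10, 50],
                "n_loy": [2, 1],
                "pct_loy": [20.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="need >= 3"):
            treg_abundance_analysis(frac)
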