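import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thawpheno as tp
from thawpheno.inference import _adjusted_p

from helpers import make_design, statsmodels_type2


class TestApplyTransform:
    def test_sqrt(self):
        out = tp.apply_transform(pd.Series([4.0, 9.0]), "sqrt")
        assert list(out) == [2.0, 3.0]

    def test_none_is_identity(self):
        s = pd.Series([1.0, -5.0])
        assert tp.apply_transform(s, "none") is s

    def test_ln_closed_form(self):
        out = tp.apply_transform(pd.Series([8.0]), "ln")
        assert out.iloc[0] == pytest.approx(np.log(8.0))

    def test_domain_violation_names_plot(self):
        s = pd.Series([4.0, -1.0], index=["P1", "P2"])
        with pytest.raises(ValueError, match="P2"):
            tp.apply_transform(s, "sqrt")


class TestTypeIISums:
    def test_balanced_toy_matches_nested_rss_oracle(self):
        plots, resp, _ = make_design([2, 2, 2, 2], [1, 2, 3, 4, 5, 6, 7, 9])
        table = tp.FactorialANOVA(resp, plots).fit().anova_table.set_index("term")
        oracle, _ = statsmodels_type2(plots, resp)
        for term, key in [
            ("ground_state", "C(ground_state)"),
            ("polygon_feature", "C(polygon_feature)"),
            ("interaction", "C(ground_state):C(polygon_feature)"),
        ]:
            assert table.loc[term, "ss"] == pytest.approx(oracle.loc[key, "sum_sq"], rel=1e-10)
            assert table.loc[term, "F"] == pytest.approx(oracle.loc[key, "F"], rel=1e-10)

    def test_unbalanced_matches_statsmodels_type2(self):
        rng = np.random.default_rng(7)
        plots, resp, _ = make_design([5, 3, 7, 4], rng.normal(180, 3, 19))
        table = tp.FactorialANOVA(resp, plots).fit().anova_table.set_index("term")
        oracle, _ = statsmodels_type2(plots, resp)
        assert table.loc["ground_state", "ss"] == pytest.approx(
            oracle.loc["C(ground_state)", "sum_sq"], rel=1e-8
        )
        assert table.loc["interaction", "p"] == pytest.approx(
            oracle.loc["C(ground_state):C(polygon_feature)", "PR(>F)"], rel=1e-8
        )

    def test_additive_construction_has_zero_interaction_ss(self):
        # pure additive shifts: state +2, feature +3, replicated twice
        y = [10, 10, 13, 13, 12, 12, 15, 15]
        plots, resp, _ = make_design([2, 2, 2, 2], y)
        table = tp.FactorialANOVA(resp, plots).fit().anova_table.set_index("term")
        assert table.loc["interaction", "ss"] == pytest.approx(0.0, abs=1e-18)

    def test_constant_response_rejected(self):
        plots, resp, _ = make_design([2, 2, 2, 2], [5.0] * 8)
        with pytest.raises(ValueError, match="constant"):
            tp.FactorialANOVA(resp, plots)

    def test_empty_cell_rejected_as_rank_deficiency(self):
        plots, resp, _ = make_design([3, 3, 3, 3], np.arange(12.0))
        drop = plots.loc[
            (plots["ground_state"] == "thermokarst") & (plots["polygon_feature"] == "trough"),
            "plot_id",
        ]
        resp = resp.drop(drop)
        with pytest.raises(ValueError, match="cell"):
            tp.FactorialANOVA(resp, plots)


class TestEmmeans:
    def test_cell_emms_equal_raw_cell_means_on_balanced_data(self):
        rng = np.random.default_rng(11)
        y = rng.normal(185, 2, 20)
        plots, resp, _ = make_design([5, 5, 5, 5], y)
        emm = tp.FactorialANOVA(resp, plots).fit().emmeans()
        raw = (
            plots.set_index("plot_id")
            .assign(y=resp)
            .groupby(["ground_state", "polygon_feature"])["y"]
            .mean()
        )
        for _, row in emm.cells.iterrows():
            assert row["emmean"] == pytest.approx(
                raw.loc[(row["ground_state"], row["polygon_feature"])], rel=1e-10
            )

    def test_identical_cell_means_give_zero_contrasts_and_p_near_one(self):
        y = [5, 7, 5, 7, 5, 7, 5, 7]  # same mean in every cell
        plots, resp, _ = make_design([2, 2, 2, 2], y)
        emm = tp.FactorialANOVA(resp, plots).fit().emmeans()
        assert np.allclose(emm.contrasts["estimate"], 0.0)
        assert (emm.contrasts["p_adj"] > 0.999).all()

    def test_contrast_ses_match_emmeans_style_formula(self):
        # Tukey-Kramer SE for a two-cell contrast: sqrt(MSE * (1/n_i + 1/n_j))
        rng = np.random.default_rng(3)
        n = [6, 4, 5, 7]
        plots, resp, _ = make_design(n, rng.normal(0, 1, sum(n)))
        res = tp.FactorialANOVA(resp, plots).fit()
        emm = res.emmeans()
        mse = res.sigma2
        ses = {
            ("control top", "control trough"): np.sqrt(mse * (1 / 6 + 1 / 4)),
            ("thermokarst top", "thermokarst trough"): np.sqrt(mse * (1 / 5 + 1 / 7)),
        }
        lookup = emm.contrasts.set_index("contrast")["se"]
        for (a, b), se in ses.items():
            assert lookup[f"{a} - {b}"] == pytest.approx(se, rel=1e-10)

    def test_main_effect_emms_average_cells_equally(self):
        rng = np.random.default_rng(5)
        n = [6, 4, 5, 7]
        plots, resp, _ = make_design(n, rng.normal(0, 1, sum(n)))
        emm = tp.FactorialANOVA(resp, plots).fit().emmeans()
        cells = emm.cells.set_index(["ground_state", "polygon_feature"])["emmean"]
        control = emm.main_effects.query("factor=='ground_state' and level=='control'")[
            "emmean"
        ].iloc[0]
        assert control == pytest.approx(
            (cells[("control", "top")] + cells[("control", "trough")]) / 2, rel=1e-12
        )


class TestTukeyAdjustment:
    def test_monotone_nonincreasing_in_t(self):
        ps = [_adjusted_p(t, 4, 60, "tukey") for t in np.linspace(0.1, 5, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_adjusted_at_least_unadjusted_for_four_groups(self):
        for t in (0.5, 1.5, 2.5, 3.5):
            unadj = 2 * stats.t.sf(t, 60)
            assert _adjusted_p(t, 4, 60, "tukey") >= unadj - 1e-12

    def test_none_adjustment_is_plain_t_test(self):
        assert _adjusted_p(2.0, 4, 60, "none") == pytest.approx(2 * stats.t.sf(2.0, 60))


class TestAncova:
    def test_orthogonal_covariate_leaves_factor_ss_unchanged(self):
        rng = np.random.default_rng(13)
        y = rng.normal(0, 1, 16)
        cov = np.tile([1.0, 2.0, 3.0, 4.0], 4)  # identical pattern per cell
        plots, resp, c = make_design([4, 4, 4, 4], y, cov)
        plain = tp.FactorialANOVA(resp, plots).fit().anova_table.set_index("term")
        adj = tp.FactorialANOVA(resp, plots, covariate=c).fit().anova_table.set_index("term")
        for term in ("ground_state", "polygon_feature", "interaction"):
            assert adj.loc[term, "ss"] == pytest.approx(plain.loc[term, "ss"], rel=1e-9)

    def test_response_linear_in_covariate_leaves_no_factor_ss(self):
        rng = np.random.default_rng(17)
        cov = rng.uniform(5, 30, 16)
        y = 2.0 * cov + 1.0
        plots, resp, c = make_design([4, 4, 4, 4], y, cov)
        table = tp.FactorialANOVA(resp, plots, covariate=c).fit().anova_table.set_index("term")
        for term in ("ground_state", "polygon_feature", "interaction"):
            assert table.loc[term, "ss"] == pytest.approx(0.0, abs=1e-16)

    def test_matches_statsmodels_type2_with_covariate(self):
        rng = np.random.default_rng(19)
        n = [5, 6, 4, 7]
        cov = rng.uniform(5, 30, sum(n))
        y = rng.normal(185, 2, sum(n)) + 0.1 * cov
        plots, resp, c = make_design(n, y, cov)
        table = tp.FactorialANOVA(resp, plots, covariate=c).fit().anova_table.set_index("term")
        oracle, _ = statsmodels_type2(plots, resp, c)
        assert table.loc["cumulative_tdd", "ss"] == pytest.approx(
            oracle.loc["c", "sum_sq"], rel=1e-8
        )
        assert table.loc["interaction", "F"] == pytest.approx(
            oracle.loc["C(ground_state):C(polygon_feature)", "F"], rel=1e-8
        )

    def test_covariate_cancels_in_cell_contrasts(self):
        rng = np.random.default_rng(23)
        n = [5, 6, 4, 7]
        cov = rng.uniform(5, 30, sum(n))
        y = rng.normal(185, 2, sum(n)) + 0.1 * cov
        plots, resp, c = make_design(n, y, cov)
        res = tp.FactorialANOVA(resp, plots, covariate=c, ln_covariate=True).fit()
        emm = res.emmeans()
        assert emm.covariate_value == pytest.approx(np.mean(np.log(cov)))
        # contrast of two cells is free of the covariate coefficient
        beta_cov = res.params[-1]
        assert np.isfinite(beta_cov)
        assert len(emm.contrasts) == 6


class TestRegression:
    def test_exact_collinearity_gives_r2_one(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = 2 * x + 1
        res = tp.regress_on_tdd(y, x, ln_transform=False)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_five_point_toy_matches_normal_equations(self):
        x = np.array([5.0, 8.0, 11.0, 17.0, 23.0])
        y = np.array([181.0, 183.0, 182.0, 187.0, 189.0])
        sx = x - x.mean()
        slope = (sx * (y - y.mean())).sum() / (sx**2).sum()
        res = tp.regress_on_tdd(
            pd.Series(y, index=list("abcde")), pd.Series(x, index=list("abcde")), ln_transform=False
        )
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.df == 3

    def test_ln_transform_applied_to_predictor(self):
        x = pd.Series([2.0, 4.0, 8.0, 16.0], index=list("abcd"))
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        res = tp.regress_on_tdd(y, x, ln_transform=True)
        assert res.r_squared == pytest.approx(1.0)  # y is linear in ln x

    def test_zero_variance_covariate_rejected(self):
        x = pd.Series([3.0, 3.0, 3.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            tp.regress_on_tdd(y, x, ln_transform=False)


class TestRandomEffectComparison:
    @staticmethod
    def _bundle_response(transect_sd, seed):
        cfg = tp.scenario("paper_like")
        cfg.transect_sd = transect_sd
        b, _ = tp.generate_landscape(cfg, seed)
        b = tp.filter_flooded(b)
        cwm = tp.cwm_table(b, ("first_open_flower",))
        resp = tp.cwm_wide(cwm)["first_open_flower"].dropna()
        return resp, b.plots

    def test_zero_transect_variance_favors_plain_model(self):
        wins = 0
        for seed in range(12):
            resp, plots = self._bundle_response(0.0, seed)
            cmp_ = tp.compare_random_effect(resp, plots)
            wins += cmp_.supported == "linear"
        assert wins >= 10

    def test_boundary_zero_variance_gives_delta_aic_two(self):
        resp, plots = self._bundle_response(0.0, 1)
        cmp_ = tp.compare_random_effect(resp, plots)
        if cmp_.singular:
            assert cmp_.aic_mixed - cmp_.aic_linear == pytest.approx(2.0, abs=1e-3)

    def test_large_transect_variance_favors_mixed_model(self):
        wins = 0
        for seed in range(6):
            resp, plots = self._bundle_response(4.0, seed)
            cmp_ = tp.compare_random_effect(resp, plots)
            wins += cmp_.supported == "mixed"
        assert wins >= 5

    def test_single_transect_rejected(self):
        resp, plots = self._bundle_response(0.0, 1)
        plots = plots.assign(transect_id="T1")
        with pytest.raises(ValueError, match="transect"):
            tp.compare_random_effect(resp, plots)
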