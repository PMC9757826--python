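import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decoychoice.analysis import (
    DesignMatrix,
    binned_map,
    build_design_matrix,
    decoy_effect_table,
    fit_weighted_logit,
    group_level_tests,
    permutation_bias_correction,
)
from decoychoice.fitting import model_spec
from decoychoice.synth import AgentSpec, simulate_agent


@pytest.fixture(scope="module")
def behav(design):
    spec = model_spec("au_static")
    return simulate_agent(design, AgentSpec(spec, dict(lam=0.45, beta=7.0)), seed=41)


class TestDesignMatrix:
    def test_zscored_columns_standardised(self, behav):
        d = build_design_matrix(behav.df, basis="ev")
        for col in ("vdiff", "dvar"):
            v = d.X[col].to_numpy()
            assert abs(v.mean()) < 1e-10
            assert np.std(v, ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_interaction_is_product_of_zscored_components(self, behav):
        d = build_design_matrix(behav.df, basis="ev")
        prod = d.X["vdiff"].to_numpy() * d.X["dvar"].to_numpy()
        assert np.allclose(d.X["vdiff_x_dvar"], prod)
        # ... and not the z-score of the raw product
        assert abs(np.std(prod, ddof=1) - 1.0) > 1e-6

    def test_combined_design_has_condition_crosses(self, behav):
        d = build_design_matrix(behav.df, basis="ev", include_sum=True)
        for col in ("C", "vdiff_x_C", "dvar_x_C", "vdiff_x_dvar_x_C", "vsum_x_C"):
            assert col in d.X.columns

    def test_au_basis_requires_lambda(self, behav):
        with pytest.raises(ValueError, match="lam"):
            build_design_matrix(behav.df, basis="au")

    def test_degenerate_distractor_column_dropped_with_warning(self):
        X = pd.DataFrame({"const": 1.0, "vdiff": [-1.0, 0.0, 1.0], "dvar": 0.0})
        d = DesignMatrix(X, np.array([0.2, 0.5, 0.8]), np.ones(3) * 5)
        with pytest.warns(UserWarning, match="rank"):
            res = fit_weighted_logit(d)
        assert "dvar" in res.dropped
        assert "dvar" not in res.params.index


class TestWeightedLogit:
    def test_intercept_only_at_half_is_zero(self):
        X = pd.DataFrame({"const": np.ones(4)})
        d = DesignMatrix(X, np.full(4, 0.5), np.full(4, 10.0))
        res = fit_weighted_logit(d)
        assert res.params["const"] == pytest.approx(0.0, abs=1e-8)

    def test_two_cell_closed_form(self):
        p1 = np.e / (np.e + 1)  # logit = 1 exactly
        X = pd.DataFrame({"const": [1.0, 1.0], "x": [1.0, 0.0]})
        d = DesignMatrix(X, np.array([p1, 0.5]), np.array([50.0, 50.0]))
        res = fit_weighted_logit(d)
        assert res.params["x"] == pytest.approx(1.0, abs=1e-6)
        assert res.params["const"] == pytest.approx(0.0, abs=1e-6)

    def test_weight_doubling_keeps_coefs_halves_variance(self, behav):
        d = build_design_matrix(behav.df, basis="ev")
        res1 = fit_weighted_logit(d)
        d2 = DesignMatrix(d.X, d.y, 2 * d.weights)
        res2 = fit_weighted_logit(d2)
        assert np.allclose(res1.params, res2.params, atol=1e-8)
        assert np.allclose(res2.bse * np.sqrt(2), res1.bse, rtol=1e-6)

    def test_coefficients_invariant_to_affine_regressor_rescaling(self, behav):
        # scaling every magnitude attribute scales all EV regressors linearly;
        # z-scoring absorbs the rescaling, so the fit is unchanged
        d = build_design_matrix(behav.df, basis="ev", include_sum=True)
        scaled = behav.df.copy()
        for c in ("hx", "lx", "dx"):
            scaled[c] = scaled[c] * 0.5
        d2 = build_design_matrix(scaled, basis="ev", include_sum=True)
        r1 = fit_weighted_logit(d)
        r2 = fit_weighted_logit(d2)
        assert np.allclose(r1.params.to_numpy(), r2.params.to_numpy(), atol=1e-8)

    def test_recovers_known_logistic_coefficients(self):
        """Simulated weighted-binomial data: each true coefficient lies inside
        its 95% CI in at least 90 of 100 replicates."""
        rng = np.random.default_rng(77)
        beta = np.array([0.0, 0.8, 0.4, -0.3])
        hits = np.zeros(4)
        for _ in range(100):
            X = np.column_stack(
                [np.ones(150), rng.normal(size=150), rng.normal(size=150),
                 rng.normal(size=150)]
            )
            p = 1 / (1 + np.exp(-X @ beta))
            w = np.full(150, 4.0)
            y = rng.binomial(4, p) / 4.0
            d = DesignMatrix(pd.DataFrame(X, columns=["const", "a", "b", "c"]), y, w)
            res = fit_weighted_logit(d)
            hits += np.abs(res.params.to_numpy() - beta) <= 1.96 * res.bse.to_numpy()
        assert np.all(hits[1:] >= 90), hits


class TestGroupTests:
    def test_zero_coefficients_give_t_zero_p_one(self):
        coefs = pd.DataFrame({"a": np.zeros(10)})
        out = group_level_tests(coefs)
        assert out.loc["a", "t"] == 0.0
        assert out.loc["a", "p"] == 1.0

    def test_holm_stepdown_hand_example(self):
        # raw p = (0.01, 0.04) over 2 tests -> (0.02, 0.04)
        rng = np.random.default_rng(0)
        # construct two coefficient vectors with exact target p-values via t
        n = 20

        def vec(p):
            t = stats.t.ppf(1 - p / 2, n - 1)
            v = rng.standard_normal(n)
            v = (v - v.mean()) / v.std(ddof=1)
            return v + t / np.sqrt(n)

        coefs = pd.DataFrame({"a": vec(0.01), "b": vec(0.04)})
        out = group_level_tests(coefs)
        assert out.loc["a", "p"] == pytest.approx(0.01, abs=1e-9)
        assert out.loc["a", "p_holm"] == pytest.approx(0.02, abs=1e-9)
        assert out.loc["b", "p_holm"] == pytest.approx(0.04, abs=1e-9)

    def test_t_statistic_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0.2, 1.0, size=30)
        out = group_level_tests(pd.DataFrame({"a": v}))
        expected = v.mean() / (v.std(ddof=1) / np.sqrt(30))
        assert out.loc["a", "t"] == pytest.approx(expected, abs=1e-12)


class TestPermutationBias:
    def test_exchangeable_null_gives_zero(self):
        t = pd.Series([0.7, 0.7, 0.7, 0.7])
        b = pd.Series([0.7, 0.7, 0.7, 0.7])
        bias, corrected = permutation_bias_correction(t, b, nperm=50, seed=0)
        assert bias == 0.0
        assert np.allclose(corrected, 0.0)

    def test_same_seed_same_bias(self):
        rng = np.random.default_rng(9)
        t = pd.Series(rng.random(20))
        b = pd.Series(rng.random(20))
        w = pd.Series(rng.integers(1, 4, size=20).astype(float))
        b1, _ = permutation_bias_correction(t, b, nperm=200, seed=5, weights=w)
        b2, _ = permutation_bias_correction(t, b, nperm=200, seed=5, weights=w)
        assert b1 == b2

    def test_bias_approximates_mean_contrast(self):
        rng = np.random.default_rng(10)
        t = pd.Series(rng.random(30))
        b = pd.Series(rng.random(30))
        bias, corrected = permutation_bias_correction(t, b, nperm=2000, seed=1)
        assert bias == pytest.approx(float(t.mean() - b.mean()), abs=1e-12)
        # correction shifts every condition by the same constant
        assert np.allclose(corrected - (t - b), -bias)


class TestBinnedMap:
    def test_default_settings_give_71_by_71(self):
        rng = np.random.default_rng(2)
        bm = binned_map(rng.normal(size=200), rng.normal(size=200), rng.random(200))
        assert bm.values.shape == (71, 71)
        assert len(bm.x1_centers) == 71

    def test_constant_outcome_constant_map(self):
        rng = np.random.default_rng(3)
        bm = binned_map(rng.normal(size=100), rng.normal(size=100), np.full(100, 0.4))
        assert np.allclose(bm.values[np.isfinite(bm.values)], 0.4)

    def test_monotone_outcome_monotone_rows(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=400)
        x2 = rng.normal(size=400)
        bm = binned_map(x1, x2, x1, window_quantile=0.3, step_quantile=0.01)
        means = np.nanmean(bm.values, axis=1)
        assert np.all(np.diff(means) > -1e-9)

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(ValueError):
            binned_map(np.ones(10), np.arange(10), np.arange(10))


class TestDecoyTable:
    @staticmethod
    def _frame(cells, n_sub):
        rows = []
        for s in range(n_sub):
            for i, (pr, dom) in enumerate(
                [("H", "inferior"), ("H", "superior"), ("L", "inferior"), ("L", "superior")]
            ):
                rows.append(dict(subject=s, proximity=pr, dominance=dom, value=cells[s, i]))
        return pd.DataFrame(rows)

    def test_all_zero_contrasts_give_zero_f(self):
        df = self._frame(np.zeros((6, 4)), 6)
        tab = decoy_effect_table(df)
        assert np.allclose(tab.anova["F"], 0.0)
        assert np.allclose(tab.cells.to_numpy(), 0.0)

    def test_known_interaction_structure_detected(self):
        rng = np.random.default_rng(6)
        delta = 0.05
        cells = rng.normal(0.0, 0.05, size=(50, 4))
        cells[:, 0] += delta   # (H, inferior)
        cells[:, 1] -= delta   # (H, superior)
        tab = decoy_effect_table(self._frame(cells, 50))
        assert tab.anova.loc["interaction", "p"] < 0.05
        assert tab.cell_tests.loc["H_inferior", "mean"] > 0

    def test_matches_pingouin_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        cells = rng.normal(size=(20, 4)) * 0.05 + np.array([0.05, -0.02, -0.01, 0.02])
        df = self._frame(cells, 20)
        tab = decoy_effect_table(df)
        aov = pg.rm_anova(data=df, dv="value", within=["proximity", "dominance"],
                          subject="subject").set_index("Source")
        assert tab.anova.loc["proximity", "F"] == pytest.approx(
            aov.loc["proximity", "F"], rel=1e-8
        )
        assert tab.anova.loc["interaction", "F"] == pytest.approx(
            aov.loc["proximity * dominance", "F"], rel=1e-8
        )
        assert tab.anova.loc["dominance", "p"] == pytest.approx(
            aov.loc["dominance", "p_unc"], rel=1e-8
        )

    def test_subject_with_empty_cell_excluded(self):
        cells = np.zeros((4, 4))
        df = self._frame(cells, 4)
        df = df[~((df["subject"] == 0) & (df["proximity"] == "H"))]
        with pytest.warns(UserWarning, match="excluded"):
            tab = decoy_effect_table(df)
        assert len(tab.cells.dropna()) == 3
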