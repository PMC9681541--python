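import math

import numpy as np
import pandas as pd
import pytest

from topoqspr import paper_data
from topoqspr.indices import INDEX_NAMES, round_half_up
from topoqspr.qspr import (
    DegeneratePredictorError,
    DegenerateResponseError,
    InsufficientDataError,
    RegressionFit,
    correlation_table,
    diagnostics_tables,
    fit_all,
    fit_simple_linear,
    predict,
    prediction_table,
)


class TestFitSimpleLinear:
    def test_exact_line(self):
        fit = fit_simple_linear([1, 2, 3], [5, 7, 9])
        assert fit.intercept == pytest.approx(3)
        assert fit.slope == pytest.approx(2)
        assert fit.r == pytest.approx(1)
        assert fit.se == 0
        assert math.isinf(fit.f_stat) and fit.p_value == 0

    def test_against_statsmodels_ols(self):
        """Independent cross-check of every reported statistic on a small
        noisy dataset."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        x = np.arange(12, dtype=float)
        y = 3.5 - 0.8 * x + rng.normal(0, 2.0, size=12)
        fit = fit_simple_linear(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(ols.params[0], rel=1e-10)
        assert fit.slope == pytest.approx(ols.params[1], rel=1e-10)
        assert fit.r2 == pytest.approx(ols.rsquared, rel=1e-10)
        assert fit.se == pytest.approx(math.sqrt(ols.mse_resid), rel=1e-10)
        assert fit.f_stat == pytest.approx(ols.fvalue, rel=1e-10)
        assert fit.p_value == pytest.approx(ols.f_pvalue, rel=1e-10)

    def test_fit_invariants(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 50, size=20)
        y = 2 + 0.5 * x + rng.normal(0, 3, size=20)
        fit = fit_simple_linear(x, y)
        resid = y - predict(fit, x)
        assert abs(resid.sum()) < 1e-9 * np.abs(y).sum()
        # fitted line passes through the centroid
        assert predict(fit, x.mean()) == pytest.approx(y.mean())
        # r2 = r^2; F equals the squared slope t statistic
        assert fit.r2 == pytest.approx(fit.r**2, abs=1e-12)
        sxx = ((x - x.mean()) ** 2).sum()
        t_slope = fit.slope / (fit.se / math.sqrt(sxx))
        assert fit.f_stat == pytest.approx(t_slope**2, rel=1e-10)

    def test_pairwise_deletion_drops_incomplete_pairs(self):
        x = [1, 2, 3, 4, np.nan]
        y = [2, np.nan, 6, 8, 10]
        fit = fit_simple_linear(x, y)
        assert fit.n == 3
        assert fit.slope == pytest.approx(2)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            fit_simple_linear([1, 2], [3, 4])
        with pytest.raises(InsufficientDataError):
            fit_simple_linear([1, 2, np.nan, np.nan], [1, 2, 3, 4])
        with pytest.raises(DegeneratePredictorError):
            fit_simple_linear([5, 5, 5], [1, 2, 3])
        with pytest.raises(DegenerateResponseError):
            fit_simple_linear([1, 2, 3], [4, 4, 4])


class TestPublishedRegressions:
    """The study's own statistics, recomputed from the bundled tables."""

    def test_complexity_on_forgotten_index(self, all_fits):
        fit = all_fits[("F", "complexity")]
        assert round_half_up(fit.intercept, 3) == -88.525
        assert round_half_up(fit.slope, 3) == 1.870
        assert round_half_up(fit.r, 3) == 0.952
        assert round_half_up(fit.f_stat, 3) == 86.119
        assert round_half_up(fit.se, 3) == 101.327

    def test_complexity_on_first_zagreb(self, all_fits):
        fit = all_fits[("M1", "complexity")]
        assert round_half_up(fit.slope, 3) == 6.269
        assert round_half_up(fit.intercept, 3) == -214.531

    def test_enthalpy_on_harmonic(self, all_fits):
        assert round_half_up(all_fits[("H", "enthalpy")].r, 3) == 0.838

    def test_refractivity_models_use_nine_drugs(self, all_fits):
        """Two drugs lack a refractivity value; pairwise deletion leaves 9."""
        for idx in INDEX_NAMES:
            assert all_fits[(idx, "refractivity")].n == 9
        for idx in INDEX_NAMES:
            assert all_fits[(idx, "complexity")].n == 11


class TestPredict:
    def test_identity_fit(self):
        fit = RegressionFit(0.0, 1.0, 5, 1.0, 1.0, 0.0, math.inf, 0.0)
        x = np.array([1.5, -2.0, 7.0])
        assert np.allclose(predict(fit, x), x)
        assert predict(fit, 3.25) == 3.25

    def test_published_coefficients_reproduce_comparison_table_cell(self):
        # enthalpy model quoted as A=11.592, b=0.374 in the source; its
        # comparison table entry for a molecule with M2=79 is 41.138
        fit = RegressionFit(11.592, 0.374, 11, 0.769, 0.591, 21.3, 12.989, 0.006)
        assert round_half_up(predict(fit, 79), 3) == 41.138

    def test_coef_rounding_switch(self, all_fits):
        fit = all_fits[("M1", "complexity")]
        assert round_half_up(predict(fit, 78, coef_digits=3), 3) == 274.451
        assert predict(fit, 78) != predict(fit, 78, coef_digits=3)


class TestTables:
    def test_correlation_table_cells_equal_fit_r(self, ti_table, property_table, all_fits):
        r, n = correlation_table(ti_table, property_table, paper_data.MODELED_PROPERTIES)
        assert r.shape == (9, 5)
        assert r.loc["F", "complexity"] == pytest.approx(all_fits[("F", "complexity")].r)
        assert round_half_up(r.loc["F", "complexity"], 3) == 0.952
        assert n.loc["M1", "refractivity"] == 9

    def test_perfect_self_correlation(self, ti_table):
        props = ti_table[["M1"]].rename(columns={"M1": "self"})
        r, _ = correlation_table(ti_table, props, ["self"])
        assert r.loc["M1", "self"] == pytest.approx(1.0)

    def test_diagnostics_structure_and_se_matrix(self, all_fits):
        diag = diagnostics_tables(all_fits)
        assert set(diag.params) == set(INDEX_NAMES)
        assert diag.se.shape == (9, 5) and diag.r2.shape == (9, 5)
        assert round_half_up(diag.se.loc["F", "complexity"], 3) == 101.327
        assert diag.r2.loc["F", "complexity"] == pytest.approx(
            all_fits[("F", "complexity")].r ** 2
        )
        row = diag.params["F"].loc["complexity"]
        assert row["N"] == 11 and row["indicator"] == "Significant"

    def test_significance_convention(self):
        sig_by_r = RegressionFit(0, 1, 11, 0.65, 0.42, 1, 4.0, 0.08)
        sig_by_p = RegressionFit(0, -1, 11, -0.9, 0.81, 1, 38.0, 0.0002)
        neither = RegressionFit(0, 1, 11, 0.3, 0.09, 1, 0.9, 0.37)
        assert sig_by_r.significant() and sig_by_p.significant()
        assert not neither.significant()
        diag = diagnostics_tables(
            {("M1", "prop"): neither, ("M2", "prop"): sig_by_r} |
            {(idx, "prop"): sig_by_p for idx in INDEX_NAMES if idx not in ("M1", "M2")}
        )
        tab = pd.concat({i: diag.params[i] for i in ("M1", "M2")})
        assert list(tab["indicator"]) == ["Not significant", "Significant"]
        assert not diag.params["M1"].loc["prop", "sig_p"]
        assert diag.params["M2"].loc["prop", "sig_r"]

    def test_perfect_line_reported_as_unbounded_f(self):
        x = pd.DataFrame(
            {name: [1.0, 2, 3, 4] for name in INDEX_NAMES},
            index=list("abcd"),
        )
        props = pd.DataFrame({"p": [2.0, 4, 6, 8]}, index=list("abcd"))
        fits = fit_all(x, props)
        diag = diagnostics_tables(fits)
        assert diag.se.loc["M1", "p"] == 0
        assert diag.r2.loc["M1", "p"] == pytest.approx(1)
        assert math.isinf(diag.params["M1"].loc["p", "F"])

    def test_prediction_table_includes_drugs_with_missing_property(
        self, ti_table, property_table, all_fits
    ):
        pred = prediction_table(ti_table, property_table, "refractivity", all_fits)
        assert len(pred) == 11
        assert pred["actual"].isna().sum() == 2
        assert pred.loc["psoralen", "M1"] == pytest.approx(
            predict(all_fits[("M1", "refractivity")], 78, coef_digits=3)
        )
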