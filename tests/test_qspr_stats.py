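"""Regression statistics against scipy oracles and numeric minimisation."""

import numpy as np
import pytest
from scipy import optimize, stats

from topoqspr import (
    DegenerateFitError,
    build_qspr_report,
    f_upper_tail_p,
    fit_simple_regression,
    pearson_correlation,
)


class TestPearsonCorrelation:
    def test_exact_positive_and_negative_lines(self):
        x = np.arange(1.0, 11.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert pearson_correlation(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateFitError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestFUpperTail:
    def test_f_zero_gives_one(self):
        assert f_upper_tail_p(0.0, 1, 13) == 1.0

    @pytest.mark.parametrize(
        "f,df2,expect",
        [(6.8854, 13, 0.0210), (20.0359, 13, 0.0006)],
    )
    def test_published_examples(self, f, df2, expect):
        assert f_upper_tail_p(f, 1, df2) == pytest.approx(expect, abs=5e-5)

    def test_matches_incomplete_beta_form(self):
        # P(F > f) = I_{df2/(df2+df1 f)}(df2/2, df1/2)
        from scipy.special import betainc

        f, df1, df2 = 3.7, 1, 13
        x = df2 / (df2 + df1 * f)
        assert f_upper_tail_p(f, df1, df2) == pytest.approx(
            betainc(df2 / 2, df1 / 2, x), abs=1e-12
        )


class TestFitSimpleRegression:
    def test_exact_line_recovered(self):
        ti = np.array([1.0, 2, 3, 4, 5])
        fit = fit_simple_regression(ti, 3 + 2 * ti)
        assert fit.intercept_A == pytest.approx(3.0)
        assert fit.slope_b == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.see == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_linregress(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, size=15)
        y = 5 + 0.3 * x + rng.normal(0, 4, size=15)
        fit = fit_simple_regression(x, y)
        ref = stats.linregress(x, y)
        assert fit.intercept_A == pytest.approx(ref.intercept, rel=1e-10)
        assert fit.slope_b == pytest.approx(ref.slope, rel=1e-10)
        assert fit.pearson_r == pytest.approx(ref.rvalue, rel=1e-10)
        assert fit.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numeric_least_squares_minimiser(self, seed):
        """Closed-form OLS equals the minimiser of the residual sum of squares."""
        rng = np.random.default_rng(40 + seed)
        x = rng.uniform(-5, 5, size=12)
        y = rng.normal(1 - 0.7 * x, 0.5)
        fit = fit_simple_regression(x, y)

        def rss(theta):
            a, b = theta
            r = y - a - b * x
            return float(r @ r)

        res = optimize.minimize(rss, x0=[0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.intercept_A == pytest.approx(res.x[0], abs=1e-6)
        assert fit.slope_b == pytest.approx(res.x[1], abs=1e-6)

    def test_internal_consistency_invariants(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, size=15)
        y = rng.normal(2 + x, 1.0)
        fit = fit_simple_regression(x, y)
        assert fit.r_squared == pytest.approx(fit.pearson_r**2, abs=1e-12)
        n = fit.n
        assert fit.f_stat == pytest.approx(
            fit.r_squared * (n - 2) / (1 - fit.r_squared), abs=1e-9
        )
        assert fit.significant == (fit.p_value < 0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, size=15)
        y = rng.normal(2 + x, 1.0)
        base = fit_simple_regression(x, y)
        scaled = fit_simple_regression(1000 * x, y)
        assert scaled.slope_b == pytest.approx(base.slope_b / 1000, rel=1e-10)
        assert scaled.pearson_r == pytest.approx(base.pearson_r, rel=1e-12)
        assert scaled.f_stat == pytest.approx(base.f_stat, rel=1e-9)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)
        assert scaled.see == pytest.approx(base.see, rel=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_simple_regression([2, 2, 2, 2], [1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_simple_regression([1, 2], [1, 2])


class TestBuildQsprReport:
    def test_report_covers_all_forty_cells(self, fixtures):
        rep = build_qspr_report(fixtures, index_source="table")
        assert len(rep.fits) == 40
        assert rep.correlation_table.shape == (5, 8)
        assert rep.see_table.shape == (5, 8)
        assert not rep.errors

    def test_published_correlation_cells(self, fixtures):
        rep = build_qspr_report(fixtures, index_source="table")
        assert rep.correlation_table.loc["detour", "molar_refractivity"] == pytest.approx(
            0.8908, abs=5e-4
        )
        assert rep.correlation_table.loc["harary", "molar_refractivity"] == pytest.approx(
            0.7987, abs=5e-4
        )

    def test_published_see_cell(self, fixtures):
        rep = build_qspr_report(fixtures, index_source="table")
        assert rep.see_table.loc["detour", "molar_refractivity"] == pytest.approx(
            3.6495, abs=5e-3
        )

    def test_melting_point_not_predicted_by_detour_harary(self, fixtures):
        rep = build_qspr_report(fixtures, index_source="table")
        assert not rep.fit("detour_harary", "melting_point").significant

    def test_small_panel_flagged_low_power(self, fixtures):
        rep = build_qspr_report(fixtures[:3], index_source="table")
        assert any("low power" in w for w in rep.warnings)
        assert len(rep.fits) == 40

    def test_computed_source_runs_and_differs_only_where_documented(self, fixtures):
        rep_t = build_qspr_report(fixtures, index_source="table")
        rep_c = build_qspr_report(fixtures, index_source="computed")
        # integer-index rows are identical between sources
        for iname in ("wiener", "hyper_wiener", "detour"):
            for pname in rep_t.correlation_table.columns:
                assert rep_c.correlation_table.loc[iname, pname] == pytest.approx(
                    rep_t.correlation_table.loc[iname, pname], abs=1e-6
                )
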