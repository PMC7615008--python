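import numpy as np
import pandas as pd
import pytest

from mvpgs import (
    CohortDataset,
    CohortSpec,
    GeneratorTruth,
    bonferroni_alpha,
    fit_indices,
    fit_model,
    fit_multivariate,
    fit_univariate,
    simulate_cohort,
    standard_errors,
    standardize_for_analysis,
    wald_results,
)
from mvpgs.fit import FitError, FitOptions, FitResult, compute_fit_indices
from mvpgs.likelihood import ParameterSpace, build_design


@pytest.fixture(scope="module")
def singleton_fit():
    """Complete-data singleton cohort: the FIML MLE has closed-form pieces."""
    spec = CohortSpec(name="A", is_twin_cohort=False, n_pcs=2)
    truth = GeneratorTruth(miss_rate=0.0, b_pcs=np.zeros((3, 2)))
    ds = simulate_cohort(spec, 800, truth, seed=21)
    std = standardize_for_analysis(ds)
    fit = fit_multivariate([std])
    return std, fit


class TestFitMultivariate:
    def test_result_improves_on_start_and_converges(self, small_std):
        fit = fit_multivariate(small_std)
        assert fit.converged
        assert np.isfinite(fit.loglik)
        assert fit.n_children == sum(ds.n_children for ds in small_std)

    def test_non_convergence_is_reported_not_silent(self, small_std):
        fit = fit_multivariate(small_std, FitOptions(maxiter=1))
        assert isinstance(fit, FitResult)
        assert fit.theta_hat.shape == (fit.n_params,)

    def test_deterministic_given_inputs(self, small_std):
        a = fit_multivariate(small_std)
        b = fit_multivariate(small_std)
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)

    def test_likelihood_ratio_of_nested_models_nonnegative(self, small_std):
        full = fit_multivariate(small_std)
        restricted_space = ParameterSpace(small_std, predictors=("MDD",))
        restricted = fit_model(small_std, restricted_space)
        assert 2 * (full.loglik - restricted.loglik) >= -1e-6


class TestStandardErrors:
    def test_single_outcome_matches_closed_form_ols_covariance(self):
        spec = CohortSpec(
            name="S", outcomes_present=("ADHD",), is_twin_cohort=False,
            n_pcs=0,
        )
        truth = GeneratorTruth(miss_rate=0.0)
        ds = simulate_cohort(spec, 2000, truth, seed=22)
        std = standardize_for_analysis(ds)
        fit = fit_multivariate([std])
        se = standard_errors(fit)
        lay = fit.space.cohorts[0]
        X = build_design(std, lay.design_columns)
        y = std.table["adhd"].to_numpy()
        # independent route: statsmodels OLS (its SEs use the unbiased
        # residual variance, ours the MLE; the ratio is sqrt(n/(n-p)))
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(
            fit.theta_hat[lay.coef_idx[:, 0]], ols.params, atol=1e-5
        )
        adj = np.sqrt((len(y) - X.shape[1]) / len(y))
        np.testing.assert_allclose(
            se[lay.coef_idx[:, 0]], ols.bse * adj, rtol=0.02
        )

    def test_duplicating_families_halves_squared_ses(self, singleton_fit):
        std, fit = singleton_fit
        se1 = standard_errors(fit)
        dup = std.table.copy()
        dup["family_id"] = dup["family_id"] + "_dup"
        doubled = CohortDataset(
            spec=std.spec,
            table=pd.concat([std.table, dup], ignore_index=True),
        )
        fit2 = fit_multivariate([doubled])
        se2 = standard_errors(fit2)
        for out in ("ADHD", "INT", "SOC"):
            for pred in ("MDD", "EA", "BMI", "sex"):
                i = fit.space.shared_slot(out, pred)
                j = fit2.space.shared_slot(out, pred)
                assert se2[j] ** 2 / se1[i] ** 2 == pytest.approx(
                    0.5, rel=0.02
                )

    def test_ignoring_twin_clustering_shrinks_family_covariate_se(self):
        # age is shared within a twin pair, so pretending twins are
        # independent overstates the information about its coefficient
        spec = CohortSpec(name="T", is_twin_cohort=True, n_pcs=0)
        truth = GeneratorTruth(miss_rate=0.0)
        ds = simulate_cohort(spec, 2000, truth, seed=23)
        std = standardize_for_analysis(ds)
        with_twin = fit_model([std], ParameterSpace([std], cross_twin=True))
        no_twin = fit_model([std], ParameterSpace([std], cross_twin=False))
        se_t = standard_errors(with_twin)
        se_n = standard_errors(no_twin)
        for out in ("ADHD", "INT", "SOC"):
            i = with_twin.space.shared_slot(out, "age")
            j = no_twin.space.shared_slot(out, "age")
            assert se_n[j] < se_t[i]
            # point estimates stay close (approximately unbiased)
            assert abs(
                with_twin.theta_hat[i] - no_twin.theta_hat[j]
            ) < 4 * se_t[i]


class TestWald:
    def test_z_and_p_arithmetic(self):
        alpha = bonferroni_alpha(3, 7, 0.05)
        from scipy.stats import norm

        z = 0.0196 / 0.01
        assert z == pytest.approx(1.96)
        assert 2 * norm.sf(abs(z)) == pytest.approx(0.05, abs=1e-3)
        # p = 0.003 is not significant at the Bonferroni threshold
        assert not (0.003 < alpha)

    def test_results_table_contract(self, small_std):
        fit = fit_multivariate(small_std)
        tab = wald_results(fit)
        # 7 PGS x 3 outcomes + sex x 3 + age x 3
        assert len(tab) == 27
        np.testing.assert_allclose(
            tab["ci_low"], tab["beta"] - 1.96 * tab["se"], atol=1e-12
        )
        np.testing.assert_allclose(
            tab["ci_high"], tab["beta"] + 1.96 * tab["se"], atol=1e-12
        )
        alpha = bonferroni_alpha(3, 7, 0.05)
        assert (tab["significant"] == (tab["p"] < alpha)).all()
        zero_beta = tab["beta"] == 0.0
        assert (tab.loc[~zero_beta, "p"] > 0).all()


class TestBonferroni:
    @pytest.mark.parametrize(
        "n_out, n_pred, fw, expected",
        [(3, 7, 0.05, 0.05 / 21), (1, 1, 0.05, 0.05), (2, 5, 0.10, 0.01)],
    )
    def test_values(self, n_out, n_pred, fw, expected):
        assert bonferroni_alpha(n_out, n_pred, fw) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0, 7, 0.05)
        with pytest.raises(ValueError):
            bonferroni_alpha(3, 7, 1.5)


class TestFitIndices:
    def test_formula_arithmetic_on_frozen_values(self):
        # hand-computed from the formulas with ll_sat=-1000, ll_fit=-1030,
        # ll_base=-1100, params 60/40/20, N=500
        fi = compute_fit_indices(
            ll_fit=-1030.0, n_fit=40,
            ll_sat=-1000.0, n_sat=60,
            ll_base=-1100.0, n_base=20,
            n_total=500,
        )
        assert fi.chi2 == pytest.approx(60.0)
        assert fi.df == 20
        assert fi.chi2_baseline == pytest.approx(200.0)
        assert fi.df_baseline == 40
        assert fi.rmsea == pytest.approx(np.sqrt(40.0 / (20 * 500)))
        assert fi.cfi == pytest.approx(1 - 40.0 / 160.0)
        assert fi.tli == pytest.approx((5.0 - 3.0) / (5.0 - 1.0))

    def test_saturated_equals_fitted_gives_zero_chi2(self):
        fi = compute_fit_indices(
            ll_fit=-500.0, n_fit=10, ll_sat=-500.0, n_sat=30,
            ll_base=-600.0, n_base=5, n_total=100,
        )
        assert fi.chi2 == pytest.approx(0.0)
        assert fi.rmsea == 0.0
        assert fi.cfi == pytest.approx(1.0)

    def test_chi2_equal_df_gives_zero_rmsea(self):
        fi = compute_fit_indices(
            ll_fit=-510.0, n_fit=10, ll_sat=-500.0, n_sat=30,
            ll_base=-600.0, n_base=5, n_total=100,
        )
        assert fi.chi2 == pytest.approx(fi.df)
        assert fi.rmsea == 0.0

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            compute_fit_indices(-500, 30, -499, 30, -600, 5, 100)

    def test_end_to_end_indices_on_small_study(self, small_std):
        fit = fit_multivariate(small_std)
        fi = fit_indices(fit, small_std)
        assert fi.chi2 >= -1e-6
        assert fi.df > 0
        assert fi.loglik_saturated >= fi.loglik_fitted - 1e-6
        assert fi.loglik_fitted >= fi.loglik_baseline - 1e-6
        assert np.isfinite(fi.rmsea)


class TestUnivariate:
    def test_unknown_predictor_raises(self, small_std):
        with pytest.raises(KeyError, match="unknown predictor"):
            fit_univariate(small_std, "IQ")

    def test_orthogonal_scores_univariate_equals_multivariate(self):
        truth = GeneratorTruth(R_pgs=np.eye(7), miss_rate=0.0,
                               Sigma_X=np.zeros((3, 3)))
        spec = CohortSpec(name="A", is_twin_cohort=False, n_pcs=0)
        ds = simulate_cohort(spec, 8000, truth, seed=24)
        std = standardize_for_analysis(ds)
        multi = wald_results(fit_multivariate([std]))
        uni = fit_univariate([std], "EA")
        for out in ("ADHD", "INT", "SOC"):
            m = multi[
                (multi.outcome == out) & (multi.predictor == "EA")
            ].iloc[0]
            u = uni[uni.outcome == out].iloc[0]
            assert u.beta == pytest.approx(m.beta, abs=3 * m.se)

    def test_univariate_table_has_three_rows(self, small_std):
        tab = fit_univariate(small_std, "MDD")
        assert list(tab["outcome"]) == ["ADHD", "INT", "SOC"]
        assert (tab["predictor"] == "MDD").all()
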