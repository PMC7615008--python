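import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from mvpgs import (
    CohortDataset,
    CohortSpec,
    GeneratorTruth,
    simulate_cohort,
    standardize_for_analysis,
)
from mvpgs.likelihood import (
    LikelihoodError,
    ParameterSpace,
    StudyEvaluator,
    chol_to_cov,
    cov_to_chol,
    family_mean_cov,
    iter_family_designs,
    loglik_naive,
)


from tests_helpers import feasible_theta as _random_theta  # noqa: E402
from tests_helpers import random_study as _random_study  # noqa: E402


class TestPackUnpack:
    def test_zero_vector_gives_null_model(self, small_std):
        space = ParameterSpace(small_std)
        theta = np.zeros(space.n_params)
        for c in range(len(small_std)):
            np.testing.assert_array_equal(
                space.coef(theta, c), np.zeros_like(space.coef(theta, c))
            )
            np.testing.assert_allclose(
                space.sigma_w(theta, c), np.eye(space.cohorts[c].d),
                atol=1e-14,
            )
            np.testing.assert_array_equal(
                space.sigma_x(theta, c),
                np.zeros((space.cohorts[c].d, space.cohorts[c].d)),
            )

    def test_round_trip_bit_exact(self, small_std, rng):
        space = ParameterSpace(small_std)
        theta = _random_theta(space, rng)
        back = space.pack(space.unpack(theta))
        np.testing.assert_array_equal(theta, back)

    def test_length_mismatch_raises(self, small_std):
        space = ParameterSpace(small_std)
        with pytest.raises(Exception, match="length|shape"):
            space.unpack(np.zeros(space.n_params + 1))

    def test_shared_slot_propagates_to_every_cohort(self, small_std, rng):
        space = ParameterSpace(small_std)
        theta = _random_theta(space, rng)
        slot = space.shared_slot("ADHD", "MDD")
        bumped = theta.copy()
        bumped[slot] += 0.123
        for c, lay in enumerate(space.cohorts):
            col = lay.design_columns.index("pgs_mdd")
            j = list(lay.oidx).index(0)  # ADHD is outcome 0 everywhere
            before = space.coef(theta, c)[col, j]
            after = space.coef(bumped, c)[col, j]
            assert after == pytest.approx(before + 0.123)

    def test_log_cholesky_round_trip(self, rng):
        for _ in range(10):
            A = rng.normal(size=(3, 3))
            S = A @ A.T + 3 * np.eye(3)
            np.testing.assert_allclose(
                chol_to_cov(cov_to_chol(S), 3), S, rtol=1e-12
            )


class TestFamilyMeanCov:
    def test_zero_cross_twin_gives_block_diagonal(self, rng):
        spec = CohortSpec(name="T", is_twin_cohort=True, n_pcs=0)
        ds = simulate_cohort(
            spec, 10, GeneratorTruth(miss_rate=0.0), seed=1
        )
        space = ParameterSpace([ds])
        theta = _random_theta(space, rng)
        theta[space.cohorts[0].sx_slice] = 0.0
        fd = next(
            f for f in iter_family_designs(space, [ds]) if f.size == 2
        )
        _, cov = family_mean_cov(space, theta, fd)
        np.testing.assert_array_equal(cov[:3, 3:], np.zeros((3, 3)))
        np.testing.assert_allclose(cov[:3, :3], cov[3:, 3:])

    def test_zero_design_gives_zero_mean(self, rng):
        spec = CohortSpec(name="T", is_twin_cohort=True, n_pcs=0)
        ds = simulate_cohort(spec, 10, GeneratorTruth(miss_rate=0.0), seed=2)
        space = ParameterSpace([ds])
        theta = _random_theta(space, rng)
        fd = next(iter_family_designs(space, [ds]))
        fd.X = np.zeros_like(fd.X)
        mean, _ = family_mean_cov(space, theta, fd)
        np.testing.assert_array_equal(mean, np.zeros_like(mean))

    def test_twin_order_swap_permutes_mean_and_cov(self, rng):
        spec = CohortSpec(name="T", is_twin_cohort=True, n_pcs=2)
        ds = simulate_cohort(spec, 10, GeneratorTruth(miss_rate=0.0), seed=3)
        space = ParameterSpace([ds])
        theta = _random_theta(space, rng)
        fd = next(
            f for f in iter_family_designs(space, [ds]) if f.size == 2
        )
        mean, cov = family_mean_cov(space, theta, fd)
        fd.X = fd.X[::-1]
        mean2, cov2 = family_mean_cov(space, theta, fd)
        perm = np.r_[3:6, 0:3]
        np.testing.assert_allclose(mean2, mean[perm])
        np.testing.assert_allclose(cov2, cov[np.ix_(perm, perm)])


def _singleton_dataset(y_values):
    """One non-twin cohort of singletons with given (n, 3) outcomes and
    all-zero predictors."""
    n = len(y_values)
    tab = pd.DataFrame(
        {
            "family_id": [f"F{i}" for i in range(n)],
            "member_index": 0,
            "sex": 0,
            "age": 9.5,
        }
    )
    for j, col in enumerate(("adhd", "int", "soc")):
        tab[col] = np.asarray(y_values, dtype=float)[:, j]
    for col in (
        "pgs_mdd", "pgs_bip", "pgs_swb", "pgs_neu", "pgs_ins", "pgs_ea",
        "pgs_bmi",
    ):
        tab[col] = 0.0
    spec = CohortSpec(name="S", is_twin_cohort=False, n_pcs=0)
    return CohortDataset(spec=spec, table=tab)


class TestLoglik:
    def test_single_observation_standard_normal_density(self):
        ds = _singleton_dataset([[0.0, np.nan, np.nan]])
        space = ParameterSpace([ds])
        theta = np.zeros(space.n_params)  # beta = 0, Sigma_W = I
        ev = StudyEvaluator(space, [ds])
        expected = -0.5 * math.log(2 * math.pi)
        assert ev.loglik(theta) == pytest.approx(expected, abs=1e-12)
        assert loglik_naive(theta, [ds], space) == pytest.approx(
            expected, abs=1e-12
        )

    def test_empty_study_and_fully_missing_family(self):
        ds = _singleton_dataset(
            [[np.nan, np.nan, np.nan], [np.nan, np.nan, np.nan]]
        )
        space = ParameterSpace([ds])
        theta = np.zeros(space.n_params)
        assert loglik_naive(theta, [ds], space) == 0.0
        assert StudyEvaluator(space, [ds]).loglik(theta) == 0.0
        assert loglik_naive(theta, [], ParameterSpace([])) == 0.0

    def test_vectorized_equals_naive_on_random_studies(self, rng):
        # the central correctness property; the 50-study version runs in
        # the acceptance suite
        for _ in range(8):
            study = _random_study(rng)
            space = ParameterSpace(study)
            theta = _random_theta(space, rng)
            ev = StudyEvaluator(space, study)
            assert ev.loglik(theta) == pytest.approx(
                loglik_naive(theta, study, space), abs=1e-8
            )

    def test_invariant_to_family_and_member_ordering(self, rng):
        spec = CohortSpec(name="T", is_twin_cohort=True, n_pcs=1)
        ds = simulate_cohort(
            spec, 30, GeneratorTruth(miss_rate=0.2), seed=11
        )
        space = ParameterSpace([ds])
        theta = _random_theta(space, rng)
        base = StudyEvaluator(space, [ds]).loglik(theta)
        order = rng.permutation(ds.n_children)
        shuffled = CohortDataset(
            spec=spec, table=ds.table.iloc[order].reset_index(drop=True)
        )
        space2 = ParameterSpace([shuffled])
        assert StudyEvaluator(space2, [shuffled]).loglik(
            theta
        ) == pytest.approx(base, abs=1e-8)

    def test_masking_changes_loglik_by_marginal_density_difference(self, rng):
        y = rng.normal(size=(1, 3))
        ds_full = _singleton_dataset(y)
        y_masked = y.copy()
        y_masked[0, 2] = np.nan
        ds_masked = _singleton_dataset(y_masked)
        space = ParameterSpace([ds_full])
        theta = _random_theta(space, rng, scale=0.2)
        sw = space.sigma_w(theta, 0)
        # the design reduces to the intercept here, so the family mean is
        # just the per-outcome intercept vector
        mu = theta[space.cohorts[0].coef_idx][0]
        ll_full = StudyEvaluator(space, [ds_full]).loglik(theta)
        space_m = ParameterSpace([ds_masked])
        ll_masked = StudyEvaluator(space_m, [ds_masked]).loglik(theta)
        expected_delta = multivariate_normal.logpdf(
            y[0], mean=mu, cov=sw
        ) - multivariate_normal.logpdf(y[0, :2], mean=mu[:2], cov=sw[:2, :2])
        assert ll_full - ll_masked == pytest.approx(expected_delta, abs=1e-10)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        study = _random_study(rng, n_cohorts=2)
        space = ParameterSpace(study)
        ev = StudyEvaluator(space, study)
        theta = _random_theta(space, rng, scale=0.2)
        _, g = ev.loglik_grad(theta)
        h = 1e-6
        k = min(20, space.n_params)
        for i in rng.choice(space.n_params, k, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            num = (ev.loglik(tp) - ev.loglik(tm)) / (2 * h)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_near_singular_covariance_raises(self):
        ds = _singleton_dataset([[0.1, 0.2, 0.3]])
        space = ParameterSpace([ds])
        theta = np.zeros(space.n_params)
        # log-Cholesky diagonal of -20 gives variances ~ e^-40
        sw = space.cohorts[0].sw_slice
        theta[sw] = np.array([-20.0, 0.0, -20.0, 0.0, 0.0, 20.0])
        with pytest.raises(LikelihoodError, match="condition"):
            StudyEvaluator(space, [ds]).loglik(theta)
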