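"""Ideal-observer statistic, AUC estimators, and derivation identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from obseval import (
    DomainError,
    EvaluationError,
    Gaussian,
    ParameterError,
    auc_2afc_mc,
    auc_approx_from_db,
    auc_empirical_roc,
    bhattacharyya,
    bhattacharyya_from_lr_samples,
    ideal_statistic,
    lambda_density_identity_check,
    log_likelihood_ratio,
    moment_identity_check,
)


class TestLogLikelihoodRatio:
    def test_identical_models_give_zero(self, std_gauss_2d):
        x = np.array([[0.3, -1.2], [5.0, 2.0]])
        np.testing.assert_allclose(
            log_likelihood_ratio(std_gauss_2d, std_gauss_2d, x), 0.0, atol=1e-12
        )

    @pytest.mark.parametrize("x,expected", [(1.0, 0.0), (2.0, 2.0), (0.0, -2.0)])
    def test_unit_variance_mean_shift_is_linear(self, x, expected):
        """For N(0,1) vs N(2,1), lambda = 2x - 2."""
        q1 = Gaussian(mean=[0.0], cov=[[1.0]])
        q2 = Gaussian(mean=[2.0], cov=[[1.0]])
        assert log_likelihood_ratio(q1, q2, np.array([x])) == pytest.approx(
            expected, abs=1e-12
        )


class TestAuc2afcMc:
    def test_matched_distributions_stay_at_chance(self, std_gauss_2d):
        q2 = Gaussian(mean=[0.0, 0.0], cov=np.eye(2))
        res = auc_2afc_mc(std_gauss_2d, q2, n_pairs=100_000, seed=5,
                          pairing="paired", tie_break="random")
        assert abs(res.auc - 0.5) < 3.0 * np.sqrt(0.25 / 100_000)

    def test_known_separation_matches_closed_form(self, std_gauss_2d, shifted_gauss_2d):
        """Equal covariance, d_A = 2: ideal AUC = Phi(sqrt(2))."""
        res = auc_2afc_mc(std_gauss_2d, shifted_gauss_2d, n_pairs=100_000, seed=6)
        assert abs(res.auc - norm.cdf(np.sqrt(2.0))) < 3.0 * res.mc_std_error

    def test_constant_statistic_all_ties_score_half(self, std_gauss_2d, shifted_gauss_2d):
        res = auc_2afc_mc(
            std_gauss_2d, shifted_gauss_2d,
            statistic=lambda x: np.zeros(len(x)), n_pairs=500, seed=0,
        )
        assert res.auc == 0.5
        assert res.tie_fraction == 1.0

    def test_cross_pairing_equals_empirical_roc_on_same_samples(
        self, std_gauss_2d, shifted_gauss_2d
    ):
        """2-AFC proportion correct over all synthetic-real pairings is the
        tie-corrected rank-sum AUC of the same scores."""
        n, seed = 3000, 42
        res = auc_2afc_mc(std_gauss_2d, shifted_gauss_2d, n_pairs=n, seed=seed)
        rng = np.random.default_rng(seed)
        stat = ideal_statistic(std_gauss_2d, shifted_gauss_2d)
        s1 = stat(std_gauss_2d.sample(n, rng))
        s2 = stat(shifted_gauss_2d.sample(n, rng))
        roc = auc_empirical_roc(s1, s2)
        assert res.auc == pytest.approx(roc.auc, abs=1e-15)

    def test_ideal_statistic_upper_bounds_linear_statistic(self):
        """Unequal-covariance pair: the likelihood ratio beats any fixed
        linear statistic, within 3 combined standard errors."""
        q1 = Gaussian(mean=[0.0, 0.0], cov=[[1.0, 0.0], [0.0, 4.0]])
        q2 = Gaussian(mean=[1.0, 0.5], cov=[[2.0, 0.5], [0.5, 1.0]])
        ideal = auc_2afc_mc(q1, q2, n_pairs=50_000, seed=21)
        for w in ([1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.7, -0.3]):
            w = np.asarray(w)
            lin = auc_2afc_mc(q1, q2, statistic=lambda x, w=w: x @ w,
                              n_pairs=50_000, seed=21)
            tol = 3.0 * np.hypot(ideal.mc_std_error, lin.mc_std_error)
            assert ideal.auc >= lin.auc - tol

    def test_nonfinite_statistic_identifies_index(self, std_gauss_2d, shifted_gauss_2d):
        def bad(x):
            out = np.ones(len(x))
            out[3] = np.nan
            return out

        with pytest.raises(EvaluationError, match="index 3"):
            auc_2afc_mc(std_gauss_2d, shifted_gauss_2d, statistic=bad,
                        n_pairs=10, seed=0)

    def test_invalid_arguments(self, std_gauss_2d):
        with pytest.raises(ParameterError):
            auc_2afc_mc(std_gauss_2d, std_gauss_2d, n_pairs=0, seed=0)
        with pytest.raises(ParameterError):
            auc_2afc_mc(std_gauss_2d, std_gauss_2d, n_pairs=5, seed=0,
                        pairing="cross", tie_break="random")


class TestAucEmpiricalRoc:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ([0, 1], [2, 3], 1.0),           # perfect separation
            ([0, 1], [0, 1], 0.5),           # brute force: (1/2+0+1+1/2)/4
            ([1], [1], 0.5),                 # single tie
            ([2, 3], [0, 1], 0.0),           # fully reversed
        ],
    )
    def test_known_small_cases(self, s1, s2, expected):
        assert auc_empirical_roc(s1, s2).auc == pytest.approx(expected, abs=1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            auc_empirical_roc([], [1.0])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        s1=st.lists(st.integers(min_value=0, max_value=6), min_size=1, max_size=25),
        s2=st.lists(st.integers(min_value=0, max_value=6), min_size=1, max_size=25),
    )
    def test_matches_brute_force_double_loop(self, s1, s2):
        """Rank-sum AUC equals the O(n1*n2) pairwise count, ties scoring half
        (integer scores force many ties)."""
        wins = sum(
            1.0 if b > a else (0.5 if b == a else 0.0) for a in s1 for b in s2
        )
        expected = wins / (len(s1) * len(s2))
        assert auc_empirical_roc(s1, s2).auc == pytest.approx(expected, abs=1e-12)


class TestBhattacharyyaFromLrSamples:
    def test_all_zero_lambdas_mean_identical_distributions(self):
        res = bhattacharyya_from_lr_samples(np.zeros(100))
        assert res.coefficient == 1.0
        assert res.distance == 0.0
        assert res.g0 == 0.0
        assert not res.bc_exceeds_one

    def test_g0_recovers_known_distance(self, std_gauss_2d, shifted_gauss_2d):
        """lambda drawn under H1 for a D_B = 0.5 pair: g0 -> 2.0."""
        rng = np.random.default_rng(17)
        x = std_gauss_2d.sample(100_000, rng)
        lams = log_likelihood_ratio(std_gauss_2d, shifted_gauss_2d, x)
        res = bhattacharyya_from_lr_samples(lams)
        assert abs(res.g0 - 2.0) < 3.0 * 4.0 * res.mc_std_error
        assert not res.bc_exceeds_one

    def test_single_sample_above_one_is_flagged(self):
        res = bhattacharyya_from_lr_samples([2.0 * np.log(2.0)])
        assert res.coefficient == pytest.approx(2.0, abs=1e-12)
        assert res.bc_exceeds_one

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            bhattacharyya_from_lr_samples([])


class TestAucApproxFromDb:
    def test_floor_at_zero_distance_is_exact(self):
        assert auc_approx_from_db(0.0) == 0.5

    def test_reference_value_at_half(self):
        from scipy.special import erf

        assert auc_approx_from_db(0.5) == pytest.approx(0.5 + 0.5 * erf(1.0), abs=1e-15)
        assert auc_approx_from_db(0.5) == pytest.approx(0.92135, abs=1e-5)

    def test_saturates_at_one(self):
        assert auc_approx_from_db(100.0) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing(self):
        d = np.linspace(0.0, 5.0, 200)
        vals = np.array([auc_approx_from_db(x) for x in d])
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals >= 0.5)

    def test_negative_distance_rejected(self):
        with pytest.raises(DomainError):
            auc_approx_from_db(-1e-9)

    def test_exact_for_equal_covariance_gaussians(self):
        """For any shared covariance the erf approximation equals
        Phi(d_A / sqrt(2)) to machine precision."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.normal(size=(2, 2))
            cov = a @ a.T + 0.5 * np.eye(2)
            mu1, mu2 = rng.normal(size=2), rng.normal(size=2)
            q1, q2 = Gaussian(mu1, cov), Gaussian(mu2, cov)
            db = bhattacharyya(q1, q2, method="closed_form").distance
            da = np.sqrt((mu2 - mu1) @ np.linalg.solve(cov, mu2 - mu1))
            assert abs(auc_approx_from_db(db) - norm.cdf(da / np.sqrt(2.0))) <= 1e-12


class TestDerivationIdentities:
    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_moment_identity_on_shifted_gaussians(self, k):
        q1 = Gaussian(mean=[0.0], cov=[[1.0]])
        q2 = Gaussian(mean=[0.5], cov=[[1.0]])
        rep = moment_identity_check(q1, q2, k=k, n=100_000, seed=k + 1)
        assert rep.agrees

    def test_moment_identity_k1_matches_closed_form(self):
        """N(0,1) vs N(1,1): both sides of the k=1 identity equal e."""
        q1 = Gaussian(mean=[0.0], cov=[[1.0]])
        q2 = Gaussian(mean=[1.0], cov=[[1.0]])
        rep = moment_identity_check(q1, q2, k=1, n=200_000, seed=2)
        assert rep.lhs == pytest.approx(np.e, abs=3.0 * rep.lhs_std_error)
        assert rep.rhs == pytest.approx(np.e, abs=3.0 * max(rep.rhs_std_error, 1e-6))

    def test_moment_identity_trivial_for_matched_models(self, std_gauss_2d):
        q2 = Gaussian(mean=[0.0, 0.0], cov=np.eye(2))
        rep = moment_identity_check(std_gauss_2d, q2, k=2, n=10_000, seed=0)
        assert rep.lhs == pytest.approx(1.0, abs=1e-12)
        assert rep.rhs == pytest.approx(1.0, abs=1e-12)
        assert rep.agrees

    def test_lambda_density_identity_1d_gaussians(self):
        """N(0,1) vs N(1,1): lambda|H1 ~ N(-1/2,1), lambda|H2 ~ N(+1/2,1);
        the exp-weighted histogram matches within MC tolerance."""
        q1 = Gaussian(mean=[0.0], cov=[[1.0]])
        q2 = Gaussian(mean=[1.0], cov=[[1.0]])
        rep = lambda_density_identity_check(q1, q2, n=100_000, bins=25, seed=8)
        assert rep.passes
        assert rep.max_discrepancy < 0.05

    def test_lambda_density_identity_2d(self, std_gauss_2d, shifted_gauss_2d):
        rep = lambda_density_identity_check(
            std_gauss_2d, shifted_gauss_2d, n=100_000, bins=20, seed=9
        )
        assert rep.passes

    def test_matched_models_point_mass_at_zero(self, std_gauss_2d):
        q2 = Gaussian(mean=[0.0, 0.0], cov=np.eye(2))
        rep = lambda_density_identity_check(std_gauss_2d, q2, n=10_000, bins=10, seed=1)
        assert rep.passes
        assert rep.max_discrepancy < 1e-9
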