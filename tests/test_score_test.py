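import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, kstest

from vcdea.io_norm import Design
from vcdea.score_test import (
    asymptotic_test,
    batch_asymptotic,
    batch_permutation,
    chi2_mixture_pvalue,
    mixture_coefficients,
    permutation_test,
    phipson_smyth_pvalue,
    score_contributions,
    score_statistic,
)
from vcdea.weights import fit_null_models

from conftest import make_gaussian_dataset


def naive_Q(y, mu, sigma, Phi):
    """Brute-force double-loop oracle for Q = q'q."""
    y, mu, sigma, Phi = map(np.asarray, (y, mu, sigma, Phi))
    if Phi.ndim == 1:
        Phi = Phi[:, None]
    n, k = Phi.shape
    Q = 0.0
    for l in range(k):
        q_l = 0.0
        for i in range(n):
            q_l += (y[i] - mu[i]) / sigma[i] * Phi[i, l]
        q_l /= np.sqrt(n)
        Q += q_l**2
    return Q


class TestScoreStatistic:
    def test_zero_residuals(self):
        y = np.array([1.0, 2.0, 3.0])
        q, Q = score_statistic(y, y, np.ones(3), np.array([0.0, 1.0, 2.0]))
        assert Q == 0.0
        np.testing.assert_array_equal(q, [0.0])

    def test_hand_arithmetic(self):
        # residuals (-1.5,-0.5,0.5,1.5), sigma 1, Phi (0,0,1,1): q = 2/2 = 1
        y = np.array([1.0, 2.0, 3.0, 4.0])
        mu = np.full(4, 2.5)
        q, Q = score_statistic(y, mu, np.ones(4), np.array([0.0, 0.0, 1.0, 1.0]))
        assert q[0] == pytest.approx(1.0)
        assert Q == pytest.approx(1.0)

    def test_homogeneity_in_inverse_sigma(self, rng):
        y = rng.normal(size=10)
        mu = np.zeros(10)
        sigma = rng.uniform(0.5, 2.0, 10)
        Phi = rng.normal(size=(10, 2))
        q1, Q1 = score_statistic(y, mu, sigma, Phi)
        q2, Q2 = score_statistic(y, mu, sigma / 2.0, Phi)
        np.testing.assert_allclose(q2, 2.0 * q1)
        assert Q2 == pytest.approx(4.0 * Q1)

    def test_errors(self):
        with pytest.raises(ValueError, match="positive"):
            score_statistic([1.0, 2.0], [0.0, 0.0], [1.0, 0.0], [[1.0], [2.0]])
        with pytest.raises(ValueError, match="sample dimension"):
            score_statistic([1.0, 2.0], [0.0], [1.0, 1.0], [[1.0], [2.0]])

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        k = int(rng.integers(1, 4))
        y = rng.normal(size=n)
        mu = rng.normal(size=n)
        sigma = rng.uniform(0.2, 3.0, size=n)
        Phi = rng.normal(size=(n, k))
        _, Q = score_statistic(y, mu, sigma, Phi)
        assert Q == pytest.approx(naive_Q(y, mu, sigma, Phi), rel=1e-10)

    def test_location_invariance(self, rng):
        y = rng.normal(size=12)
        mu = rng.normal(size=12)
        sigma = rng.uniform(0.5, 2.0, 12)
        Phi = rng.normal(size=(12, 1))
        _, Q1 = score_statistic(y, mu, sigma, Phi)
        _, Q2 = score_statistic(y + 7.3, mu + 7.3, sigma, Phi)
        assert Q2 == pytest.approx(Q1, rel=1e-10)


class TestScoreContributions:
    def test_reproduces_q(self, rng):
        y, mu = rng.normal(size=8), rng.normal(size=8)
        sigma = rng.uniform(0.5, 2.0, 8)
        Phi = rng.normal(size=(8, 3))
        C = score_contributions(y, mu, sigma, Phi)
        q, _ = score_statistic(y, mu, sigma, Phi)
        np.testing.assert_array_equal(C.sum(axis=0) / np.sqrt(8), q)

    def test_unit_phi_gives_standardized_residuals(self, rng):
        y, mu = rng.normal(size=6), rng.normal(size=6)
        sigma = rng.uniform(0.5, 2.0, 6)
        C = score_contributions(y, mu, sigma, np.ones((6, 1)))
        np.testing.assert_allclose(C[:, 0], (y - mu) / sigma)

    def test_sample_permutation_permutes_rows(self, rng):
        y, mu = rng.normal(size=9), rng.normal(size=9)
        sigma = rng.uniform(0.5, 2.0, 9)
        Phi = rng.normal(size=(9, 2))
        perm = rng.permutation(9)
        C = score_contributions(y, mu, sigma, Phi)
        C_perm = score_contributions(y[perm], mu[perm], sigma[perm], Phi[perm])
        np.testing.assert_allclose(C_perm, C[perm])
        q1, _ = score_statistic(y, mu, sigma, Phi)
        q2, _ = score_statistic(y[perm], mu[perm], sigma[perm], Phi[perm])
        np.testing.assert_allclose(q2, q1)


class TestMixtureCoefficients:
    def test_iid_unit_variance(self):
        rng = np.random.default_rng(5)
        n = 20000
        C = rng.normal(size=(n, 1))
        D = np.ones((n, 1))
        a = mixture_coefficients(C, D)
        # Var(sample variance) ~ 2/n for Gaussian: 3 MC SEs
        assert a[0] == pytest.approx(1.0, abs=3 * np.sqrt(2.0 / n))

    def test_zero_contributions(self):
        a = mixture_coefficients(np.zeros((10, 2)), np.ones((10, 1)))
        np.testing.assert_array_equal(a, [0.0, 0.0])

    def test_duplicated_column_rank_deficiency(self, rng):
        c = rng.normal(size=(50, 1))
        C = np.hstack([c, c])
        a = mixture_coefficients(C, np.ones((50, 1)))
        assert a[1] == pytest.approx(0.0, abs=1e-12)
        assert a[0] >= 0

    def test_small_n_warning(self, rng):
        with pytest.warns(UserWarning, match="regularized"):
            mixture_coefficients(rng.normal(size=(2, 3)), np.ones((2, 1)))

    def test_nonnegative(self, rng):
        for _ in range(5):
            C = rng.normal(size=(15, 3))
            a = mixture_coefficients(C, np.ones((15, 1)))
            assert np.all(a >= 0)


class TestChi2MixturePvalue:
    def test_single_chi2_quantile(self):
        # chi2_1 survival oracle at its 0.95 quantile
        assert chi2_mixture_pvalue(3.841459, np.array([1.0])) == pytest.approx(
            chi2.sf(3.841459, 1), rel=1e-6
        )
        assert chi2_mixture_pvalue(3.841459, np.array([1.0])) == pytest.approx(
            0.05, rel=1e-4
        )

    def test_two_equal_terms_chi2_2(self):
        assert chi2_mixture_pvalue(5.991465, np.array([1.0, 1.0])) == pytest.approx(
            chi2.sf(5.991465, 2), rel=1e-6
        )

    def test_equal_coefficients_match_closed_form(self):
        for k in (1, 2, 5):
            for Q in (0.5, 2.0, 10.0):
                c = 1.7
                p = chi2_mixture_pvalue(Q, np.full(k, c))
                assert p == pytest.approx(chi2.sf(Q / c, k), rel=1e-6)

    def test_scale_invariance(self):
        a = np.array([2.0, 0.7, 0.1])
        for c in (0.5, 3.0, 100.0):
            assert chi2_mixture_pvalue(4.0, a) == pytest.approx(
                chi2_mixture_pvalue(c * 4.0, c * a), rel=1e-8
            )

    def test_unequal_mixture_against_monte_carlo(self):
        # independent oracle: direct simulation of sum a_l chi2_1
        a = np.array([3.0, 1.0, 0.5])
        rng = np.random.default_rng(17)
        draws = rng.chisquare(1, size=(400_000, 3)) @ a
        for Q in (2.0, 8.0, 15.0):
            mc = np.mean(draws > Q)
            se = np.sqrt(mc * (1 - mc) / draws.shape[0])
            assert chi2_mixture_pvalue(Q, a) == pytest.approx(mc, abs=4 * se)

    def test_liu_fallback_agrees_with_imhof_in_bulk(self):
        from vcdea.score_test import _liu_pvalue

        # Liu is a moment-matching approximation: coarse agreement only
        a = np.array([2.0, 1.0, 0.3])
        for Q in (1.0, 4.0, 9.0):
            assert _liu_pvalue(Q, a) == pytest.approx(
                chi2_mixture_pvalue(Q, a), abs=0.03
            )

    def test_edge_cases(self):
        assert chi2_mixture_pvalue(0.0, np.array([1.0])) == 1.0
        with pytest.warns(UserWarning, match="zero"):
            assert chi2_mixture_pvalue(1.0, np.array([0.0])) == 0.0
        with pytest.raises(ValueError):
            chi2_mixture_pvalue(-1.0, np.array([1.0]))
        with pytest.raises(ValueError):
            chi2_mixture_pvalue(1.0, np.array([-0.5]))


class TestAsymptoticTest:
    def _design(self, n):
        return Design(
            X=np.empty((n, 0)),
            Phi=np.repeat([0.0, 1.0], n // 2)[:, None],
            sample_ids=[f"s{i}" for i in range(n)],
        )

    def test_fitted_y_gives_p_one(self):
        design = self._design(4)
        res = asymptotic_test(np.full(4, 3.3), design, np.ones(4))
        assert res.pvalue == 1.0
        assert res.Q == pytest.approx(0.0, abs=1e-20)

    def test_deterministic(self, rng):
        design = self._design(20)
        y = rng.normal(size=20)
        r1 = asymptotic_test(y, design, np.ones(20))
        r2 = asymptotic_test(y, design, np.ones(20))
        assert r1.pvalue == r2.pvalue and r1.Q == r2.Q

    def test_null_uniformity_ks(self):
        # calibration claim: p uniform under a standardized Gaussian null
        y, design = make_gaussian_dataset(G=2000, n=100, seed=23)
        fit = fit_null_models(y, design)
        sigma = np.ones_like(y.values)
        _, pvals = batch_asymptotic(fit, sigma, design.Phi)
        assert kstest(pvals, "uniform").statistic < 0.05

    def test_batch_matches_per_gene(self):
        y, design = make_gaussian_dataset(G=30, n=24, seed=9)
        fit = fit_null_models(y, design)
        sigma = np.full_like(y.values, 1.3)
        Q_batch, p_batch = batch_asymptotic(fit, sigma, design.Phi)
        for g in range(0, 30, 7):
            res = asymptotic_test(y.values[g], design, sigma[g])
            assert res.Q == pytest.approx(Q_batch[g], rel=1e-10)
            assert res.pvalue == pytest.approx(p_batch[g], rel=1e-8)

    def test_multi_column_phi(self, rng):
        n = 40
        Phi = np.column_stack([np.repeat([0.0, 1.0], n // 2), rng.normal(size=n)])
        design = Design(X=np.empty((n, 0)), Phi=Phi, sample_ids=[f"s{i}" for i in range(n)])
        res = asymptotic_test(rng.normal(size=n), design, np.ones(n))
        assert res.a.shape == (2,)
        assert 0 < res.pvalue <= 1


class TestPhipsonSmyth:
    def test_formula(self):
        assert phipson_smyth_pvalue(0, 999) == pytest.approx(0.001)
        assert phipson_smyth_pvalue(999, 999) == 1.0

    def test_never_zero_and_monotone(self):
        m = 50
        ps = [phipson_smyth_pvalue(b, m) for b in range(m + 1)]
        assert min(ps) == pytest.approx(1 / (m + 1))
        assert all(p2 > p1 for p1, p2 in zip(ps, ps[1:]))

    def test_close_to_uniform_prior_alternative(self):
        m = 200
        for b in range(0, m + 1, 10):
            alt = (b + 1) / (m + 2)
            assert abs(phipson_smyth_pvalue(b, m) - alt) < 1 / (m + 1)

    def test_errors(self):
        with pytest.raises(ValueError):
            phipson_smyth_pvalue(5, 4)
        with pytest.raises(ValueError):
            phipson_smyth_pvalue(0, 0)


class TestPermutationTest:
    def _design(self, n, with_x=False, seed=0):
        rng = np.random.default_rng(seed)
        return Design(
            X=rng.normal(size=(n, 1)) if with_x else np.empty((n, 0)),
            Phi=np.repeat([0.0, 1.0], n // 2)[:, None],
            sample_ids=[f"s{i}" for i in range(n)],
        )

    def test_fitted_y_gives_p_one(self):
        design = self._design(6)
        res = permutation_test(np.full(6, 2.0), design, np.ones(6), n_perm=99, rng_seed=1)
        assert res.pvalue == 1.0

    def test_seed_contract(self, rng):
        design = self._design(10)
        y = rng.normal(size=10)
        p1 = permutation_test(y, design, np.ones(10), n_perm=200, rng_seed=7).pvalue
        p2 = permutation_test(y, design, np.ones(10), n_perm=200, rng_seed=7).pvalue
        p3 = permutation_test(y, design, np.ones(10), n_perm=200, rng_seed=8).pvalue
        assert p1 == p2
        assert abs(p3 - p1) < 10 / np.sqrt(200)  # O(m^-1/2) wobble

    def test_p_at_least_one_over_m_plus_one(self, rng):
        design = self._design(8)
        y = rng.normal(size=8) + 10 * design.Phi[:, 0]  # huge effect
        res = permutation_test(y, design, np.ones(8), n_perm=100, rng_seed=3)
        assert res.pvalue >= 1 / 101

    def test_validity_small_n(self):
        # conservative-or-exact under an exchangeable null at n=4
        reps, m, hits = 300, 60, 0
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            design = self._design(4)
            y = rng.normal(size=4)
            p = permutation_test(y, design, np.ones(4), n_perm=m, rng_seed=r).pvalue
            hits += p <= 0.05
        # exchangeable null: P(p <= alpha) <= alpha; 3 MC SEs slack
        assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_freedman_lane_with_covariates(self, rng):
        design = self._design(16, with_x=True, seed=4)
        y = rng.normal(size=16) + 0.8 * design.X[:, 0]
        res = permutation_test(y, design, np.ones(16), n_perm=150, rng_seed=5)
        assert 0 < res.pvalue <= 1
        assert res.method == "permutation" and res.n_perm_used == 150

    def test_batch_matches_scheme(self):
        # batch path (shared permutations) has the same observed Q
        y, design = make_gaussian_dataset(G=15, n=12, seed=31)
        fit = fit_null_models(y, design)
        sigma = np.ones_like(y.values)
        Q_batch, p_batch = batch_permutation(
            fit, sigma, design.Phi, has_covariates=False, n_perm=100, seed=2
        )
        for g in range(15):
            res = permutation_test(y.values[g], design, sigma[g], n_perm=100, rng_seed=2)
            assert res.Q == pytest.approx(Q_batch[g], rel=1e-10)
        assert np.all(p_batch >= 1 / 101) and np.all(p_batch <= 1)

    def test_errors(self):
        design = self._design(4)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(np.ones(4), design, np.ones(4), n_perm=0)
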