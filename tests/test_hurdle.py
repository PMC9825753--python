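"""Unit and property tests for the hurdle pmf, normalization and M-step updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import poisson

from phclust import (
    ClusterParams,
    CountMatrix,
    cluster_loglik,
    hurdle_log_pmf,
    update_alpha_mu,
    update_gamma,
    upper_quartile_factors,
)
from phclust.hurdle import _update_alpha_mu_arrays, _Workspace

from conftest import random_instance


class TestUpperQuartileFactors:
    def test_identical_samples_center_to_zero(self):
        counts = np.tile([[4], [0], [9], [2]], (1, 5))
        cm = CountMatrix(counts, np.array(["A"] * 5))
        assert np.allclose(upper_quartile_factors(cm), 0.0)

    def test_two_sample_hand_computation(self):
        # nonzero upper quartiles 4 and 16 -> factors -log 2 and +log 2
        counts = np.array([[4, 16], [4, 16], [4, 16], [0, 0]])
        cm = CountMatrix(counts, np.array(["A", "B"]))
        assert np.allclose(upper_quartile_factors(cm),
                           [-np.log(2), np.log(2)])

    def test_feature_order_invariance(self, tiny_counts, rng):
        s = upper_quartile_factors(tiny_counts)
        perm = rng.permutation(tiny_counts.n_features)
        cm2 = CountMatrix(tiny_counts.counts[perm],
                          tiny_counts.treatment_of_sample)
        assert np.allclose(upper_quartile_factors(cm2), s)

    def test_sums_to_zero(self, tiny_counts):
        assert abs(upper_quartile_factors(tiny_counts).sum()) < 1e-12

    def test_all_zero_sample_raises_with_name(self):
        counts = np.array([[3, 0], [5, 0]])
        cm = CountMatrix(counts, np.array(["A", "B"]), sample_ids=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            upper_quartile_factors(cm)


class TestHurdleLogPmf:
    def test_zero_branch(self):
        assert hurdle_log_pmf(0, 5.0, 0.3) == pytest.approx(np.log(0.7))

    def test_positive_branch_hand_computation(self):
        # n=2, lam=1, q=0.5 -> log(0.5 * e^-1 / (2 (1 - e^-1)))
        expected = np.log(0.5 * np.exp(-1) / (2 * (1 - np.exp(-1))))
        assert hurdle_log_pmf(2, 1.0, 0.5) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("lam,q", [(2.0, 0.6), (0.3, 0.95), (8.0, 0.1),
                                       (1e-4, 0.5), (25.0, 0.99)])
    def test_normalizes_to_one(self, lam, q):
        n = np.arange(0, 201)
        total = np.exp(hurdle_log_pmf(n, lam, q)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 2.0, 7.0])
    def test_matches_poisson_when_gate_is_poisson_positive_prob(self, lam):
        # q = 1 - e^-lam recovers the untruncated Poisson pointwise
        q = 1.0 - np.exp(-lam)
        n = np.arange(0, 40)
        assert np.allclose(hurdle_log_pmf(n, lam, q),
                           poisson.logpmf(n, lam), atol=1e-10)

    def test_boundaries_give_minus_inf(self):
        assert hurdle_log_pmf(3, 2.0, 0.0) == -np.inf
        assert hurdle_log_pmf(0, 2.0, 1.0) == -np.inf

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            hurdle_log_pmf(-1, 1.0, 0.5)
        with pytest.raises(ValueError):
            hurdle_log_pmf(1.5, 1.0, 0.5)


def _naive_cluster_loglik(cm, weights, cluster, alpha_col, s):
    """Term-by-term re-evaluation of the weighted hurdle log-likelihood."""
    total = 0.0
    for g in range(cm.n_features):
        for j in range(cm.n_samples):
            i = cm.treatment_codes[j]
            lam = np.exp(s[j] + alpha_col[g] + cluster.mu[i])
            q = expit(cluster.gamma0[i] + cluster.gamma1[i] * s[j])
            total += weights[g] * hurdle_log_pmf(int(cm.counts[g, j]), lam, q)
    return total


class TestClusterLoglik:
    def _cluster(self, I=2):
        mu = np.linspace(-0.5, 0.5, I)
        mu -= mu.mean()
        return ClusterParams(mu=mu, gamma0=np.full(I, 0.4),
                             gamma1=np.full(I, 0.2), p=0.5)

    def test_zero_weights_give_zero(self, tiny_counts):
        s = upper_quartile_factors(tiny_counts)
        cl = self._cluster()
        val = cluster_loglik(tiny_counts, np.zeros(6), cl, np.zeros(6), s)
        assert val == 0.0

    def test_single_feature_matches_pmf_sum(self, tiny_counts):
        s = upper_quartile_factors(tiny_counts)
        cl = self._cluster()
        w = np.zeros(6)
        w[2] = 1.0
        alpha = np.full(6, 0.8)
        expected = _naive_cluster_loglik(tiny_counts, w, cl, alpha, s)
        assert cluster_loglik(tiny_counts, w, cl, alpha, s) == pytest.approx(
            expected, rel=1e-12)

    def test_matches_naive_on_random_instance(self):
        cm = random_instance(3, G=3, I=2, J=3)
        r = np.random.default_rng(5)
        s = upper_quartile_factors(cm)
        cl = self._cluster()
        w = r.random(3)
        alpha = r.normal(1.0, 0.3, size=3)
        expected = _naive_cluster_loglik(cm, w, cl, alpha, s)
        assert cluster_loglik(cm, w, cl, alpha, s) == pytest.approx(
            expected, rel=1e-10)


class TestUpdateGamma:
    def test_all_positive_treatment_hits_upper_clamp(self):
        cm = random_instance(1, G=8, I=2, J=3, zero_frac=0.0)
        assert (cm.counts > 0).all()
        s = upper_quartile_factors(cm)
        cl = ClusterParams(mu=np.zeros(2), gamma0=np.zeros(2),
                           gamma1=np.zeros(2), p=1.0)
        zp = cm.counts == 0
        w = np.ones(8)
        for _ in range(200):
            cl = update_gamma(zp, w, s, cm.treatment_codes, cl)
        assert np.allclose(cl.gamma0, 12.0)

    def test_constant_s_converges_to_logit_of_positive_fraction(self):
        cm = random_instance(2, G=20, I=1, J=6, zero_frac=0.4)
        s = np.zeros(6)
        r = np.random.default_rng(0)
        w = r.random(20)
        cl = ClusterParams(mu=np.zeros(1), gamma0=np.zeros(1),
                           gamma1=np.zeros(1), p=1.0)
        zp = cm.counts == 0
        for _ in range(300):
            cl = update_gamma(zp, w, s, cm.treatment_codes, cl)
        frac = (w @ (cm.counts > 0)).sum() / (w.sum() * 6)
        assert cl.gamma1[0] == 0.0
        assert cl.gamma0[0] == pytest.approx(logit(frac), abs=1e-6)

    def test_iterated_update_matches_numerical_maximizer(self):
        cm = random_instance(4, G=12, I=2, J=4, zero_frac=0.4)
        s = upper_quartile_factors(cm)
        r = np.random.default_rng(1)
        w = r.random(12)
        zp = cm.counts == 0
        cl = ClusterParams(mu=np.zeros(2), gamma0=np.zeros(2),
                           gamma1=np.zeros(2), p=1.0)
        for _ in range(400):
            cl = update_gamma(zp, w, s, cm.treatment_codes, cl)

        pos = (~zp).astype(float)
        a = w @ pos

        def neg(gs):
            g0, g1 = gs[:2], np.maximum(gs[2:], 0.0)
            eta = g0[cm.treatment_codes] + g1[cm.treatment_codes] * s
            ll = (a * -np.logaddexp(0, -eta)
                  + (w.sum() - a) * -np.logaddexp(0, eta)).sum()
            return -ll

        best = min(
            (minimize(neg, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
             for x0 in ([0.0, 0.0, 0.1, 0.1], [1.0, -1.0, 0.0, 0.0])),
            key=lambda rr: rr.fun,
        )
        ours = -neg(np.concatenate([cl.gamma0, cl.gamma1]))
        assert ours >= -best.fun - 1e-6


class TestUpdateAlphaMu:
    def test_single_treatment_forces_zero_mu(self):
        cm = random_instance(6, G=5, I=1, J=6)
        s = upper_quartile_factors(cm)
        cl = ClusterParams(mu=np.zeros(1), gamma0=np.zeros(1),
                           gamma1=np.zeros(1), p=1.0)
        out, _ = update_alpha_mu(cm, np.ones(5), cl, np.zeros(5), s)
        assert np.allclose(out.mu, 0.0)

    def test_symmetric_counts_give_zero_mu(self):
        counts = np.tile([[6], [3], [9]], (1, 6))
        cm = CountMatrix(counts, np.array(["A"] * 3 + ["B"] * 3))
        s = np.zeros(6)
        cl = ClusterParams(mu=np.zeros(2), gamma0=np.zeros(2),
                           gamma1=np.zeros(2), p=1.0)
        alpha = np.log(np.array([6.0, 3.0, 9.0]))
        for _ in range(100):
            cl, alpha = update_alpha_mu(cm, np.ones(3), cl, alpha, s)
        assert np.allclose(cl.mu, 0.0, atol=1e-8)

    def test_iterated_update_matches_constrained_maximizer(self):
        cm = random_instance(8, G=4, I=2, J=3, zero_frac=0.0)
        s = upper_quartile_factors(cm)
        w = np.ones(4)
        cl = ClusterParams(mu=np.zeros(2), gamma0=np.zeros(2),
                           gamma1=np.zeros(2), p=1.0)
        alpha = np.log(cm.counts.mean(axis=1).astype(float))
        for _ in range(500):
            cl, alpha = update_alpha_mu(cm, w, cl, alpha, s)
        ours = cluster_loglik(cm, w, cl, alpha, s)

        tc = cm.treatment_codes

        def neg(x):
            al, m0 = x[:4], x[4]
            mu = np.array([m0, -m0])  # sum-to-zero parameterization
            lam = np.exp(s[None, :] + al[:, None] + mu[tc][None, :])
            ll = (cm.counts * np.log(lam) - lam
                  - np.log1p(-np.exp(-lam))).sum()
            return -ll

        res = minimize(neg, np.concatenate([alpha, [0.0]]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 20000})
        # gate part is unchanged by (alpha, mu); compare truncated parts via
        # the full weighted likelihood at the oracle optimum
        mu_hat = np.array([res.x[4], -res.x[4]])
        cl_hat = ClusterParams(mu=mu_hat, gamma0=cl.gamma0, gamma1=cl.gamma1)
        oracle = cluster_loglik(cm, w, cl_hat, res.x[:4], s)
        assert ours >= oracle - 1e-5

    @pytest.mark.parametrize("seed", range(6))
    def test_one_step_never_decreases_cluster_loglik(self, seed):
        cm = random_instance(seed + 100, G=10, I=3, J=3)
        s = upper_quartile_factors(cm)
        r = np.random.default_rng(seed)
        w = r.random(10)
        mu = r.normal(0, 0.5, 3)
        mu -= mu.mean()
        cl = ClusterParams(mu=mu, gamma0=r.normal(0, 1, 3),
                           gamma1=r.uniform(0, 0.5, 3), p=1.0)
        alpha = r.normal(1, 0.5, 10)
        before = cluster_loglik(cm, w, cl, alpha, s)
        cl2 = update_gamma(cm.counts == 0, w, s, cm.treatment_codes, cl)
        cl3, alpha3 = update_alpha_mu(cm, w, cl2, alpha, s)
        after = cluster_loglik(cm, w, cl3, alpha3, s)
        assert after >= before - 1e-8

    def test_identifiability_shift_invariance(self):
        cm = random_instance(55, G=6, I=2, J=3)
        ws = _Workspace(cm, upper_quartile_factors(cm))
        r = np.random.default_rng(2)
        w = r.random(6)
        mu = np.array([0.3, -0.3])
        alpha = r.normal(1, 0.3, 6)
        c = 0.7
        mu_a, al_a = _update_alpha_mu_arrays(ws, w, mu.copy(), alpha.copy())
        mu_b, al_b = _update_alpha_mu_arrays(ws, w, mu + c, alpha - c)
        assert np.allclose(mu_a, mu_b, atol=1e-9)
        assert np.allclose(al_a, al_b, atol=1e-9)


@settings(deadline=None, max_examples=25)
@given(lam=st.floats(0.05, 30.0), q=st.floats(0.01, 0.99))
def test_pmf_sums_to_one_property(lam, q):
    n = np.arange(0, 400)
    assert np.exp(hurdle_log_pmf(n, lam, q)).sum() == pytest.approx(1.0, abs=1e-9)
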