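"""Tests for Kendall's-tau seeding and multiple starts."""

import itertools

import numpy as np
import pytest
from scipy.stats import kendalltau

from phclust import (
    CountMatrix,
    multi_start,
    params_from_seeds,
    select_seeds,
    tau_distance_matrix,
)
from phclust.initialization import default_first_seed


def _brute_force_tau_b(x, y):
    """Exhaustive concordant/discordant pair counting with tie correction."""
    num = 0
    tx = ty = 0
    n = len(x)
    for a, b in itertools.combinations(range(n), 2):
        sx = np.sign(x[a] - x[b])
        sy = np.sign(y[a] - y[b])
        num += sx * sy
        tx += sx == 0
        ty += sy == 0
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return num / denom if denom > 0 else np.nan


class TestTauDistanceMatrix:
    def test_self_distance_zero(self, tiny_counts):
        D = tau_distance_matrix(tiny_counts)
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(D, D.T)

    def test_reversed_ranking_distance_two(self):
        counts = np.array([[1, 2, 3, 4, 5], [9, 7, 5, 3, 1]])
        D = tau_distance_matrix(CountMatrix(counts, np.array(["A"] * 5)))
        assert D[0, 1] == pytest.approx(2.0)

    def test_hand_example(self):
        counts = np.array([[1, 2, 3, 4], [1, 3, 2, 4]])
        D = tau_distance_matrix(CountMatrix(counts, np.array(["A"] * 4)))
        expected = 1.0 - _brute_force_tau_b(counts[0], counts[1])
        assert D[0, 1] == pytest.approx(expected)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(8)
        X = rng.poisson(2.0, size=(12, 8))  # plenty of tied zeros
        D = tau_distance_matrix(CountMatrix(X, np.array(["A"] * 8)))
        for g, h in itertools.combinations(range(12), 2):
            ref = _brute_force_tau_b(X[g], X[h])
            if np.isnan(ref):
                assert D[g, h] == 1.0
            else:
                assert D[g, h] == pytest.approx(1.0 - ref, abs=1e-12)

    def test_agrees_with_scipy_tau_b(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(3.0, size=(10, 8))
        X[0] = 5  # constant feature
        D = tau_distance_matrix(CountMatrix(X, np.array(["A"] * 8)))
        for g, h in itertools.combinations(range(1, 10), 2):
            tau = kendalltau(X[g], X[h], variant="b").statistic
            assert D[g, h] == pytest.approx(1.0 - tau, abs=1e-12)
        assert np.all(D[0, 1:] == 1.0)


class TestSelectSeeds:
    def test_all_features_when_k_equals_g(self):
        D = tau_distance_matrix(np.random.default_rng(0).poisson(4, (5, 6)))
        seeds = select_seeds(D, 5, first_seed=2)
        assert sorted(seeds) == list(range(5))

    def test_maximin_hand_example(self):
        D = np.array([[0.0, 0.1, 1.9],
                      [0.1, 0.0, 1.9],
                      [1.9, 1.9, 0.0]])
        assert list(select_seeds(D, 2, first_seed=0)) == [0, 2]

    def test_k_one_returns_anchor(self):
        D = np.zeros((4, 4))
        assert list(select_seeds(D, 1, first_seed=3)) == [3]

    def test_too_many_seeds_raises(self):
        with pytest.raises(ValueError):
            select_seeds(np.zeros((3, 3)), 4, first_seed=0)

    def test_deterministic(self, tiny_counts):
        D = tau_distance_matrix(tiny_counts)
        a = select_seeds(D, 3, first_seed=1)
        b = select_seeds(D, 3, first_seed=1)
        assert np.array_equal(a, b)

    def test_default_anchor_is_highest_total_feature(self, tiny_counts):
        totals = tiny_counts.counts.sum(axis=1)
        assert default_first_seed(tiny_counts) == int(np.argmax(totals))


class TestParamsFromSeeds:
    def test_uniform_mixing(self, tiny_counts):
        params = params_from_seeds(tiny_counts, [0, 2, 4])
        assert np.allclose(params.p, 1.0 / 3.0)
        assert np.allclose(params.mu.sum(axis=1), 0.0, atol=1e-8)
        assert np.all(params.gamma1 >= 0)

    def test_symmetric_seed_gives_zero_mu(self):
        counts = np.tile([[7], [2]], (1, 6))
        cm = CountMatrix(counts, np.array(["A"] * 3 + ["B"] * 3))
        params = params_from_seeds(cm, [0], s=np.zeros(6))
        assert np.allclose(params.mu, 0.0, atol=1e-9)

    def test_single_seed_fit_matches_numerical_maximizer(self):
        # two treatments, all-positive counts: the seed's centered treatment
        # effects equal the difference of per-treatment truncated-Poisson
        # offset MLEs found by a 1-D numerical oracle
        from scipy.optimize import minimize_scalar
        from phclust.hurdle import _fit_single_feature, _log1mexp, _Workspace

        counts = np.array([[4, 7, 5, 12, 15, 9]])
        cm = CountMatrix(counts, np.array(["A", "A", "A", "B", "B", "B"]))
        s = np.array([-0.1, 0.0, 0.1, -0.2, 0.1, 0.1])
        s -= s.mean()
        ws = _Workspace(cm, s)
        mu, g0, g1 = _fit_single_feature(ws, 0)
        # gate: all positive -> intercepts at the +12 clamp
        assert np.allclose(g0, 12.0)

        xi = []
        for cols in (slice(0, 3), slice(3, 6)):
            cnt = counts[0, cols].astype(float)
            sv = s[cols]

            def neg(x):
                lam = np.exp(sv + x)
                return -(cnt * (sv + x) - lam - _log1mexp(lam)).sum()

            xi.append(minimize_scalar(neg, bounds=(-5, 10), method="bounded",
                                      options={"xatol": 1e-10}).x)
        expected = np.array(xi) - np.mean(xi)
        assert np.allclose(mu, expected, atol=1e-5)

    def test_missing_treatment_positive_counts_zeroes_mu(self):
        counts = np.array([[3, 4, 0, 0], [1, 1, 2, 2]])
        cm = CountMatrix(counts, np.array(["A", "A", "B", "B"]))
        params = params_from_seeds(cm, [0], s=np.zeros(4))
        assert params.mu[0, 1] == 0.0

    def test_duplicate_seeds_rejected(self, tiny_counts):
        with pytest.raises(ValueError):
            params_from_seeds(tiny_counts, [1, 1])


class TestMultiStart:
    def test_single_start_is_deterministic_run(self, default_small_dataset):
        cm = default_small_dataset.counts
        a = multi_start(cm, 3, n_starts=1, seed=0)
        b = multi_start(cm, 3, n_starts=1, seed=99)  # seed only affects starts >= 2
        assert a.loglik == b.loglik
        assert np.array_equal(a.assignments, b.assignments)

    def test_returns_best_of_starts(self, default_small_dataset):
        cm = default_small_dataset.counts
        res = multi_start(cm, 3, n_starts=4, seed=1)
        logliks = [st["loglik"] for st in res.extra["starts"]]
        assert res.loglik == pytest.approx(max(logliks))

    def test_invalid_args(self, default_small_dataset):
        cm = default_small_dataset.counts
        with pytest.raises(ValueError):
            multi_start(cm, 2, n_starts=0)
        with pytest.raises(ValueError):
            multi_start(cm, 2, method="kmeans")
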