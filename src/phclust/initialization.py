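"""Kendall's-tau seeding and multiple-starts orchestration.

EM results for mixtures depend strongly on the starting point.  The seeding
used here picks K features that are far apart under the distance
``1 - tau_b``, where ``tau_b`` is the tie-corrected Kendall rank correlation
of two features' count vectors (microbiome vectors are tie-heavy because of
zeros, so the tie correction matters).  Single-feature hurdle MLEs of the
selected seeds become the starting cluster parameters; running several such
starts and keeping the highest-likelihood fit guards against local maxima.
"""

from __future__ import annotations

import logging

import numpy as np

from .em import ClusteringResult, run_em
from .hurdle import (
    CountMatrix,
    HurdleParams,
    _fit_single_feature,
    _Workspace,
    upper_quartile_factors,
)
from .sa import AnnealSchedule, run_sa

logger = logging.getLogger(__name__)


def tau_distance_matrix(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Pairwise ``1 - tau_b`` distances between feature count vectors.

    Computed exactly from all sample pairs: the tau_b numerator is the sum
    of products of pairwise difference signs, and the tie correction removes
    tied sample pairs from each feature's denominator.  Constant features
    (all ranks tied) have undefined tau; their distance is set to the
    uninformative value 1.
    """
    X = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    G, N = X.shape
    if G < 2:
        raise ValueError("need at least two features for a distance matrix")
    j1, j2 = np.triu_indices(N, k=1)
    S = np.sign(X[:, j1].astype(float) - X[:, j2].astype(float))
    num = S @ S.T
    n_pairs = j1.size
    untied = n_pairs - (S == 0).sum(axis=1)
    const = untied == 0
    scale = np.sqrt(np.maximum(untied, 1).astype(float))
    tau = num / np.outer(scale, scale)
    D = 1.0 - tau
    if const.any():
        logger.warning("%d constant feature(s); their tau distances set to 1",
                       int(const.sum()))
        D[const, :] = 1.0
        D[:, const] = 1.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def default_first_seed(counts: CountMatrix) -> int:
    """Deterministic anchor for start 1: the feature with the largest total."""
    return int(np.argmax(counts.counts.sum(axis=1)))


def select_seeds(D: np.ndarray, K: int, first_seed: int) -> np.ndarray:
    """Greedy maximin selection of K well-separated features.

    Starting from ``first_seed``, each subsequent seed maximizes its minimum
    distance to the seeds already chosen; ties break to the lowest index.
    """
    D = np.asarray(D)
    G = D.shape[0]
    if K > G:
        raise ValueError(f"cannot select {K} seeds from {G} features")
    seeds = [int(first_seed)]
    mind = D[first_seed].copy()
    mind[first_seed] = -np.inf
    while len(seeds) < K:
        nxt = int(np.argmax(mind))
        seeds.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -np.inf
    return np.asarray(seeds)


def params_from_seeds(counts: CountMatrix, seeds, s: np.ndarray | None = None,
                      variant: str = "full") -> HurdleParams:
    """Starting parameters from single-feature MLEs of the seed features.

    Each seed contributes its own fitted treatment effects (centered; a
    treatment without positive counts starts at 0) and logistic gate; every
    feature's alpha starts from its own log mean positive count, and the
    mixing proportions start uniform at 1/K.
    """
    seeds = np.asarray(seeds, dtype=int)
    if len(set(seeds.tolist())) != seeds.size:
        raise ValueError("seed features must be distinct")
    if s is None:
        s = upper_quartile_factors(counts)
    ws = _Workspace(counts, s)
    K = seeds.size
    I = ws.I
    mu = np.zeros((K, I))
    g0 = np.zeros((K, I))
    g1 = np.zeros((K, I))
    for k, g in enumerate(seeds):
        mu[k], g0[k], g1[k] = _fit_single_feature(ws, int(g))
    alpha = np.tile(ws.log_mean_pos[:, None], (1, K))
    if variant == "reduced":
        alpha = np.tile(ws.log_mean_pos[seeds][None, :], (ws.G, 1))
    return HurdleParams(
        p=np.full(K, 1.0 / K), mu=mu, gamma0=g0, gamma1=g1,
        alpha=alpha, s=np.asarray(s, dtype=float), variant=variant,
    )


def multi_start(counts: CountMatrix, K: int, n_starts: int = 5,
                method: str = "em", seed: int | None = None,
                tol: float = 1e-6, max_iter: int = 200,
                schedule: AnnealSchedule | None = None,
                s: np.ndarray | None = None,
                D: np.ndarray | None = None) -> ClusteringResult:
    """Run the clustering from several seedings; keep the best likelihood.

    Start 1 anchors deterministically at the highest-count feature; starts
    2..n anchor at random features.  The returned result carries the
    per-start anchors and log-likelihoods in ``extra["starts"]``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if method not in ("em", "sa"):
        raise ValueError("method must be 'em' or 'sa'")
    if s is None:
        s = upper_quartile_factors(counts)
    if D is None:
        D = tau_distance_matrix(counts)
    children = np.random.SeedSequence(seed).spawn(n_starts)
    anchor0 = default_first_seed(counts)
    best = None
    starts_info = []
    for r in range(n_starts):
        rng = np.random.default_rng(children[r])
        anchor = anchor0 if r == 0 else int(rng.integers(counts.n_features))
        seeds = select_seeds(D, K, anchor)
        init = params_from_seeds(counts, seeds, s=s)
        if method == "em":
            res = run_em(counts, K=K, init=init, tol=tol, max_iter=max_iter)
        else:
            res = run_sa(counts, K=K, init=init, schedule=schedule, tol=tol,
                         max_iter=max_iter, rng=rng)
        starts_info.append({"start": r, "anchor": int(anchor),
                            "loglik": res.loglik})
        logger.debug("start %d anchor %d loglik %.4f", r, anchor, res.loglik)
        if best is None or res.loglik > best.loglik:
            best = res
    best.extra["starts"] = starts_info
    return best
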