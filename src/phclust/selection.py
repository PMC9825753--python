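"""Choosing the number of clusters.

The primary procedure is hybrid hierarchical merging: fit a deliberately
large mixture (``k_max``), then repeatedly merge the pair of clusters whose
pooling costs the least likelihood, stopping the first time a likelihood
ratio test rejects the merged (restricted) model.  The test statistic
``2 * (loglik_K - loglik_{K-1})`` is referred to a chi-square whose degrees
of freedom count every parameter eliminated by the merge: ``(I - 1)``
treatment effects, ``2 I`` logistic gate parameters, one mixing proportion,
and — in the full model variant — one alpha per active feature, since a
K-cluster mixture carries ``G x K`` feature abundances while the merged
model carries ``G x (K - 1)``.  The alpha block dominates the df and puts
the rejection threshold on the same scale as the real likelihood gain of an
extra component; ``df`` is exposed as a knob for sensitivity checks (e.g.
the cluster-level-only count).

AIC/BIC baselines over separate fits at K = 1..k_max are provided for
comparison; they penalize the ``G x K`` alpha matrix heavily and are known
to underestimate K on data of this kind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .em import ClusteringResult, _log_density_all, _posterior_from_logf, run_em
from .hurdle import (
    CountMatrix,
    HurdleParams,
    _feature_logf,
    _update_alpha_mu_arrays,
    _update_gamma_arrays,
    _Workspace,
)
from .initialization import multi_start

logger = logging.getLogger(__name__)


@dataclass
class MergeStep:
    """One accepted (or finally rejected) merge along the path."""

    k_before: int
    k_after: int
    pair: tuple[int, int]
    loglik_before: float
    loglik_after: float
    statistic: float
    df: int
    pvalue: float
    accepted: bool


@dataclass
class ChooseKResult:
    k_selected: int
    result: ClusteringResult
    path: list[MergeStep] = field(default_factory=list)


def default_lrt_df(n_treatments: int, n_features_active: int = 0) -> int:
    """Parameters removed by one merge.

    Cluster-level: ``I - 1`` treatment effects, ``2 I`` gate parameters and
    one mixing proportion; plus one alpha per active feature in the full
    variant (pass ``n_features_active=0`` for the cluster-level-only count
    or the reduced variant's single shared alpha via ``1``).
    """
    return (n_treatments - 1) + 2 * n_treatments + 1 + n_features_active


def lrt_stop(loglik_full: float, loglik_merged: float, df: int,
             alpha: float = 0.05):
    """Likelihood-ratio decision on one merge.

    Returns ``(stop, statistic, pvalue)``; ``stop`` is True when the merge
    is rejected (p < alpha), i.e. the restricted model no longer fits.
    """
    if loglik_full < loglik_merged - 1e-6:
        raise ValueError("full-model log-likelihood below merged model's")
    stat = max(2.0 * (loglik_full - loglik_merged), 0.0)
    pvalue = float(chi2.sf(stat, df))
    return stat > 0 and pvalue < alpha, stat, pvalue


def _merge_candidate(ws, params, Z, logf, a, b, n_refine=2):
    """Quickly refit the pooled cluster (a, b); return candidate pieces."""
    pa, pb = params.p[a], params.p[b]
    pm = pa + pb
    wa = pa / pm if pm > 0 else 0.5
    w = Z[:, a] + Z[:, b]
    mu_m = wa * params.mu[a] + (1 - wa) * params.mu[b]
    mu_m = mu_m - mu_m.mean()
    g0_m = wa * params.gamma0[a] + (1 - wa) * params.gamma0[b]
    g1_m = wa * params.gamma1[a] + (1 - wa) * params.gamma1[b]
    za, zb = Z[:, a], Z[:, b]
    tot = za + zb
    alpha_m = np.where(
        tot > 1e-12,
        (za * params.alpha[:, a] + zb * params.alpha[:, b]) / np.maximum(tot, 1e-12),
        0.5 * (params.alpha[:, a] + params.alpha[:, b]),
    )
    for _ in range(n_refine):
        g0_m, g1_m = _update_gamma_arrays(ws, w, g0_m, g1_m)
        mu_m, alpha_m = _update_alpha_mu_arrays(ws, w, mu_m, alpha_m,
                                                params.variant)
    logf_m = _feature_logf(ws, g0_m, g1_m, mu_m, alpha_m)
    keep = [c for c in range(params.n_clusters) if c not in (a, b)]
    with np.errstate(divide="ignore"):
        lp = np.column_stack([
            logf[:, keep] + np.log(params.p[keep])[None, :],
            (logf_m + np.log(pm))[:, None],
        ])
    m = lp.max(axis=1, keepdims=True)
    ll = float((np.log(np.exp(lp - m).sum(axis=1)) + m[:, 0]).sum())
    return ll, (mu_m, g0_m, g1_m, alpha_m, pm, keep)


def merge_once(counts: CountMatrix, result: ClusteringResult,
               polish_iter: int = 20, tol: float = 1e-6):
    """Merge the cheapest cluster pair and polish with a short EM.

    Every pair is scored by the total mixture log-likelihood after pooling
    the pair's posteriors and quickly refitting the pooled cluster; the best
    pair's merged model is then polished by at most ``polish_iter`` EM
    iterations.  Returns ``(merged_result, pair, delta_loglik)`` with
    ``delta_loglik >= 0`` the likelihood lost by the merge.
    """
    params = result.params
    K = params.n_clusters
    if K < 2:
        raise ValueError("need at least two clusters to merge")
    ws = _Workspace(counts, params.s)
    logf = _log_density_all(ws, params)
    Z, L0 = _posterior_from_logf(logf, params.p)
    best_ll = -np.inf
    best = None
    for a in range(K):
        for b in range(a + 1, K):
            ll, pieces = _merge_candidate(ws, params, Z, logf, a, b)
            if ll > best_ll:
                best_ll = ll
                best = (a, b, pieces)
    a, b, (mu_m, g0_m, g1_m, alpha_m, pm, keep) = best
    merged = HurdleParams(
        p=np.append(params.p[keep], pm),
        mu=np.vstack([params.mu[keep], mu_m[None, :]]),
        gamma0=np.vstack([params.gamma0[keep], g0_m[None, :]]),
        gamma1=np.vstack([params.gamma1[keep], g1_m[None, :]]),
        alpha=np.column_stack([params.alpha[:, keep], alpha_m]),
        s=params.s.copy(),
        variant=params.variant,
    )
    merged.p = merged.p / merged.p.sum()
    polished = run_em(counts, init=merged, tol=tol, max_iter=polish_iter)
    delta = max(L0 - polished.loglik, 0.0)
    return polished, (a, b), delta


def choose_k(counts: CountMatrix, k_max: int = 15, alpha: float = 0.05,
             starts: int = 5, seed: int | None = None, method: str = "em",
             tol: float = 1e-6, max_iter: int = 200, df: int | None = None,
             polish_iter: int = 20,
             initial: ClusteringResult | None = None) -> ChooseKResult:
    """Hybrid selection of the number of clusters.

    Fits ``k_max`` clusters with multiple starts, merges downward, and stops
    at the first likelihood-ratio rejection; the selected K is the model
    before that merge.  If no merge is ever rejected the selection is K=1.
    ``initial`` lets the caller reuse an existing ``k_max`` fit.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if df is None:
        n_active = int((counts.counts > 0).any(axis=1).sum())
        df = default_lrt_df(counts.n_treatments, n_active)
    fit = initial
    if fit is None:
        fit = multi_start(counts, k_max, n_starts=starts, method=method,
                          seed=seed, tol=tol, max_iter=max_iter)
    path: list[MergeStep] = []
    current = fit
    while current.n_clusters >= 2:
        merged, pair, delta = merge_once(counts, current,
                                         polish_iter=polish_iter, tol=tol)
        # the polished merge may even beat the larger model's local optimum;
        # such a merge costs nothing, so the statistic is clipped at zero
        stop, stat, pvalue = lrt_stop(current.loglik,
                                      min(merged.loglik, current.loglik),
                                      df, alpha)
        path.append(MergeStep(
            k_before=current.n_clusters, k_after=merged.n_clusters, pair=pair,
            loglik_before=current.loglik, loglik_after=merged.loglik,
            statistic=stat, df=df, pvalue=pvalue, accepted=not stop,
        ))
        if stop:
            logger.info("merge %s rejected (stat %.2f, p %.3g); K = %d",
                        pair, stat, pvalue, current.n_clusters)
            return ChooseKResult(current.n_clusters, current, path)
        current = merged
    return ChooseKResult(current.n_clusters, current, path)


def count_parameters(result: ClusteringResult, counts: CountMatrix) -> int:
    """Free parameters of a fitted mixture.

    Per cluster: ``I - 1`` treatment effects and ``2 I`` gate parameters;
    ``K - 1`` free mixing proportions; one alpha per (active feature,
    cluster) in the full variant (features without positive counts have no
    identified alpha), or one per cluster in the reduced variant.
    """
    params = result.params
    K = params.n_clusters
    I = params.n_treatments
    if params.variant == "reduced":
        n_alpha = K
    else:
        n_active = int((counts.counts > 0).any(axis=1).sum())
        n_alpha = n_active * K
    return K * ((I - 1) + 2 * I) + (K - 1) + n_alpha


def aic_bic(result: ClusteringResult, counts: CountMatrix,
            bic_n: str = "features"):
    """(AIC, BIC) for a converged fit.

    ``AIC = -2 loglik + 2 npar``; ``BIC = -2 loglik + log(n) npar`` with
    ``n = G`` (features, the mixture's independent units) by default or
    ``n = G * N`` when ``bic_n="cells"``.
    """
    npar = count_parameters(result, counts)
    ll = result.loglik
    if bic_n == "features":
        n = counts.n_features
    elif bic_n == "cells":
        n = counts.n_features * counts.n_samples
    else:
        raise ValueError("bic_n must be 'features' or 'cells'")
    return -2.0 * ll + 2.0 * npar, -2.0 * ll + np.log(n) * npar


def select_k_by_ic(fits: dict[int, ClusteringResult], counts: CountMatrix,
                   criterion: str = "aic", bic_n: str = "features") -> int:
    """K minimizing an information criterion over pre-computed fits."""
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    scores = {}
    for k, fit in fits.items():
        a, b = aic_bic(fit, counts, bic_n=bic_n)
        scores[k] = a if criterion == "aic" else b
    return min(sorted(scores), key=lambda k: scores[k])
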