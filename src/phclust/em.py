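"""EM algorithm for the Poisson hurdle mixture.

The E-step computes posterior membership probabilities in log space; the
M-step combines the closed-form mixing-proportion update with the guarded
one-step coordinate-descent updates of :mod:`phclust.hurdle`.  Because every
M-step block is ascent-guarded, the algorithm is a generalized EM and the
total mixture log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hurdle import (
    CountMatrix,
    HurdleParams,
    _feature_logf,
    _fit_single_feature,
    _update_alpha_mu_arrays,
    _update_gamma_arrays,
    _Workspace,
)

logger = logging.getLogger(__name__)

EMPTY_CLUSTER_TOL = 1e-8


@dataclass
class ClusteringResult:
    """Outcome of one mixture fit.

    ``assignments`` are the row-argmax of ``posterior`` (ties broken by the
    lowest cluster index); ``loglik_trace`` holds the total mixture
    log-likelihood after initialization and after each M-step and is
    non-decreasing up to numerical slack (except across a rare empty-cluster
    re-seed, recorded in ``n_reseeds``).
    """

    assignments: np.ndarray
    params: HurdleParams
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    posterior: np.ndarray
    method: str = "em"
    n_reseeds: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_clusters(self) -> int:
        return self.params.n_clusters


def _log_density_all(ws: _Workspace, params: HurdleParams) -> np.ndarray:
    """G x K matrix of per-feature log hurdle densities."""
    K = params.n_clusters
    out = np.empty((ws.G, K))
    for k in range(K):
        out[:, k] = _feature_logf(ws, params.gamma0[k], params.gamma1[k],
                                  params.mu[k], params.alpha[:, k])
    return out


def _posterior_from_logf(logf: np.ndarray, p: np.ndarray):
    """Row-normalized posteriors and the total mixture log-likelihood."""
    with np.errstate(divide="ignore"):
        lp = logf + np.log(p)[None, :]
    m = lp.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError(
            "a feature has zero density under every cluster; "
            "cannot normalize posteriors"
        )
    w = np.exp(lp - m)
    tot = w.sum(axis=1, keepdims=True)
    Z = w / tot
    ll = float((np.log(tot[:, 0]) + m[:, 0]).sum())
    return Z, ll


def e_step(counts: CountMatrix, params: HurdleParams) -> np.ndarray:
    """Posterior membership probabilities Z_gk, rows summing to 1."""
    ws = _Workspace(counts, params.s)
    logf = _log_density_all(ws, params)
    return _posterior_from_logf(logf, params.p)[0]


def total_loglik(counts: CountMatrix, params: HurdleParams) -> float:
    """Total mixture log-likelihood sum_g log sum_k p_k f(N_g | theta_k)."""
    ws = _Workspace(counts, params.s)
    logf = _log_density_all(ws, params)
    return _posterior_from_logf(logf, params.p)[1]


def _m_step(ws: _Workspace, Z: np.ndarray, params: HurdleParams) -> HurdleParams:
    K = Z.shape[1]
    new = params.copy()
    new.p = Z.mean(axis=0)
    for k in range(K):
        w = Z[:, k]
        new.gamma0[k], new.gamma1[k] = _update_gamma_arrays(
            ws, w, params.gamma0[k], params.gamma1[k]
        )
        mu_k, alpha_k = _update_alpha_mu_arrays(
            ws, w, params.mu[k].copy(), params.alpha[:, k].copy(), params.variant
        )
        new.mu[k] = mu_k
        new.alpha[:, k] = alpha_k
    return new


def m_step(counts: CountMatrix, Z: np.ndarray, params: HurdleParams) -> HurdleParams:
    """One M-step: exact p_k update plus guarded one-step parameter updates."""
    Z = np.asarray(Z, dtype=float)
    ws = _Workspace(counts, params.s)
    return _m_step(ws, Z, params)


def _reseed_cluster(ws: _Workspace, params: HurdleParams, Z: np.ndarray,
                    k: int) -> HurdleParams:
    """Re-seed an emptied cluster from the worst-explained feature."""
    g_star = int(np.argmin(Z.max(axis=1)))
    mu, g0, g1 = _fit_single_feature(ws, g_star)
    params = params.copy()
    params.mu[k] = mu
    params.gamma0[k] = g0
    params.gamma1[k] = g1
    params.alpha[:, k] = ws.log_mean_pos
    params.p[k] = 1.0 / ws.G
    params.p = params.p / params.p.sum()
    logger.info("re-seeded empty cluster %d from feature %d", k, g_star)
    return params


def run_em(counts: CountMatrix, K: int | None = None,
           init: HurdleParams | None = None, tol: float = 1e-6,
           max_iter: int = 200) -> ClusteringResult:
    """Iterate E- and M-steps until the relative log-likelihood change is small.

    Convergence: ``|delta loglik| / (|loglik| + 1) < tol`` (default 1e-6) or
    ``max_iter`` (default 200) iterations.  Emptied clusters (posterior mass
    below 1e-8) are re-seeded from the feature with the lowest maximum
    posterior rather than aborting.
    """
    if init is None:
        raise ValueError("run_em requires initial parameters "
                         "(see phclust.initialization)")
    if K is not None and K != init.n_clusters:
        raise ValueError("K does not match the initial parameters")
    params = init.copy()
    ws = _Workspace(counts, params.s)
    logf = _log_density_all(ws, params)
    Z, ll = _posterior_from_logf(logf, params.p)
    trace = [ll]
    converged = False
    n_reseeds = 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        empty = np.where(Z.sum(axis=0) < EMPTY_CLUSTER_TOL)[0]
        for k in empty:
            params = _reseed_cluster(ws, params, Z, int(k))
            n_reseeds += 1
        if empty.size:
            logf = _log_density_all(ws, params)
            Z, ll = _posterior_from_logf(logf, params.p)
        params = _m_step(ws, Z, params)
        logf = _log_density_all(ws, params)
        Z, ll_new = _posterior_from_logf(logf, params.p)
        trace.append(ll_new)
        logger.debug("EM iter %d loglik %.6f", n_iter, ll_new)
        if abs(ll_new - ll) / (abs(ll_new) + 1.0) < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    assignments = np.argmax(Z, axis=1)
    return ClusteringResult(
        assignments=assignments,
        params=params,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
        posterior=Z,
        method="em",
        n_reseeds=n_reseeds,
    )
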