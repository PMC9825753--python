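"""Simulated-annealing variant of the EM clustering algorithm.

Instead of soft posteriors, each iteration draws a hard one-hot assignment
per feature from a *tempered* posterior ``(p_k f)^(1/t)`` and runs the usual
M-step on the indicator matrix.  The temperature cools geometrically,
``t(m+1) = c * t(m)`` (recommended ``t0 = 2``, ``c = 0.9``); high
temperatures flatten the posterior and inject randomness that helps escape
local maxima.  Once the temperature drops below ``t_min`` the run finishes
with plain EM iterations, so the reported endpoint is a deterministic EM
fixed point refined from the annealed state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .em import ClusteringResult, _log_density_all, _m_step, _posterior_from_logf
from .hurdle import CountMatrix, HurdleParams, _Workspace

logger = logging.getLogger(__name__)


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule: t(m) = t0 * c**m, EM tail below t_min."""

    t0: float = 2.0
    c: float = 0.9
    t_min: float = 0.01

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if not 0.0 < self.c < 1.0:
            raise ValueError("cooling rate c must lie in (0, 1)")
        if self.t_min <= 0:
            raise ValueError("t_min must be positive")


def _tempered_from_logf(logf: np.ndarray, p: np.ndarray, t: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lp = (logf + np.log(p)[None, :]) / t
    m = lp.max(axis=1, keepdims=True)
    w = np.exp(lp - m)
    return w / w.sum(axis=1, keepdims=True)


def tempered_posterior(counts: CountMatrix, params: HurdleParams,
                       t: float) -> np.ndarray:
    """Posterior rows proportional to ``(p_k f)^(1/t)``; t=1 is the E-step."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    ws = _Workspace(counts, params.s)
    logf = _log_density_all(ws, params)
    return _tempered_from_logf(logf, params.p, t)


def sa_assign(ztilde: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a one-hot indicator row per feature from multinomial(Z-tilde)."""
    Z = np.asarray(ztilde, dtype=float)
    cum = np.cumsum(Z, axis=1)
    u = rng.random((Z.shape[0], 1)) * cum[:, -1:]
    idx = (u > cum).sum(axis=1)
    out = np.zeros_like(Z)
    out[np.arange(Z.shape[0]), idx] = 1.0
    return out


def run_sa(counts: CountMatrix, K: int | None = None,
           init: HurdleParams | None = None,
           schedule: AnnealSchedule | None = None, tol: float = 1e-6,
           max_iter: int = 200,
           rng: np.random.Generator | int | None = None) -> ClusteringResult:
    """Annealed clustering: tempered draw -> M-step, then an EM tail.

    The SA phase runs while ``t >= t_min`` (at most ``max_iter`` draws); the
    EM tail then iterates to the same convergence rule as
    :func:`phclust.em.run_em`.  All randomness flows through ``rng``, so a
    fixed seed reproduces the trajectory bit for bit.
    """
    if init is None:
        raise ValueError("run_sa requires initial parameters")
    if K is not None and K != init.n_clusters:
        raise ValueError("K does not match the initial parameters")
    if schedule is None:
        schedule = AnnealSchedule()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    params = init.copy()
    ws = _Workspace(counts, params.s)
    logf = _log_density_all(ws, params)
    _, ll = _posterior_from_logf(logf, params.p)
    trace = [ll]
    t = schedule.t0
    n_sa = 0
    while t >= schedule.t_min and n_sa < max_iter:
        ztilde = _tempered_from_logf(logf, params.p, t)
        ind = sa_assign(ztilde, rng)
        # guard against annealing emptying a component for good: move the
        # feature fondest of an emptied cluster into it (rows stay one-hot)
        for col in np.where(ind.sum(axis=0) == 0)[0]:
            g = int(np.argmax(ztilde[:, col]))
            ind[g, :] = 0.0
            ind[g, col] = 1.0
        params = _m_step(ws, ind, params)
        logf = _log_density_all(ws, params)
        _, ll = _posterior_from_logf(logf, params.p)
        trace.append(ll)
        logger.debug("SA iter %d t=%.4f loglik %.6f", n_sa, t, ll)
        t *= schedule.c
        n_sa += 1
    switch_loglik = trace[-1]
    Z, ll = _posterior_from_logf(logf, params.p)
    converged = False
    n_em = 0
    for n_em in range(1, max_iter + 1):
        params = _m_step(ws, Z, params)
        logf = _log_density_all(ws, params)
        Z, ll_new = _posterior_from_logf(logf, params.p)
        trace.append(ll_new)
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
        n_iter=n_sa + n_em,
        posterior=Z,
        method="sa",
        extra={"n_sa_iter": n_sa, "switch_loglik": switch_loglik},
    )
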