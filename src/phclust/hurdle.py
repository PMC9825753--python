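"""Poisson hurdle probability model for microbiome count matrices.

Each count ``N_gij`` (feature *g*, treatment *i*, replicate *j*) is modelled
in two parts: a Bernoulli "gate" with positive-probability
``q_kij = expit(gamma0_ki + gamma1_ki * s_ij)`` and, conditional on being
positive, a zero-truncated Poisson with rate
``lambda_kgij = exp(s_ij + alpha_gk + mu_ki)``.  Here ``s_ij`` is a fixed
per-sample sequencing-depth offset (log upper-quartile estimator),
``alpha_gk`` the feature's log geometric-mean abundance under cluster *k*
and ``mu_ki`` the cluster's treatment effect, constrained to
``sum_i mu_ki = 0`` for identifiability.  ``gamma1_ki >= 0`` because deeper
samples tend to have more positive counts.

This module provides the probability computations plus the guarded one-step
Newton (coordinate-descent) updates used inside the M-step of the EM
clustering algorithm.  Every update is step-halved so that the weighted
per-cluster log-likelihood never decreases, which makes the surrounding EM a
generalized EM with a monotone total likelihood.

Zero cells contribute to the likelihood only through the gate, so all
truncated-Poisson arithmetic runs on a flattened array of the matrix's
positive cells with per-feature / per-treatment segment sums — the count
matrices this package targets are mostly zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

#: clamp for the logistic intercept; keeps q away from exact 0/1 when a
#: (cluster, treatment) cell is all-zero or all-positive
GAMMA0_BOUND = 12.0
#: clamp for log-scale abundance parameters (lambda stays in a sane range)
ALPHA_BOUND = 30.0
_MAX_HALVINGS = 20
_LN2 = 0.6931471805599453


# ---------------------------------------------------------------------------
# numeric helpers
# ---------------------------------------------------------------------------

def _log1mexp(lam):
    """log(1 - exp(-lam)) for lam > 0, stable for both small and large lam."""
    lam = np.asarray(lam, dtype=float)
    out = np.log1p(-np.exp(-lam))
    small = lam < _LN2
    if np.any(small):
        out = np.where(small, np.log(-np.expm1(-np.where(small, lam, 1.0))), out)
    return out


def _log1mexp_flat(lam):
    """In-place-friendly variant for 1-D arrays of positive rates."""
    out = np.log1p(-np.exp(-lam))
    small = lam < _LN2
    if small.any():
        out[small] = np.log(-np.expm1(-lam[small]))
    return out


def _trunc_mean(lam):
    """Mean of the zero-truncated Poisson: lam / (1 - exp(-lam))."""
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lam / (-np.expm1(-lam))
    return np.where(lam < 1e-12, 1.0, out)


def _trunc_mean_slope(lam):
    """d(truncated mean)/d(log lam) = lam * m_t'(lam); nonnegative."""
    lam = np.asarray(lam, dtype=float)
    em = np.exp(-lam)
    denom = -np.expm1(-lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = lam * (1.0 - em * (1.0 + lam)) / (denom * denom)
    return np.where(lam < 1e-6, 0.5 * lam, out)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """A features-by-samples matrix of sequencing read counts.

    Parameters
    ----------
    counts
        ``(G, N)`` array of non-negative integers.
    treatment_of_sample
        Length-``N`` treatment label per sample (column).
    feature_ids, sample_ids
        Optional string identifiers; generated when omitted.
    """

    counts: np.ndarray
    treatment_of_sample: np.ndarray
    feature_ids: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D (features x samples) matrix")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
                raise ValueError("counts must be integral")
            arr = np.round(arr).astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError("need at least 1 feature and 2 samples")
        self.counts = arr.astype(np.int64)
        labels = np.asarray(self.treatment_of_sample)
        if labels.shape != (arr.shape[1],):
            raise ValueError("treatment_of_sample must have one label per sample")
        self.treatment_of_sample = labels
        _, first = np.unique(labels, return_index=True)
        self.treatments = labels[np.sort(first)]
        lut = {t: i for i, t in enumerate(self.treatments)}
        self.treatment_codes = np.array([lut[t] for t in labels], dtype=np.int64)
        if self.feature_ids is None:
            self.feature_ids = [f"F{g + 1:05d}" for g in range(arr.shape[0])]
        if self.sample_ids is None:
            self.sample_ids = [f"S{n + 1:03d}" for n in range(arr.shape[1])]
        if len(self.feature_ids) != arr.shape[0] or len(self.sample_ids) != arr.shape[1]:
            raise ValueError("feature_ids/sample_ids lengths do not match counts")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)


@dataclass
class ClusterParams:
    """Cluster-level hurdle parameters (one mixture component).

    ``mu`` is the length-``I`` vector of log-scale treatment effects summing
    to zero; ``gamma0``/``gamma1`` the per-treatment logistic intercept and
    (non-negative) depth slope of the positive-probability; ``p`` the mixing
    proportion.
    """

    mu: np.ndarray
    gamma0: np.ndarray
    gamma1: np.ndarray
    p: float = 1.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.gamma0 = np.asarray(self.gamma0, dtype=float)
        self.gamma1 = np.asarray(self.gamma1, dtype=float)
        if not (self.mu.shape == self.gamma0.shape == self.gamma1.shape):
            raise ValueError("mu, gamma0, gamma1 must share the same length")
        if abs(float(self.mu.sum())) > 1e-6:
            raise ValueError("treatment effects mu must sum to zero")
        if np.any(self.gamma1 < -1e-12):
            raise ValueError("gamma1 must be non-negative")
        self.gamma1 = np.maximum(self.gamma1, 0.0)
        if not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValueError("mixing proportion p must lie in [0, 1]")
        self.p = float(min(self.p, 1.0))


@dataclass
class HurdleParams:
    """Full parameter set of a K-component Poisson hurdle mixture.

    Stored as arrays for vectorized likelihood evaluation: ``p`` ``(K,)``,
    ``mu``/``gamma0``/``gamma1`` ``(K, I)``, ``alpha`` ``(G, K)`` and the
    fixed normalization factors ``s`` ``(N,)``.  ``variant`` is ``"full"``
    (feature-specific alpha) or ``"reduced"`` (one alpha per cluster, i.e.
    every row of an alpha column identical).
    """

    p: np.ndarray
    mu: np.ndarray
    gamma0: np.ndarray
    gamma1: np.ndarray
    alpha: np.ndarray
    s: np.ndarray
    variant: str = "full"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.gamma0 = np.asarray(self.gamma0, dtype=float)
        self.gamma1 = np.asarray(self.gamma1, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        K = self.p.size
        if self.mu.shape[0] != K or self.alpha.shape[1] != K:
            raise ValueError("inconsistent cluster count across parameter arrays")
        if self.variant not in ("full", "reduced"):
            raise ValueError("variant must be 'full' or 'reduced'")
        if abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError("mixing proportions must sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.p.size

    @property
    def n_treatments(self) -> int:
        return self.mu.shape[1]

    def cluster(self, k: int) -> ClusterParams:
        return ClusterParams(
            mu=self.mu[k].copy(),
            gamma0=self.gamma0[k].copy(),
            gamma1=self.gamma1[k].copy(),
            p=float(self.p[k]),
        )

    @classmethod
    def from_clusters(cls, clusters, alpha, s, variant="full"):
        return cls(
            p=np.array([c.p for c in clusters]),
            mu=np.stack([c.mu for c in clusters]),
            gamma0=np.stack([c.gamma0 for c in clusters]),
            gamma1=np.stack([c.gamma1 for c in clusters]),
            alpha=np.asarray(alpha, dtype=float),
            s=np.asarray(s, dtype=float),
            variant=variant,
        )

    def copy(self) -> "HurdleParams":
        return HurdleParams(
            p=self.p.copy(), mu=self.mu.copy(), gamma0=self.gamma0.copy(),
            gamma1=self.gamma1.copy(), alpha=self.alpha.copy(), s=self.s.copy(),
            variant=self.variant,
        )

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "s": self.s.tolist(),
            "alpha": self.alpha.tolist(),
            "clusters": [
                {
                    "p": float(self.p[k]),
                    "mu": self.mu[k].tolist(),
                    "gamma0": self.gamma0[k].tolist(),
                    "gamma1": self.gamma1[k].tolist(),
                }
                for k in range(self.n_clusters)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HurdleParams":
        cl = d["clusters"]
        return cls(
            p=np.array([c["p"] for c in cl]),
            mu=np.array([c["mu"] for c in cl]),
            gamma0=np.array([c["gamma0"] for c in cl]),
            gamma1=np.array([c["gamma1"] for c in cl]),
            alpha=np.array(d["alpha"], dtype=float),
            s=np.array(d["s"], dtype=float),
            variant=d.get("variant", "full"),
        )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def upper_quartile_factors(counts) -> np.ndarray:
    """Log upper-quartile normalization factors, centered to sum to zero.

    For each sample the 75th percentile (linear-interpolation quantile) of
    its *nonzero* counts is taken; the log of these upper quartiles is then
    centered by its across-sample mean so that ``sum_n s_n = 0``, which
    identifies the additive decomposition ``s + alpha + mu``.
    """
    if isinstance(counts, CountMatrix):
        X = counts.counts
        ids = counts.sample_ids
    else:
        X = np.asarray(counts)
        ids = [f"S{n + 1:03d}" for n in range(X.shape[1])]
    N = X.shape[1]
    uq = np.empty(N, dtype=float)
    for n in range(N):
        nz = X[:, n][X[:, n] > 0]
        if nz.size == 0:
            raise ValueError(
                f"sample {ids[n]!r} has no nonzero counts; "
                "upper-quartile factor is undefined"
            )
        uq[n] = np.percentile(nz, 75)
    s = np.log(uq)
    return s - s.mean()


# ---------------------------------------------------------------------------
# pmf / likelihood
# ---------------------------------------------------------------------------

def hurdle_log_pmf(n, lam, q):
    """Log pmf of the Poisson hurdle distribution.

    ``log(1-q)`` at ``n == 0``; for ``n > 0`` the zero-truncated Poisson
    scaled by the gate probability ``q``.  ``-inf`` is returned at boundary
    parameter values (``q = 0`` with ``n > 0`` etc.).
    """
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(n.dtype, np.integer) and np.any(n != np.round(n)):
        raise ValueError("counts must be integral")
    lam = np.asarray(lam, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    nf = n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        zero_branch = np.log1p(-q)
        pos_branch = (
            np.log(q) - _log1mexp(lam)
            + nf * np.log(lam) - lam - gammaln(nf + 1.0)
        )
    out = np.where(n == 0, zero_branch, pos_branch)
    return float(out) if out.ndim == 0 else out


class _Workspace:
    """Precomputed per-dataset arrays shared by all likelihood evaluations.

    The positive cells of the count matrix are flattened (row-major) into
    parallel vectors ``pos_g``/``pos_j``/``pos_c`` so that truncated-Poisson
    terms are evaluated once per positive cell and aggregated by feature or
    treatment with ``np.bincount``.
    """

    def __init__(self, cm: CountMatrix, s: np.ndarray):
        self.cm = cm
        self.C = cm.counts.astype(float)
        self.P = cm.counts > 0
        self.s = np.asarray(s, dtype=float)
        self.tcode = cm.treatment_codes
        self.I = cm.n_treatments
        self.G, self.N = self.C.shape
        self.logNfact = gammaln(self.C + 1.0).sum(axis=1)
        self.has_pos = self.P.any(axis=1)
        self.treat_cols = [np.where(self.tcode == i)[0] for i in range(self.I)]
        pg, pj = np.nonzero(self.P)
        self.pos_g = np.ascontiguousarray(pg)
        self.pos_j = np.ascontiguousarray(pj)
        self.pos_c = np.ascontiguousarray(self.C[pg, pj])
        self.pos_s = np.ascontiguousarray(self.s[pj])
        self.pos_t = np.ascontiguousarray(self.tcode[pj])
        self.M = pg.size
        npos = self.P.sum(axis=1)
        with np.errstate(divide="ignore"):
            mean_pos = np.where(npos > 0, self.C.sum(axis=1) / np.maximum(npos, 1), 1.0)
        self.log_mean_pos = np.where(npos > 0, np.log(mean_pos), 0.0)

def _trunc_cell_stats(ws: _Workspace, alpha_col, mu):
    """Per-positive-cell objective, gradient and curvature terms.

    One vectorized pass: rate ``lam = exp(s + alpha + mu)``, the truncated
    log-likelihood term, the score ``n - m_t(lam)`` and the (negative)
    curvature ``lam * m_t'(lam)`` of each cell with respect to its log rate.
    """
    loglam = ws.pos_s + mu[ws.pos_t]
    loglam += alpha_col[ws.pos_g]
    np.minimum(loglam, 300.0, out=loglam)
    lam = np.exp(loglam)
    denom = -np.expm1(-lam)
    l1me = _log1mexp_flat(lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        mt = np.where(lam < 1e-12, 1.0, lam / denom)
        em = np.exp(-lam)
        slope = np.where(lam < 1e-6, 0.5 * lam,
                         lam * (1.0 - em * (1.0 + lam)) / (denom * denom))
    obj = ws.pos_c * loglam - lam - l1me
    return obj, ws.pos_c - mt, slope


def _trunc_cells(ws: _Workspace, alpha_col, mu):
    """Per-positive-cell truncated log-likelihood terms only."""
    loglam = ws.pos_s + mu[ws.pos_t]
    loglam += alpha_col[ws.pos_g]
    np.minimum(loglam, 300.0, out=loglam)
    lam = np.exp(loglam)
    return ws.pos_c * loglam - lam - _log1mexp_flat(lam)


def _trunc_rows(ws: _Workspace, alpha_col, mu) -> np.ndarray:
    """Per-feature truncated-Poisson log-likelihood part."""
    return np.bincount(ws.pos_g, weights=_trunc_cells(ws, alpha_col, mu),
                       minlength=ws.G)


def _gate_logprobs(gamma0, gamma1, s, tcode):
    """(log q_j, log(1-q_j)) per sample for one cluster."""
    eta = gamma0[tcode] + gamma1[tcode] * s
    return -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta)


def _feature_logf(ws: _Workspace, gamma0, gamma1, mu, alpha_col):
    """Length-G vector of per-feature log hurdle densities under one cluster."""
    logq, log1mq = _gate_logprobs(gamma0, gamma1, ws.s, ws.tcode)
    gate = log1mq.sum() + np.bincount(
        ws.pos_g, weights=(logq - log1mq)[ws.pos_j], minlength=ws.G)
    return gate + _trunc_rows(ws, alpha_col, mu) - ws.logNfact


def cluster_loglik(counts: CountMatrix, weights, cluster: ClusterParams,
                   alpha_col, s) -> float:
    """Weighted per-cluster log-likelihood ``l_k``.

    ``sum_g w_g * log f(N_g | mu_k, gamma_k, alpha_gk)`` with the hurdle
    density built from the additive Poisson-mean and logistic-gate
    structures.  Zero-weight features contribute exactly zero even when
    their log-density is ``-inf``.
    """
    ws = _Workspace(counts, s)
    w = np.asarray(weights, dtype=float)
    lf = _feature_logf(ws, cluster.gamma0, cluster.gamma1, cluster.mu,
                       np.asarray(alpha_col, dtype=float))
    return float(np.where(w > 0, w * np.where(np.isfinite(lf), lf, -np.inf), 0.0).sum())


# ---------------------------------------------------------------------------
# M-step one-step updates
# ---------------------------------------------------------------------------

def _gate_obj(a, b, s, g0, g1):
    eta = g0 + g1 * s
    return float(a @ (-np.logaddexp(0.0, -eta)) + b @ (-np.logaddexp(0.0, eta)))


def _gamma_newton(a, b, s, g0, g1):
    """One guarded Newton step for a weighted logistic gate fit.

    ``a``/``b`` are weighted positive/zero pseudo-counts per sample; the
    step is halved until the weighted Bernoulli log-likelihood does not
    decrease, gamma1 is projected to >= 0 and gamma0 clamped.
    """
    tot = a + b
    W = tot.sum()
    if W <= 1e-12:
        return g0, g1
    eta = g0 + g1 * s
    qv = expit(eta)
    d = a - tot * qv
    v = tot * qv * (1.0 - qv)
    grad = np.array([d.sum(), d @ s])
    if abs(grad[0]) + abs(grad[1]) < 1e-9 * W:
        return g0, g1
    h01 = v @ s
    H = np.array([[v.sum(), h01], [h01, v @ (s * s)]])
    det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
    degenerate = det <= 1e-10 * max(H[0, 0], 1e-300) ** 2 * max(1.0, float(np.max(s * s)))
    if not degenerate:
        step = np.linalg.solve(H, grad)
    if degenerate or (g1 <= 0.0 and g1 + step[1] < 0.0):
        # constraint gamma1 >= 0 active (or degenerate design, e.g. constant
        # s within the treatment): Newton on the intercept alone
        step = np.array([grad[0] / max(H[0, 0], 1e-300), 0.0])
    f0 = _gate_obj(a, b, s, g0, g1)
    scale = 1.0
    for _ in range(_MAX_HALVINGS + 1):
        c0 = float(np.clip(g0 + scale * step[0], -GAMMA0_BOUND, GAMMA0_BOUND))
        c1 = max(float(g1 + scale * step[1]), 0.0)
        if (c0, c1) == (g0, g1) or _gate_obj(a, b, s, c0, c1) >= f0 - 1e-10:
            return c0, c1
        scale *= 0.5
    return g0, g1


def _update_gamma_arrays(ws: _Workspace, w, gamma0, gamma1):
    a_all = np.bincount(ws.pos_j, weights=w[ws.pos_g], minlength=ws.N)
    W = w.sum()
    g0 = np.asarray(gamma0, dtype=float).copy()
    g1 = np.asarray(gamma1, dtype=float).copy()
    for i in range(ws.I):
        cols = ws.treat_cols[i]
        a = a_all[cols]
        g0[i], g1[i] = _gamma_newton(a, W - a, ws.s[cols], g0[i], g1[i])
    return g0, g1


def update_gamma(zero_pattern, weights, s, treatment_codes,
                 cluster: ClusterParams) -> ClusterParams:
    """One guarded Newton update of the logistic gate pair per treatment.

    ``zero_pattern`` is the G x N boolean matrix of zero cells; ``weights``
    the posterior membership weights of the cluster.
    """
    zp = np.asarray(zero_pattern, dtype=bool)
    w = np.asarray(weights, dtype=float)
    s = np.asarray(s, dtype=float)
    tcode = np.asarray(treatment_codes)
    I = cluster.mu.size
    a_all = w @ (~zp).astype(float)
    W = w.sum()
    g0 = cluster.gamma0.copy()
    g1 = cluster.gamma1.copy()
    for i in range(I):
        cols = np.where(tcode == i)[0]
        a = a_all[cols]
        g0[i], g1[i] = _gamma_newton(a, W - a, s[cols], g0[i], g1[i])
    return ClusterParams(mu=cluster.mu.copy(), gamma0=g0, gamma1=g1, p=cluster.p)


def _alpha_newton_full(ws: _Workspace, w, mu, alpha_col):
    """Vectorized guarded Newton pass over alpha_gk (full variant).

    Features with no positive weighted count retain their alpha (their
    likelihood has no truncated-Poisson term).  The posterior weight w_g
    multiplies the whole per-feature objective, so it does not move the
    per-feature maximizer; zero-weight features are skipped outright.
    """
    alpha = np.asarray(alpha_col, dtype=float).copy()
    obj_c, grad_c, curv_c = _trunc_cell_stats(ws, alpha, mu)
    f0 = np.bincount(ws.pos_g, weights=obj_c, minlength=ws.G)
    grad = np.bincount(ws.pos_g, weights=grad_c, minlength=ws.G)
    curv = np.bincount(ws.pos_g, weights=curv_c, minlength=ws.G)
    active = ws.has_pos & (np.asarray(w) > 0) & (curv > 1e-12)
    step = np.where(active, grad / np.maximum(curv, 1e-12), 0.0)
    if not np.any(step != 0):
        return alpha
    scale = np.ones(ws.G)
    pending = step != 0.0
    a0 = alpha.copy()
    for _ in range(_MAX_HALVINGS):
        cand = np.where(pending,
                        np.clip(a0 + scale * step, -ALPHA_BOUND, ALPHA_BOUND),
                        alpha)
        f1 = _trunc_rows(ws, cand, mu)
        ok = pending & (f1 >= f0 - 1e-10)
        alpha[ok] = cand[ok]
        pending &= ~ok
        if not pending.any():
            break
        scale[pending] *= 0.5
    return alpha


def _alpha_newton_reduced(ws: _Workspace, w, mu, alpha_col):
    """Guarded Newton step for the shared per-cluster alpha (reduced model)."""
    alpha = np.asarray(alpha_col, dtype=float).copy()
    wg = np.asarray(w, dtype=float)[ws.pos_g]
    a_shared = float(alpha[0]) if alpha.size else 0.0
    obj_c, grad_c, curv_c = _trunc_cell_stats(ws, alpha, mu)
    f0 = float(wg @ obj_c)
    grad = float(wg @ grad_c)
    curv = float(wg @ curv_c)
    if curv <= 1e-12:
        return alpha
    step = grad / curv
    scale = 1.0
    for _ in range(_MAX_HALVINGS):
        cand = float(np.clip(a_shared + scale * step, -ALPHA_BOUND, ALPHA_BOUND))
        f1 = float(wg @ _trunc_cells(ws, np.full(ws.G, cand), mu))
        if f1 >= f0 - 1e-10:
            alpha[:] = cand
            return alpha
        scale *= 0.5
    return alpha


def _mu_newton(ws: _Workspace, w, mu, alpha_col):
    """Guarded per-treatment Newton pass for mu, then re-centering.

    The per-treatment objectives are separable (treatments partition the
    samples), so all I Newton steps are computed from one pass over the
    positive cells and guarded jointly.  The sum-to-zero shift is absorbed
    into alpha so the Poisson means are unchanged by the re-centering.
    """
    mu = np.asarray(mu, dtype=float).copy()
    alpha_col = np.asarray(alpha_col, dtype=float)
    wg = np.asarray(w, dtype=float)[ws.pos_g]
    obj_c, grad_c, curv_c = _trunc_cell_stats(ws, alpha_col, mu)
    f0 = np.bincount(ws.pos_t, weights=wg * obj_c, minlength=ws.I)
    grad = np.bincount(ws.pos_t, weights=wg * grad_c, minlength=ws.I)
    curv = np.bincount(ws.pos_t, weights=wg * curv_c, minlength=ws.I)
    step = np.where(curv > 1e-12, grad / np.maximum(curv, 1e-12), 0.0)
    if np.any(step != 0):
        new = mu.copy()
        scale = np.ones(ws.I)
        pending = step != 0.0
        for _ in range(_MAX_HALVINGS):
            cand = np.where(pending,
                            np.clip(mu + scale * step, -ALPHA_BOUND, ALPHA_BOUND),
                            new)
            f1 = np.bincount(ws.pos_t,
                             weights=wg * _trunc_cells(ws, alpha_col, cand),
                             minlength=ws.I)
            ok = pending & (f1 >= f0 - 1e-10)
            new[ok] = cand[ok]
            pending &= ~ok
            if not pending.any():
                break
            scale[pending] *= 0.5
        mu = new
    shift = mu.mean()
    mu -= shift
    return mu, alpha_col + shift


def _update_alpha_mu_arrays(ws: _Workspace, w, mu, alpha_col, variant="full"):
    if variant == "reduced":
        alpha = _alpha_newton_reduced(ws, w, mu, alpha_col)
    else:
        alpha = _alpha_newton_full(ws, w, mu, alpha_col)
    mu, alpha = _mu_newton(ws, w, mu, alpha)
    return mu, alpha


def update_alpha_mu(counts: CountMatrix, weights, cluster: ClusterParams,
                    alpha_col, s, variant: str = "full"):
    """One guarded coordinate pass over (alpha_gk, mu_ki).

    alpha is updated first (features with at least one positive weighted
    count), then mu per treatment; mu is re-centered to sum to zero with the
    shift absorbed into alpha.  The weighted truncated-Poisson part of
    ``l_k`` never decreases.

    Returns
    -------
    (ClusterParams, ndarray)
        Updated cluster-level parameters and alpha column.
    """
    ws = _Workspace(counts, s)
    w = np.asarray(weights, dtype=float)
    mu, alpha = _update_alpha_mu_arrays(
        ws, w, cluster.mu.copy(), np.asarray(alpha_col, dtype=float).copy(), variant
    )
    return (
        ClusterParams(mu=mu, gamma0=cluster.gamma0.copy(),
                      gamma1=cluster.gamma1.copy(), p=cluster.p),
        alpha,
    )


# ---------------------------------------------------------------------------
# single-feature maximum likelihood (seeding / cluster re-seeding)
# ---------------------------------------------------------------------------

def _fit_single_feature(ws: _Workspace, g: int, max_iter: int = 100,
                        tol: float = 1e-10):
    """Per-treatment hurdle MLE for one feature.

    Returns centered treatment effects ``mu`` (components without any
    positive count are set to 0) and the clamped logistic gate fit of the
    feature's zero pattern.  Used to build EM starting values and to
    re-seed emptied clusters.
    """
    I = ws.I
    g0 = np.zeros(I)
    g1 = np.zeros(I)
    y = ws.P[g].astype(float)
    for i in range(I):
        cols = ws.treat_cols[i]
        a = y[cols]
        b = 1.0 - a
        sv = ws.s[cols]
        for _ in range(max_iter):
            n0, n1 = _gamma_newton(a, b, sv, g0[i], g1[i])
            if abs(n0 - g0[i]) + abs(n1 - g1[i]) < tol:
                g0[i], g1[i] = n0, n1
                break
            g0[i], g1[i] = n0, n1
    xi = np.zeros(I)
    defined = np.zeros(I, dtype=bool)
    for i in range(I):
        cols = ws.treat_cols[i]
        pos = cols[ws.P[g, cols]]
        if pos.size == 0:
            continue
        defined[i] = True
        cnt = ws.C[g, pos]
        sv = ws.s[pos]
        x = float(np.log(cnt.mean()) - sv.mean())

        def obj(v):
            loglam = np.minimum(sv + v, 300.0)
            lam = np.exp(loglam)
            return float((cnt * loglam - lam - _log1mexp(lam)).sum())

        for _ in range(max_iter):
            lam = np.exp(np.minimum(sv + x, 300.0))
            grad = float((cnt - _trunc_mean(lam)).sum())
            curv = float(_trunc_mean_slope(lam).sum())
            if curv <= 1e-12:
                break
            step = grad / curv
            f0 = obj(x)
            scale = 1.0
            moved = False
            for _ in range(_MAX_HALVINGS):
                cand = float(np.clip(x + scale * step, -ALPHA_BOUND, ALPHA_BOUND))
                if obj(cand) >= f0 - 1e-12:
                    moved = abs(cand - x) > tol
                    x = cand
                    break
                scale *= 0.5
            if not moved:
                break
        xi[i] = x
    mu = np.zeros(I)
    if defined.any():
        center = xi[defined].mean()
        mu[defined] = xi[defined] - center
    if not defined.all():
        logger.debug("feature %d has treatments with no positive counts; "
                     "their mu components start at 0", g)
    return mu, g0, g1
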