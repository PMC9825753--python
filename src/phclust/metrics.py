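"""External clustering-agreement criteria: purity, ARI and NMI.

All three live in [0, 1] (ARI can dip below 0 for worse-than-chance
agreement) and are invariant to relabeling of either partition.  ARI and
NMI are symmetric in their arguments; purity is not — it asks how dominated
each *predicted* cluster is by a single true class, so a trivial
all-singletons prediction scores 1.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score


def _check(pred, truth):
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size != truth.size:
        raise ValueError(
            f"partition lengths differ: {pred.size} vs {truth.size}"
        )
    if pred.size == 0:
        raise ValueError("empty partitions")
    return pred, truth


def purity(pred, truth) -> float:
    """Mean dominant-true-class share across predicted clusters.

    ``(1/G) * sum_k max_j |pred cluster k  intersect  true class j|``.
    """
    pred, truth = _check(pred, truth)
    total = 0
    for lab in np.unique(pred):
        members = truth[pred == lab]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return float(total) / pred.size


def adjusted_rand_index(pred, truth) -> float:
    """Chance-adjusted pair-counting agreement (1 = identical partitions)."""
    pred, truth = _check(pred, truth)
    return float(adjusted_rand_score(truth, pred))


def nmi(pred, truth, average_method: str = "geometric") -> float:
    """Mutual information normalized by the geometric mean of entropies.

    The arithmetic-mean and max normalizers are available through
    ``average_method`` for sensitivity checks.  A degenerate single-cluster
    partition against a non-degenerate one scores 0.
    """
    pred, truth = _check(pred, truth)
    return float(normalized_mutual_info_score(truth, pred,
                                              average_method=average_method))
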