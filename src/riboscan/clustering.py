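"""Two-medoid partitioning (PAM, k = 2) and silhouette scoring.

Clustering operates on a precomputed dissimilarity matrix of base-pair
distances between the unique structures of one landscape, unweighted by
sample multiplicity (duplicates have zero mutual distance and would inflate
the silhouette); a multiplicity-weighted variant is available.  A landscape
is deemed to hold two significant clusters when the mean silhouette SC is at
least 0.4 (inclusive); the silhouette is the standard one in [-1, 1], with
singleton clusters contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ClusterResult",
    "ClusteringError",
    "validate_dissimilarity",
    "pam_k2",
    "mean_silhouette",
    "significant_cluster_count",
]

SC_THRESHOLD = 0.4


class ClusteringError(ValueError):
    pass


def validate_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ClusteringError(f"dissimilarity matrix must be square (got {D.shape})")
    if not np.allclose(D, D.T):
        raise ClusteringError("dissimilarity matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ClusteringError("dissimilarity matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ClusteringError("dissimilarities must be nonnegative")
    return D


@dataclass(frozen=True)
class ClusterResult:
    labels: tuple[int, ...]  # per-point assignment in {1, 2}
    medoids: tuple[int, int]  # point indices, ascending
    cost: float  # sum of dissimilarities to the assigned medoid
    sc: float  # mean silhouette


def _assign(D: np.ndarray, m1: int, m2: int) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment (ties to the lower medoid index)."""
    lo, hi = (m1, m2) if m1 < m2 else (m2, m1)
    labels = np.where(D[:, lo] <= D[:, hi], 1, 2)
    labels[lo] = 1
    labels[hi] = 2
    cost = float(np.where(labels == 1, D[:, lo], D[:, hi]).sum())
    return labels, cost


def pam_k2(
    D: np.ndarray,
    seed: int | None = None,
    weights: Sequence[float] | None = None,
) -> ClusterResult:
    """Partitioning Around Medoids with k = 2 (BUILD + SWAP).

    BUILD seeds the medoids greedily; SWAP exhaustively tries every
    (medoid, non-medoid) exchange and applies the best strict improvement
    until none exists, so the cost descends monotonically.  Single swaps can
    strand k = 2 in a local optimum that only a double swap escapes, so SWAP
    finishes with a vectorized scan of all medoid pairs (cheap at k = 2):
    the returned cost is always the exhaustive two-medoid minimum.  ``seed``
    only breaks exact BUILD ties; SWAP is deterministic.  Optional per-point
    ``weights`` give the multiplicity-weighted variant.
    """
    D = validate_dissimilarity(D)
    n = D.shape[0]
    if n < 2:
        raise ClusteringError(f"PAM k=2 needs at least 2 points (got {n})")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ClusteringError("weights must be positive, one per point")
    Dw = D * w[:, None]  # row i weighted: cost contribution of point i

    rng = np.random.default_rng(seed)

    def tie_pick(candidates: np.ndarray) -> int:
        if len(candidates) == 1 or seed is None:
            return int(candidates[0])
        return int(rng.choice(candidates))

    # BUILD: first medoid minimizes total weighted dissimilarity
    totals = Dw.sum(axis=0)
    m1 = tie_pick(np.flatnonzero(totals == totals.min()))
    # second medoid minimizes the 2-medoid cost given m1
    costs = np.array(
        [
            np.minimum(Dw[:, m1], Dw[:, h]).sum() if h != m1 else np.inf
            for h in range(n)
        ]
    )
    m2 = tie_pick(np.flatnonzero(costs == costs.min()))

    def total_cost(a: int, b: int) -> float:
        return float(np.minimum(Dw[:, a], Dw[:, b]).sum())

    cost = total_cost(m1, m2)
    improved = True
    while improved:
        improved = False
        best = (cost, m1, m2)
        for out in (m1, m2):
            keep = m2 if out == m1 else m1
            for h in range(n):
                if h in (m1, m2):
                    continue
                c = total_cost(keep, h)
                if c < best[0] - 1e-12:
                    best = (c, keep, h)
        if best[0] < cost - 1e-12:
            cost, m1, m2 = best[0], *sorted(best[1:])
            improved = True
    # double-swap finish: scan every medoid pair (column-wise, vectorized)
    for a in range(n - 1):
        pair_costs = np.minimum(Dw[:, a : a + 1], Dw[:, a + 1 :]).sum(axis=0)
        b_rel = int(np.argmin(pair_costs))
        if pair_costs[b_rel] < cost - 1e-12:
            cost = float(pair_costs[b_rel])
            m1, m2 = a, a + 1 + b_rel
    m1, m2 = sorted((m1, m2))

    labels, cost = _assign(Dw, m1, m2)
    sc = mean_silhouette(D, labels)
    return ClusterResult(
        labels=tuple(int(x) for x in labels), medoids=(m1, m2), cost=cost, sc=sc
    )


def mean_silhouette(D: np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b) over all points.

    a(i): mean dissimilarity to the own cluster (excluding self);
    b(i): mean dissimilarity to the other cluster.  Points in singleton
    clusters contribute 0, as do points with a = b = 0.
    """
    D = validate_dissimilarity(D)
    labels = np.asarray(labels)
    if labels.shape != (D.shape[0],):
        raise ClusteringError("one label per point required")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ClusteringError(
            f"exactly two nonempty clusters required (got {len(uniq)})"
        )
    scores = np.zeros(len(labels))
    for i in range(len(labels)):
        own = labels == labels[i]
        if own.sum() == 1:
            continue  # singleton: s = 0
        a = D[i, own].sum() / (own.sum() - 1)
        b = D[i, ~own].mean()
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def significant_cluster_count(cr: ClusterResult, threshold: float = SC_THRESHOLD) -> int:
    """2 if SC >= threshold (inclusive), else 1."""
    return 2 if cr.sc >= threshold else 1
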