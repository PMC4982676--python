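"""Similarity of a connectivity matrix to an ideal synfire chain or to
self-connected assemblies.

Neurons are grouped by k-means on their combined input/output profiles (the
concatenation of row i and column i of W_ex, squared Euclidean distance).
For chain scoring the groups are ordered greedily: starting from a candidate
head group, repeatedly append the unused group that receives the largest
total synaptic input from the current group.  The grouped matrix is compared
against an ideal binary matrix B (complete feed-forward connectivity between
consecutive groups, or complete within-group connectivity for assemblies):

    score = 1 - || A / max(A) - B ||_F^2 / || B ||_F^2 ,

clipped to [0, 1], and maximized over the group count k, clustering restarts,
and the choice of head group (a deterministic strengthening of picking the
head at random).  A perfect chain with equal weights scores exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ScoreResult",
    "cluster_neurons",
    "order_groups_chain",
    "ideal_matrix",
    "chain_score",
    "ideal_chain_matrix",
    "ideal_assembly_matrix",
]


@dataclass
class ScoreResult:
    score: float
    best_k: int
    labels: np.ndarray
    ordering: np.ndarray  # permutation of group indices, head first
    mode: str
    degenerate: bool = False


def cluster_neurons(W_ex: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """k-means labels on the 2N-dimensional input+output weight vectors."""
    W_ex = np.asarray(W_ex, dtype=float)
    n = W_ex.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= N, got k={k}, N={n}")
    feats = np.hstack([W_ex, W_ex.T])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can trip ConvergenceWarning
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(feats)
    return labels


def order_groups_chain(labels: np.ndarray, W_ex: np.ndarray,
                       first_group: Optional[int] = None) -> np.ndarray:
    """Greedy feed-forward ordering of the groups.

    From the head group, repeatedly pick the unused group receiving the
    largest total synaptic input from the current one (W_ex[next, current]
    block sum); ties broken by the lowest group index.  If ``first_group`` is
    None the lowest group label starts.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        return groups.copy()
    if first_group is None:
        first_group = int(groups[0])
    members = {int(g): np.flatnonzero(labels == g) for g in groups}
    order = [int(first_group)]
    remaining = [int(g) for g in groups if int(g) != int(first_group)]
    while remaining:
        cur = members[order[-1]]
        # block sums W[next_members, cur_members]; argmax with lowest-index ties
        inputs = np.array([W_ex[np.ix_(members[g], cur)].sum() for g in remaining])
        order.append(remaining.pop(int(np.argmax(inputs))))
    return np.array(order)


def ideal_matrix(labels: np.ndarray, ordering: Sequence[int], mode: str,
                 wrap_around: bool = False) -> np.ndarray:
    """Ideal binary target matrix for the given grouping.

    chain:    entry (i, j) = 1 iff group(j) immediately precedes group(i) in
              ``ordering`` (so the block g -> g+1 is fully connected); the
              last group projects nowhere unless ``wrap_around``.
    assembly: entry (i, j) = 1 iff i and j share a group, i != j.
    """
    labels = np.asarray(labels)
    n = labels.size
    B = np.zeros((n, n))
    if mode == "assembly":
        same = labels[:, None] == labels[None, :]
        B[same] = 1.0
        np.fill_diagonal(B, 0.0)
        return B
    if mode != "chain":
        raise ValueError(f"unknown mode {mode!r}")
    ordering = list(ordering)
    pairs = list(zip(ordering[:-1], ordering[1:]))
    if wrap_around and len(ordering) > 1:
        pairs.append((ordering[-1], ordering[0]))
    for src, dst in pairs:
        B[np.ix_(np.flatnonzero(labels == dst), np.flatnonzero(labels == src))] = 1.0
    np.fill_diagonal(B, 0.0)
    return B


def _score_against(A_scaled: np.ndarray, B: np.ndarray) -> float:
    x = float(np.sum((A_scaled - B) ** 2)) / max(float(np.sum(B**2)), 1.0)
    return float(np.clip(1.0 - x, 0.0, 1.0))


def chain_score(W_ex: np.ndarray, k_range: Optional[Iterable[int]] = None,
                seeds: Sequence[int] = (0,), mode: str = "chain",
                n_init: int = 10, wrap_around: bool = False) -> ScoreResult:
    """Structure score maximized over k, clustering seeds, and head groups.

    ``k_range`` defaults to 2..floor(N/2).  An all-zero matrix is scored with
    A/max(A) taken as the zero matrix.
    """
    W_ex = np.asarray(W_ex, dtype=float)
    n = W_ex.shape[0]
    if k_range is None:
        k_range = range(2, max(n // 2, 2) + 1)
    mx = W_ex.max()
    A_scaled = W_ex / mx if mx > 0 else np.zeros_like(W_ex)
    best = None
    for k in k_range:
        for seed in seeds:
            labels = cluster_neurons(W_ex, k, seed=seed, n_init=n_init)
            groups = np.unique(labels)
            degenerate = groups.size < k
            if mode == "assembly":
                B = ideal_matrix(labels, groups, "assembly")
                cand = ScoreResult(_score_against(A_scaled, B), k, labels,
                                   groups.copy(), mode, degenerate)
                if best is None or cand.score > best.score:
                    best = cand
            else:
                for head in groups:
                    ordering = order_groups_chain(labels, W_ex, first_group=int(head))
                    B = ideal_matrix(labels, ordering, "chain", wrap_around)
                    cand = ScoreResult(_score_against(A_scaled, B), k, labels,
                                       ordering, mode, degenerate)
                    if best is None or cand.score > best.score:
                        best = cand
    return best


# ---------------------------------------------------------------------------
# Ideal-matrix constructors (fixtures for tests and calibration)
# ---------------------------------------------------------------------------

def ideal_chain_matrix(n_groups: int, group_size: int, weight: float = 1.0,
                       wrap_around: bool = False) -> np.ndarray:
    """Perfect wide synfire chain: group g projects all-to-all onto group g+1."""
    labels = np.repeat(np.arange(n_groups), group_size)
    B = ideal_matrix(labels, np.arange(n_groups), "chain", wrap_around)
    return weight * B


def ideal_assembly_matrix(n_groups: int, group_size: int, weight: float = 1.0) -> np.ndarray:
    """Perfect self-connected assemblies: all-to-all within each group."""
    labels = np.repeat(np.arange(n_groups), group_size)
    return weight * ideal_matrix(labels, np.arange(n_groups), "assembly")
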