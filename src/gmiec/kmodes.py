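"""Huang k-modes for binary matrices.

K-means analogue for categorical data: dissimilarity is the Hamming distance
(count of mismatching columns), centroids are per-column modes, and the
objective is the total within-cluster dissimilarity. Every tie-break is
deterministic so runs reproduce exactly from a seed:

* assignment ties go to the smallest cluster index;
* mode-update ties (equal 0/1 counts in a column) keep the current centroid
  value;
* an emptied cluster is re-seeded with the point farthest (max Hamming) from
  its current centroid;
* restarts initialize from distinct data rows — ordered tuples enumerated
  exhaustively when there are no more of them than restarts, sampled
  otherwise — and each converged restart is polished by a deterministic
  single-point relocation descent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .io import ValidationError

logger = logging.getLogger("gmiec")


@dataclass
class KModesResult:
    labels: np.ndarray  # cluster index per row, 0-based, contiguous
    centroids: np.ndarray
    cost: int
    cost_history: list[int]  # cost after each assignment step, non-increasing
    k_effective: int


def _hamming_to_centroids(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return (X[:, None, :] != centroids[None, :, :]).sum(axis=2)


def _update_modes(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    new = centroids.copy()
    for c in range(centroids.shape[0]):
        members = X[labels == c]
        if len(members) == 0:
            continue
        ones = members.sum(axis=0)
        zeros = len(members) - ones
        col = np.where(ones > zeros, 1, np.where(ones < zeros, 0, centroids[c]))
        new[c] = col
    return new


def _partition_cost(X: np.ndarray, labels: np.ndarray) -> int:
    """Optimal-mode within-cluster Hamming cost of a fixed partition."""
    cost = 0
    for c in np.unique(labels):
        rows = X[labels == c]
        ones = rows.sum(axis=0)
        cost += int(np.minimum(ones, len(rows) - ones).sum())
    return cost


def _relocate(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Best-improvement single-point relocation until no move lowers the cost.

    Escapes the local optima batch Huang can converge to on small inputs;
    moves that would empty a cluster are skipped so k stays fixed. Ties are
    broken deterministically (smallest point index, then cluster index).
    """
    labels = labels.copy()
    clusters = np.unique(labels)
    cost = _partition_cost(X, labels)
    improved = True
    while improved:
        improved = False
        best_move = None
        best_cost = cost
        for i in range(len(X)):
            if np.sum(labels == labels[i]) == 1:
                continue
            for c in clusters:
                if c == labels[i]:
                    continue
                trial = labels.copy()
                trial[i] = c
                tcost = _partition_cost(X, trial)
                if tcost < best_cost:
                    best_cost = tcost
                    best_move = (i, c)
        if best_move is not None:
            labels[best_move[0]] = best_move[1]
            cost = best_cost
            improved = True
    return labels, cost


def _single_run(X: np.ndarray, init: np.ndarray, max_iter: int = 100) -> KModesResult:
    k = init.shape[0]
    centroids = init.copy()
    prev_labels = None
    history: list[int] = []
    for _ in range(max_iter):
        D = _hamming_to_centroids(X, centroids)
        labels = D.argmin(axis=1)  # argmin takes the smallest index on ties
        # re-seed emptied clusters with the point farthest from its centroid
        for c in range(k):
            if not np.any(labels == c):
                assigned = D[np.arange(len(X)), labels]
                movable = np.array(
                    [np.sum(labels == labels[i]) > 1 for i in range(len(X))]
                )
                candidates = np.where(movable, assigned, -1)
                far = int(candidates.argmax())
                labels[far] = c
                centroids[c] = X[far]
        cost = int(
            (X != centroids[labels]).sum()
        )
        history.append(cost)
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels
        centroids = _update_modes(X, labels, centroids)
    labels, cost = _relocate(X, labels)
    if cost < history[-1]:
        history.append(cost)
    centroids = _update_modes(X, labels, centroids)
    return KModesResult(
        labels=labels,
        centroids=centroids,
        cost=history[-1],
        cost_history=history,
        k_effective=len(np.unique(labels)),
    )


def kmodes(
    X: np.ndarray, k: int, n_init: int = 10, seed: int = 0, max_iter: int = 100
) -> KModesResult:
    """Best-of-``n_init`` Huang k-modes on a binary matrix.

    If fewer than ``k`` distinct rows exist, the effective k drops to the
    number of distinct rows (logged); surplus clusters are never padded.
    Returns the restart with the smallest total within-cluster Hamming cost
    (earlier restart wins ties). Labels are compacted to 0..k_eff-1.
    """
    X = np.asarray(X, dtype=np.int8)
    if not np.isin(X, (0, 1)).all():
        raise ValidationError("k-modes input must be binary")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range [1, {n}]")
    distinct = np.unique(X, axis=0)
    if len(distinct) < k:
        logger.info(
            "only %d distinct rows for k=%d; reducing effective k", len(distinct), k
        )
        k = len(distinct)

    rng = np.random.default_rng(seed)
    n_perms = _n_permutations(len(distinct), k)
    inits: list[np.ndarray]
    if n_perms is not None and n_perms <= n_init:
        # assignment ties depend on centroid order, so enumerate ordered tuples
        inits = [distinct[list(c)] for c in permutations(range(len(distinct)), k)]
    else:
        inits = [
            distinct[rng.choice(len(distinct), size=k, replace=False)]
            for _ in range(n_init)
        ]
    best: KModesResult | None = None
    for init in inits:
        res = _single_run(X, init, max_iter=max_iter)
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    # compact labels to a contiguous 0..k_eff-1 range, order of first appearance
    remap = {}
    out = np.empty_like(best.labels)
    for i, lab in enumerate(best.labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    best.labels = out
    best.k_effective = len(remap)
    return best


def _n_permutations(n: int, k: int) -> int | None:
    """P(n, k), or None when it overflows a sane bound (treated as 'many')."""
    from math import perm

    try:
        value = perm(n, k)
    except (OverflowError, ValueError):
        return None
    return value if value < 10**6 else None
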