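import numpy as np
import pandas as pd
import pytest

from gmiec import OmicsDataset, ProximityMatrix, align_bundle


def make_dataset(kind, genes, samples, values):
    return OmicsDataset(
        layer_kind=kind,
        values=pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
    )


@pytest.fixture
def small_bundle():
    """Two patients, four genes, expression + copy number."""
    genes = ["A", "B", "C", "D"]
    samples = ["s1", "s2"]
    expr = make_dataset("expression", genes, samples, [[1.0, 2.0], [0.5, 0.1], [3.0, 0.0], [2.0, 1.0]])
    cn = make_dataset("copy_number", genes, samples, [[0.4, 0.0], [-0.5, 0.1], [0.0, 0.6], [0.2, -0.1]])
    return align_bundle([expr, cn])


def random_proximity(n, rng):
    """Random valid proximity matrix: symmetric, unit diagonal, values in [0, 1]."""
    A = rng.uniform(0.0, 1.0, size=(n, n))
    P = (A + A.T) / 2.0
    np.fill_diagonal(P, 1.0)
    return ProximityMatrix(genes=[f"g{i:02d}" for i in range(n)], values=P)


def block_proximity(n_blocks, block_size, within=0.95, between=0.05):
    """Planted block-structured proximity matrix with unit diagonal."""
    n = n_blocks * block_size
    P = np.full((n, n), between)
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        P[sl, sl] = within
    np.fill_diagonal(P, 1.0)
    return ProximityMatrix(genes=[f"g{i:02d}" for i in range(n)], values=P)


# --- independent brute-force oracles (never call package internals) ---


def brute_kmodes_cost(X, k):
    """Exhaustive minimum within-cluster Hamming cost over all <=k-partitions."""
    import itertools

    X = np.asarray(X)
    n = len(X)
    best = None
    for labs in itertools.product(range(k), repeat=n):
        canon, seen, ok = [], {}, True
        for lab in labs:
            if lab not in seen:
                if lab != len(seen):
                    ok = False
                    break
                seen[lab] = len(seen)
            canon.append(seen[lab])
        if not ok:
            continue
        cost = 0
        for c in set(canon):
            rows = X[[i for i in range(n) if canon[i] == c]]
            ones = rows.sum(axis=0)
            cost += int(np.minimum(ones, len(rows) - ones).sum())
        if best is None or cost < best:
            best = cost
    return best


def brute_kmeans_sse_2(P):
    """Exhaustive minimum SSE over all 2-partitions of the rows of P."""
    n = len(P)
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):
        a = [i for i in range(n) if (mask >> i) & 1]
        b = [i for i in range(n) if not (mask >> i) & 1]
        if not a or not b:
            continue
        sse = 0.0
        for idx in (a, b):
            rows = P[idx]
            sse += ((rows - rows.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def partition_sse(P, labels):
    sse = 0.0
    for c in np.unique(labels):
        rows = P[labels == c]
        sse += ((rows - rows.mean(axis=0)) ** 2).sum()
    return sse
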