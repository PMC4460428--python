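"""Independent brute-force reference implementations used only by tests.

Deliberately naive and algorithmically distinct from the package:
Floyd-Warshall distances, matrix-power shortest-path counting, exhaustive
triangle counts, restricted-growth-string partition enumeration, and a
dictionary-based contingency-table mutual information.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def char_path_length_oracle(A: np.ndarray) -> float:
    D = floyd_warshall(A)
    n = A.shape[0]
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals))


def global_efficiency_oracle(A: np.ndarray) -> float:
    D = floyd_warshall(A)
    n = A.shape[0]
    if n < 2:
        return 0.0
    total = sum(1.0 / D[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(D[i, j]))
    return total / (n * (n - 1))


def local_efficiency_oracle(A: np.ndarray) -> float:
    n = A.shape[0]
    vals = []
    for v in range(n):
        nbrs = np.flatnonzero(A[v])
        if nbrs.size < 2:
            vals.append(0.0)
            continue
        vals.append(global_efficiency_oracle(A[np.ix_(nbrs, nbrs)]))
    return float(np.mean(vals))


def clustering_oracle(A: np.ndarray):
    n = A.shape[0]
    nodal = []
    for v in range(n):
        nbrs = np.flatnonzero(A[v])
        k = nbrs.size
        if k < 2:
            nodal.append(0.0)
            continue
        links = sum(A[i, j] for i, j in itertools.combinations(nbrs, 2))
        nodal.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(nodal)), nodal


def betweenness_oracle(A: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness via matrix-power path counting.

    The number of shortest s-t paths equals (A^d(s,t))[s,t] because a walk
    whose length equals the graph distance cannot revisit a node.
    """
    n = A.shape[0]
    D = floyd_warshall(A)
    powers = [np.eye(n, dtype=object)]
    for _ in range(n):
        powers.append(powers[-1] @ A.astype(object))

    def n_paths(i, j):
        d = D[i, j]
        return powers[int(d)][i, j] if np.isfinite(d) else 0

    bc = np.zeros(n)
    for v in range(n):
        for s, t in itertools.combinations(range(n), 2):
            if v in (s, t) or not np.isfinite(D[s, t]):
                continue
            sigma = n_paths(s, t)
            if sigma == 0:
                continue
            if np.isfinite(D[s, v]) and np.isfinite(D[v, t]) \
                    and D[s, v] + D[v, t] == D[s, t]:
                bc[v] += n_paths(s, v) * n_paths(v, t) / sigma
    if n > 2:
        bc *= 2.0 / ((n - 1) * (n - 2))
    return bc


def assortativity_oracle(A: np.ndarray) -> float | None:
    """Degree correlation over the edge list; None when undefined."""
    deg = A.sum(axis=0)
    xs, ys = [], []
    for i in range(A.shape[0]):
        for j in range(A.shape[0]):
            if i != j and A[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    if len(xs) < 2:
        return None
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if np.ptp(xs) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def _restricted_growth_strings(n: int):
    """Yield all partitions of range(n) as label vectors."""
    labels = [0] * n

    def rec(i, maxlab):
        if i == n:
            yield list(labels)
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0) if n > 1 else iter([[0] * n])


def modularity_q(A: np.ndarray, labels) -> float:
    """Newman Q straight from the adjacency matrix."""
    m2 = A.sum()  # 2m
    deg = A.sum(axis=0)
    q = 0.0
    for c in set(labels):
        idx = [i for i, l in enumerate(labels) if l == c]
        e_in = A[np.ix_(idx, idx)].sum() / m2
        d_c = deg[idx].sum() / m2
        q += e_in - d_c**2
    return float(q)


def max_modularity_oracle(A: np.ndarray) -> float:
    """Exhaustive maximum of Q over every partition (small n only)."""
    n = A.shape[0]
    best = -np.inf
    for labels in _restricted_growth_strings(n):
        best = max(best, modularity_q(A, labels))
    return best


def mi_oracle(x_bins, y_bins) -> float:
    """Plug-in MI in bits from pre-binned samples, via plain dictionaries."""
    n = len(x_bins)
    joint, px, py = {}, {}, {}
    for a, b in zip(x_bins, y_bins):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        px[a] = px.get(a, 0) + 1
        py[b] = py.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / n
        mi += p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return max(mi, 0.0)
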