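"""Brute-force reference implementations of the graph metrics.

Deliberately naive and independent of the package's algorithms: distances
by Floyd-Warshall, shortest-path counts by dynamic programming on the
distance matrix, everything else straight from the definitions.
"""

from __future__ import annotations

import numpy as np


def fw_distances(A: np.ndarray) -> np.ndarray:
    """Floyd-Warshall hop distances with explicit triple loop."""
    n = len(A)
    D = np.full((n, n), np.inf)
    for i in range(n):
        D[i, i] = 0.0
        for j in range(n):
            if A[i, j]:
                D[i, j] = 1.0
    for k in range(n):
        D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
    return D


def bf_clustering(A: np.ndarray) -> np.ndarray:
    n = len(A)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        e = sum(1 for a in range(k) for b in range(a + 1, k) if A[nbrs[a], nbrs[b]])
        out[i] = 2.0 * e / (k * (k - 1))
    return out


def bf_char_path_length(A: np.ndarray) -> float:
    D = fw_distances(A)
    vals = [D[i, j] for i in range(len(A)) for j in range(len(A)) if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals))


def bf_global_efficiency(A: np.ndarray) -> float:
    D = fw_distances(A)
    n = len(A)
    if n < 2:
        return 0.0
    vals = [1.0 / D[i, j] if np.isfinite(D[i, j]) else 0.0 for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def bf_local_efficiency(A: np.ndarray) -> float:
    n = len(A)
    acc = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        if len(nbrs) >= 2:
            acc += bf_global_efficiency(A[np.ix_(nbrs, nbrs)])
    return acc / n if n else 0.0


def path_counts(A: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of shortest s-t paths, by DP over distance."""
    n = len(A)
    D = fw_distances(A)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted(range(n), key=lambda t: D[s, t])
        for t in order:
            if t == s or not np.isfinite(D[s, t]):
                continue
            sigma[s, t] = sum(
                sigma[s, u] for u in range(n) if A[u, t] and D[s, u] == D[s, t] - 1
            )
    return sigma


def bf_betweenness(A: np.ndarray) -> np.ndarray:
    """BC_i = sum over unordered pairs s<t (s,t != i) of sigma_st(i)/sigma_st."""
    n = len(A)
    D = fw_distances(A)
    sigma = path_counts(A)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(D[s, t]) or sigma[s, t] == 0:
                continue
            for i in range(n):
                if i in (s, t):
                    continue
                if D[s, i] + D[i, t] == D[s, t]:
                    bc[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return bc
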