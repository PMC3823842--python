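"""Global and nodal metrics of binary undirected networks.

All quantities follow the standard binary-graph definitions used
throughout the functional-connectomics literature:

* clustering coefficient ``C_i = 2 E_i / (k_i (k_i - 1))`` where ``E_i``
  counts edges among the neighbors of node ``i`` (Watts-Strogatz), with
  ``C_i = 0`` for degree < 2; ``Cp`` is the mean over all nodes,
* characteristic path length ``Lp``: mean BFS hop distance over reachable
  ordered pairs, with an explicit ``disconnected`` flag when any pair is
  unreachable,
* global efficiency ``Eglob``: mean of ``1/d(i,j)`` over ordered pairs
  with ``1/inf = 0`` (Latora-Marchiori), so disconnection is handled
  natively,
* local efficiency ``Eloc``: mean over nodes of the global efficiency of
  each node's neighbor-induced subgraph (the node itself excluded),
* betweenness centrality ``BC_i``: sum over unordered pairs ``(s, t)``,
  endpoints excluded, of the fraction of shortest s-t paths through
  ``i``, accumulated with Brandes' algorithm.

Functions accept a boolean/0-1 adjacency array or any object exposing an
``adjacency`` attribute (e.g. :class:`brainnet.connectivity.BinaryNetwork`).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path


def _as_adj(G) -> np.ndarray:
    A = getattr(G, "adjacency", G)
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    A = A != 0
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    if A.diagonal().any():
        raise ValueError("self-loops are not allowed")
    return A


class PathLength(NamedTuple):
    """Characteristic path length with a disconnection flag."""

    value: float
    disconnected: bool


@dataclass(frozen=True)
class GlobalMetrics:
    cp: float
    lp: float
    eglob: float
    eloc: float
    disconnected: bool = False


@dataclass(frozen=True)
class NodalMetrics:
    degree: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray


def degrees(G) -> np.ndarray:
    return _as_adj(G).sum(axis=0).astype(int)


def clustering(G) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean ``Cp``.

    Triangles through node i are counted as ``(A^3)_ii / 2``; nodes with
    degree < 2 contribute 0 and remain in the mean.
    """
    A = _as_adj(G).astype(float)
    k = A.sum(axis=0)
    tri = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, tri / denom, 0.0)
    return ci, float(ci.mean())


def shortest_paths(G) -> np.ndarray:
    """All-pairs BFS hop distances; unreachable pairs are ``inf``."""
    A = _as_adj(G)
    if A.shape[0] == 0:
        return np.zeros((0, 0))
    return _csgraph_shortest_path(csr_matrix(A), method="D", unweighted=True)


def characteristic_path_length(G) -> PathLength:
    """Mean hop distance over reachable ordered pairs i != j.

    A graph with unreachable pairs yields the mean over reachable pairs
    and ``disconnected=True``; a graph with no edges raises.
    """
    A = _as_adj(G)
    if not A.any():
        raise ValueError("characteristic path length undefined for an edgeless graph")
    D = shortest_paths(A)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    lp = float(D[finite].mean())
    return PathLength(lp, bool((~np.isfinite(D[off])).any()))


def global_efficiency(G) -> float:
    """Mean inverse hop distance over ordered pairs, ``1/inf = 0``."""
    A = _as_adj(G)
    n = A.shape[0]
    if n < 2:
        return 0.0
    D = shortest_paths(A)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].mean())


def local_efficiency(G) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    A = _as_adj(G)
    n = A.shape[0]
    if n == 0:
        return 0.0
    acc = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if len(nbrs) >= 2:
            acc += global_efficiency(A[np.ix_(nbrs, nbrs)])
    return acc / n


def betweenness(G) -> np.ndarray:
    """Brandes betweenness over unordered pairs, endpoints excluded."""
    A = _as_adj(G)
    n = A.shape[0]
    nbrs = [np.flatnonzero(A[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        order: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1, dtype=int)
        dist[s] = 0
        q: deque[int] = deque([s])
        while q:
            v = q.popleft()
            order.append(v)
            dv = dist[v]
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dv + 1
                    q.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while order:
            w = order.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair contributes from both endpoints


def global_metrics(G) -> GlobalMetrics:
    A = _as_adj(G)
    _, cp = clustering(A)
    lp, disc = characteristic_path_length(A)
    return GlobalMetrics(
        cp=cp,
        lp=lp,
        eglob=global_efficiency(A),
        eloc=local_efficiency(A),
        disconnected=disc,
    )


def nodal_metrics(G) -> NodalMetrics:
    A = _as_adj(G)
    ci, _ = clustering(A)
    return NodalMetrics(degree=A.sum(axis=0).astype(int), clustering=ci, betweenness=betweenness(A))
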