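"""From regional time series to binary networks.

The processing chain mirrors standard task-fMRI connectivity practice:
voxel time courses are averaged within atlas regions, nuisance signals
(global mean, white matter, CSF, six head-motion parameters) are removed
by ordinary least squares, Pearson correlations between the residual
regional series form an N x N connectivity matrix, and the matrix is
binarized at a target *sparsity* — the fraction of the N(N-1)/2 possible
edges that are kept — so that every subject's network has the same edge
count at each threshold.

By default edges are ranked by absolute correlation (after global-signal
regression, strong negative correlations are genuine couplings); set
``rank_by="positive"`` to rank signed values instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import LabeledMatrix, RegionAtlas


@dataclass(frozen=True)
class SparsityGrid:
    """Evenly spaced sparsity thresholds, endpoints inclusive.

    Defaults cover 0.10 to 0.49 in steps of 0.01 — 40 grid points."""

    start: float = 0.10
    stop: float = 0.49
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.start < self.stop < 1):
            raise ValueError("need 0 < start < stop < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def n_points(self) -> int:
        return int(np.floor((self.stop - self.start) / self.step + 0.5)) + 1

    @property
    def points(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


@dataclass
class RegionalTimeSeries:
    """T x N matrix of region-averaged signals with node labels."""

    data: np.ndarray
    labels: list[str]
    subject_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("time series must be a T x N matrix")
        if len(self.labels) != d.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {d.shape[1]} regions"
            )
        if np.isnan(d).any():
            raise ValueError("time series contains NaN")
        self.data = d


@dataclass
class BinaryNetwork:
    """Undirected, unweighted network at a given sparsity."""

    adjacency: np.ndarray
    labels: list[str] = field(default_factory=list)
    sparsity: float = float("nan")
    achieved_sparsity: float = float("nan")

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        A = A != 0
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T) or A.diagonal().any():
            raise ValueError("adjacency must be symmetric with empty diagonal")
        if not self.labels:
            self.labels = [f"R{i + 1:03d}" for i in range(A.shape[0])]
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_labeled_matrix(self) -> LabeledMatrix:
        return LabeledMatrix(self.adjacency.astype(float), self.labels, kind="adjacency")


def average_by_region(
    voxel_ts: np.ndarray, voxel_labels: np.ndarray, atlas: RegionAtlas
) -> RegionalTimeSeries:
    """Average voxel time courses within each atlas region.

    ``voxel_labels`` holds 1-based region indices per voxel; 0 marks
    unassigned voxels and is ignored.  Every region must receive at least
    one voxel.
    """
    V = np.asarray(voxel_ts, dtype=float)
    lab = np.asarray(voxel_labels, dtype=int)
    if V.ndim != 2 or lab.shape != (V.shape[1],):
        raise ValueError("voxel_ts must be T x V with one label per voxel")
    n = atlas.n_regions
    out = np.empty((V.shape[0], n))
    for r in range(1, n + 1):
        mask = lab == r
        if not mask.any():
            raise ValueError(f"empty region {atlas.labels[r - 1]}")
        out[:, r - 1] = V[:, mask].mean(axis=1)
    return RegionalTimeSeries(out, atlas.labels)


def regress_nuisance(ts: RegionalTimeSeries, nuisance: np.ndarray) -> RegionalTimeSeries:
    """OLS residuals of every regional series on [intercept | nuisance].

    The returned residuals are orthogonal to the intercept and to every
    nuisance column.  A rank-deficient design (collinear or constant
    columns) raises with the offending columns listed.
    """
    Z = np.asarray(nuisance, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != ts.data.shape[0]:
        raise ValueError("nuisance must be T x K with the same T as the time series")
    T, K = Z.shape
    if T <= K + 1:
        raise ValueError(f"need T > K+1 time points (T={T}, K={K})")
    X = np.column_stack([np.ones(T), Z])
    rank = np.linalg.matrix_rank(X)
    if rank < K + 1:
        # greedy scan: columns that add no rank given the preceding ones
        bad = []
        cols = [np.ones(T)]
        for k in range(K):
            trial = np.column_stack(cols + [Z[:, k]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(k)
            else:
                cols.append(Z[:, k])
        raise ValueError(f"rank-deficient nuisance design; collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return RegionalTimeSeries(resid, ts.labels, ts.subject_id, ts.condition)


def pearson_matrix(ts: RegionalTimeSeries) -> LabeledMatrix:
    """Pearson correlation between every pair of regional series."""
    sd = ts.data.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero-variance region {ts.labels[zero[0]]}")
    C = np.corrcoef(ts.data, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return LabeledMatrix(C, ts.labels, kind="correlation")


def threshold_by_sparsity(
    C: LabeledMatrix, s: float, rank_by: str = "absolute"
) -> BinaryNetwork:
    """Keep the strongest E = round(s * N(N-1)/2) correlations as edges.

    Ranking is by |r| (default) or by signed r (``rank_by="positive"``).
    Ties at the cutoff are broken by lowest (row, column) index so the
    network is bit-reproducible.
    """
    if not (0 < s <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    if rank_by not in ("absolute", "positive"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    n = C.n
    m_max = n * (n - 1) // 2
    n_edges = int(np.floor(s * m_max + 0.5))  # round half up, fp-stable
    if n_edges == 0:
        raise ValueError(f"sparsity {s} too low for N={n} (no edges survive)")
    r, c = np.triu_indices(n, 1)
    vals = C.values[r, c]
    key = np.abs(vals) if rank_by == "absolute" else vals
    order = np.lexsort((c, r, -key))
    keep = order[:n_edges]
    A = np.zeros((n, n), dtype=bool)
    A[r[keep], c[keep]] = True
    A |= A.T
    return BinaryNetwork(A, list(C.labels), sparsity=s, achieved_sparsity=n_edges / m_max)
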