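"""Graph topology of thresholded connectivity networks.

Connectivity matrices are binarized by proportional thresholding (keep the
strongest ``s`` fraction of possible edges) over the sparsity grid 0.10,
0.15, 0.20, 0.25, 0.30.  For each binary graph three global metrics are
computed -- global efficiency, average local efficiency and average
clustering coefficient -- and each metric's trajectory across the grid is
integrated with the trapezoid rule into a single threshold-independent
AUC feature.

Conventions (stated because they are not universal): graphs are binary and
undirected; disconnected node pairs contribute zero efficiency (no
largest-component restriction); the edge count at sparsity ``s`` is
``round(s * n(n-1)/2)`` with round-half-to-even; ties at the cutoff weight
are resolved by ascending (row, column) index so thresholding is
deterministic and nested across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix
from .errors import InputError, ParameterError

__all__ = [
    "DEFAULT_SPARSITY_GRID",
    "BinaryGraph",
    "TopologyFeatures",
    "proportional_threshold",
    "global_efficiency",
    "local_efficiency_avg",
    "clustering_avg",
    "auc_over_sparsity",
    "topology_features",
]

DEFAULT_SPARSITY_GRID: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30)
METRICS: tuple[str, ...] = ("global_efficiency", "local_efficiency", "clustering")


@dataclass
class BinaryGraph:
    """Undirected binary graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InputError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise InputError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise InputError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class TopologyFeatures:
    """Per-threshold metric values and their AUCs for one network."""

    sparsities: tuple[float, ...]
    per_threshold: dict[str, list[float]]
    auc: dict[str, float]
    subject_id: str = ""
    task: str = ""
    band: str = ""
    extra: dict = field(default_factory=dict)


def _as_matrix(W) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        return W.values
    return np.asarray(W, dtype=float)


def proportional_threshold(W, sparsity: float, *, binary: bool = True) -> BinaryGraph:
    """Keep the strongest ``sparsity`` fraction of possible edges.

    The ``round(s * n(n-1)/2)`` largest upper-triangle weights become
    edges; ties at the cutoff are taken in ascending (row, column) order.
    Because the retained set is a top-k of a fixed ordering, edge sets are
    nested across increasing sparsities.  With ``binary=False`` the
    retained edges keep their connectivity weights.
    """
    if not 0 < sparsity <= 1:
        raise ParameterError("sparsity must be in (0, 1]")
    W = _as_matrix(W)
    n = W.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    weights = W[rows, cols]
    k = round(sparsity * n * (n - 1) / 2)
    # Sort by descending weight, then ascending (row, col) for determinism.
    order = np.lexsort((cols, rows, -weights))
    keep = order[:k]
    if binary:
        adj = np.zeros((n, n), dtype=np.int8)
        adj[rows[keep], cols[keep]] = 1
        adj |= adj.T
    else:
        adj = np.zeros((n, n))
        adj[rows[keep], cols[keep]] = weights[keep]
        adj = adj + adj.T
    return BinaryGraph(adjacency=adj, sparsity=sparsity)


def _pairwise_efficiency_sum(adj: np.ndarray, weighted: bool = False) -> float:
    if weighted:
        with np.errstate(divide="ignore"):
            dist = np.where(adj > 0, 1.0 / np.maximum(adj, 1e-300), 0.0)
        d = shortest_path(csr_matrix(dist), method="D", directed=False)
    else:
        d = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum())


def global_efficiency(G: BinaryGraph | np.ndarray, *, weighted: bool = False) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Disconnected pairs contribute 0; a complete binary graph gives 1.
    With ``weighted=True`` edge lengths are the reciprocal weights.
    """
    adj = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    n = adj.shape[0]
    if n < 2:
        raise InputError("global efficiency undefined for n < 2")
    return _pairwise_efficiency_sum(adj, weighted) / (n * (n - 1))


def local_efficiency_avg(G: BinaryGraph | np.ndarray, *, weighted: bool = False) -> float:
    """Mean over nodes of the global efficiency of the open neighborhood.

    Nodes with fewer than two neighbors contribute 0.  The weighted
    variant applies the weighted efficiency to the neighborhood subgraph.
    """
    adj = G.adjacency if isinstance(G, BinaryGraph) else np.asarray(G)
    n = adj.shape[0]
    if n < 2:
        raise InputError("local efficiency undefined for n < 2")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += _pairwise_efficiency_sum(sub, weighted) / (k * (k - 1))
    return total / n


def clustering_avg(G: BinaryGraph | np.ndarray, *, weighted: bool = False) -> float:
    """Average clustering coefficient (triangles over possible triangles).

    Per node, ``2 T_i / (k_i (k_i - 1))`` with ``T_i`` the number of
    triangles through the node; nodes of degree < 2 contribute 0.  The
    weighted variant uses the geometric-mean triangle intensity (Onnela)
    on weights normalized by the network maximum.
    """
    adj = np.asarray(G.adjacency if isinstance(G, BinaryGraph) else G, dtype=float)
    n = adj.shape[0]
    if n < 2:
        raise InputError("clustering undefined for n < 2")
    binary = (adj > 0).astype(float)
    deg = binary.sum(axis=1)
    if weighted and adj.max() > 0:
        w = np.cbrt(adj / adj.max())
        triangles = np.diag(w @ w @ w) / 2.0
    else:
        triangles = np.diag(binary @ binary @ binary) / 2.0
    denom = deg * (deg - 1) / 2.0
    coef = np.divide(
        triangles, denom, out=np.zeros(n), where=denom > 0
    )
    return float(coef.mean())


def auc_over_sparsity(
    values: Sequence[float], sparsities: Sequence[float] = DEFAULT_SPARSITY_GRID
) -> float:
    """Trapezoid integral of a metric's trajectory over the sparsity axis."""
    values = np.asarray(values, dtype=float)
    sparsities = np.asarray(sparsities, dtype=float)
    if len(sparsities) < 2:
        raise ParameterError("need at least two thresholds for an AUC")
    if np.any(np.diff(sparsities) <= 0):
        raise ParameterError("sparsity thresholds must be strictly ascending")
    if values.shape != sparsities.shape:
        raise ParameterError("values and thresholds must have the same length")
    return float(np.trapezoid(values, sparsities))


def topology_features(
    W,
    sparsities: Sequence[float] = DEFAULT_SPARSITY_GRID,
    *,
    subject_id: str = "",
    task: str = "",
    band: str = "",
    weighted: bool = False,
) -> TopologyFeatures:
    """Threshold sweep plus AUC integration for one connectivity matrix."""
    if isinstance(W, ConnectivityMatrix):
        subject_id = subject_id or W.subject_id
        task = task or W.task
        band = band or W.band.name
    per: dict[str, list[float]] = {m: [] for m in METRICS}
    for s in sparsities:
        g = proportional_threshold(W, s, binary=not weighted)
        per["global_efficiency"].append(global_efficiency(g, weighted=weighted))
        per["local_efficiency"].append(local_efficiency_avg(g, weighted=weighted))
        per["clustering"].append(clustering_avg(g, weighted=weighted))
    auc = {m: auc_over_sparsity(per[m], sparsities) for m in METRICS}
    return TopologyFeatures(
        sparsities=tuple(sparsities),
        per_threshold=per,
        auc=auc,
        subject_id=subject_id,
        task=task,
        band=band,
    )
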