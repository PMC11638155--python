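"""Patient-similarity population graph.

Nodes are subjects; edges connect clinically similar subjects.  Construction:
pairwise Euclidean distances on the processed feature matrix, a Gaussian RBF
kernel ``s_ij = exp(-d_ij^2 / (2 sigma^2))``, and rank-based sparsification
keeping only pairs whose similarity strictly exceeds a percentile (default
80th, i.e. the top 20% of candidate pairs) of the off-diagonal similarity
scores.  The graph is undirected with no self-loops; the edge index stores
each retained pair in both directions.

Because the kernel is a strictly decreasing function of distance and the
threshold is a percentile of the resulting scores, the edge set depends only
on the *ranking* of distances -- the bandwidth matters for exported similarity
values, not for connectivity.  The default bandwidth is the median heuristic
(median off-diagonal distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SimilarityGraph",
    "GraphSummary",
    "pairwise_euclidean",
    "median_bandwidth",
    "rbf_similarity",
    "threshold_edges",
    "graph_summary",
    "build_graph",
    "to_networkx",
]


@dataclass
class SimilarityGraph:
    similarity: np.ndarray           # n x n, symmetric, unit diagonal
    bandwidth: float                 # RBF sigma
    threshold: float                 # similarity cut value actually used
    percentile: float                # retention percentile requested
    edge_index: np.ndarray           # (E, 2) directed entries, no self-loops
    n_nodes: int


@dataclass
class GraphSummary:
    n_nodes: int
    n_edge_entries: int              # directed count (undirected pair -> 2)
    avg_degree: float
    n_isolated: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edge_entries": self.n_edge_entries,
            "avg_degree": self.avg_degree,
            "n_isolated": self.n_isolated,
        }


def pairwise_euclidean(values: np.ndarray) -> np.ndarray:
    """Dense Euclidean distance matrix between rows of ``values``."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    return squareform(pdist(values, metric="euclidean"))


def median_bandwidth(distances: np.ndarray) -> float:
    """Median-heuristic RBF bandwidth: median off-diagonal distance."""
    n = distances.shape[0]
    offdiag = distances[np.triu_indices(n, k=1)]
    sigma = float(np.median(offdiag))
    if sigma <= 0:
        raise ValueError("median off-diagonal distance is zero; "
                         "features are degenerate")
    return sigma


def rbf_similarity(distances: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian kernel ``exp(-d^2 / (2 sigma^2))``; unit diagonal, values in (0, 1]."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    distances = np.asarray(distances, dtype=float)
    return np.exp(-(distances ** 2) / (2.0 * bandwidth ** 2))


def threshold_edges(similarity: np.ndarray, percentile: float = 80.0
                    ) -> SimilarityGraph:
    """Percentile sparsification of a similarity matrix.

    The threshold is the given percentile (linear interpolation between order
    statistics) of the strict-upper-triangle scores -- the diagonal's trivial
    self-similarities are excluded from the population.  A pair becomes an
    edge only when its score is *strictly* above the threshold ("top 20%"
    retention semantics; ties at the threshold are dropped), and appears in
    the edge index in both directions.
    """
    similarity = np.asarray(similarity, dtype=float)
    n = similarity.shape[0]
    if similarity.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if not np.allclose(similarity, similarity.T):
        raise ValueError("similarity matrix must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    scores = similarity[iu, ju]
    threshold = float(np.percentile(scores, percentile))
    keep = scores > threshold
    if not np.any(keep):
        warnings.warn(
            "no pair exceeds the percentile threshold strictly; "
            "edge set is empty (all candidate scores may be tied)",
            stacklevel=2,
        )
    src = np.concatenate([iu[keep], ju[keep]])
    dst = np.concatenate([ju[keep], iu[keep]])
    edge_index = np.stack([src, dst], axis=1)
    order = np.lexsort((edge_index[:, 1], edge_index[:, 0]))
    edge_index = edge_index[order]
    # Median-heuristic bandwidth is recorded by build_graph; a graph built
    # directly from a similarity matrix has no intrinsic sigma.
    return SimilarityGraph(
        similarity=similarity, bandwidth=float("nan"), threshold=threshold,
        percentile=float(percentile), edge_index=edge_index, n_nodes=n)


def graph_summary(graph: SimilarityGraph) -> GraphSummary:
    """Node/edge counts, average degree (directed entries per node), isolates.

    Isolated nodes are reported but never removed from the dataset: the
    classifiers still receive their features (and, with self-loops, their own
    signal); only visualizations drop them.
    """
    n = graph.n_nodes
    entries = int(graph.edge_index.shape[0])
    connected = set(graph.edge_index.ravel().tolist())
    return GraphSummary(
        n_nodes=n,
        n_edge_entries=entries,
        avg_degree=entries / n if n else 0.0,
        n_isolated=n - len(connected),
    )


def build_graph(values: np.ndarray, percentile: float = 80.0,
                bandwidth: float | str = "median") -> SimilarityGraph:
    """Distance -> RBF similarity -> percentile threshold, in one call."""
    d = pairwise_euclidean(values)
    sigma = median_bandwidth(d) if bandwidth == "median" else float(bandwidth)
    s = rbf_similarity(d, sigma)
    graph = threshold_edges(s, percentile)
    graph.bandwidth = sigma
    return graph


def to_networkx(graph: SimilarityGraph, node_ids=None):
    """Undirected networkx view (for GraphML export or layout plots)."""
    import networkx as nx

    g = nx.Graph()
    ids = list(node_ids) if node_ids is not None else list(range(graph.n_nodes))
    g.add_nodes_from(ids)
    for i, j in graph.edge_index:
        if i < j:
            g.add_edge(ids[i], ids[j], weight=float(graph.similarity[i, j]))
    return g
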