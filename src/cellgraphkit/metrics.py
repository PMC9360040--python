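"""Rank-based marker scoring and evaluation statistics.

Marker scores: for every feature, cells are ranked by normalized value
(average ranks on ties), ranks are averaged within each cluster and the
cluster means are normalized to sum to 1 across clusters.  A score near 1
means the feature's high values concentrate in that cluster; scores near
1/P (P clusters) mean no specificity.

Evaluation statistics quantify how faithfully an embedding or a subsample
preserves graph structure:

* ACD — mean Euclidean distance of cells to their cluster centroid in
  embedding space (lower = tighter clusters);
* log2 cluster enrichment — per-cluster log2 ratio of a cluster's share
  among selected cells vs its overall share;
* non-zero-degree fraction — % of selected cells with at least one
  original-graph edge to another selected cell;
* KNN preservation — mean per-cell overlap between graph neighbours and
  embedding-space neighbours;
* cluster-similarity Spearman — per-cluster rank correlation between the
  graph-based and embedding-based cluster-similarity matrices (log2 with a
  +1 pseudo-count).

All functions are pure: inputs are never mutated.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .cluster import ClusterLabels, ClusterSimilarityMatrix, as_adjacency

__all__ = [
    "marker_scores",
    "average_centroid_distance",
    "cluster_enrichment",
    "nonzero_degree_fraction",
    "knn_preservation",
    "cluster_similarity_spearman",
]


def marker_scores(norm_values, labels: ClusterLabels) -> np.ndarray:
    """Features x clusters matrix of normalized mean ranks in [0, 1]."""
    x = np.asarray(norm_values, dtype=float)
    lab = labels.label
    if x.shape[0] != lab.shape[0]:
        raise ValueError("labels do not match the number of cells")
    p = labels.n_clusters
    sizes = np.bincount(lab, minlength=p)
    if (sizes == 0).any():
        raise ValueError("every cluster must be non-empty")
    ranks = stats.rankdata(x, axis=0)  # per-feature ranks across cells
    ind = np.zeros((lab.size, p))
    ind[np.arange(lab.size), lab] = 1.0
    mean_ranks = (ranks.T @ ind) / sizes  # features x clusters
    return mean_ranks / mean_ranks.sum(axis=1, keepdims=True)


def average_centroid_distance(coords, labels: ClusterLabels) -> float:
    """Mean distance of cells to their cluster centroid in the embedding."""
    coords = np.asarray(coords, dtype=float)
    lab = labels.label
    centroids = np.vstack(
        [coords[lab == c].mean(axis=0) for c in range(labels.n_clusters)]
    )
    return float(np.linalg.norm(coords - centroids[lab], axis=1).mean())


def cluster_enrichment(labels: ClusterLabels, selected_mask) -> np.ndarray:
    """Per-cluster log2(share among selected / share overall).

    A cluster absent from the selection yields -inf (flagged by a
    warning-free sentinel the caller can test with ``np.isneginf``).
    """
    mask = np.asarray(selected_mask, dtype=bool)
    if not mask.any():
        raise ValueError("selection is empty")
    lab = labels.label
    p = labels.n_clusters
    overall = np.bincount(lab, minlength=p) / lab.size
    sel = np.bincount(lab[mask], minlength=p) / mask.sum()
    with np.errstate(divide="ignore"):
        return np.log2(sel / overall)


def nonzero_degree_fraction(graph, selected_mask) -> float:
    """% of selected cells with >= 1 original-graph edge into the selection."""
    mask = np.asarray(selected_mask, dtype=bool)
    if not mask.any():
        raise ValueError("selection is empty")
    adj = as_adjacency(graph)
    sub = adj[mask][:, mask]
    deg = np.asarray((sub > 0).sum(axis=1)).ravel()
    return float(100.0 * (deg > 0).mean())


def knn_preservation(coords, graph, k: int | None = None) -> float:
    """Mean fraction of graph neighbours recovered among embedding
    neighbours (exact Euclidean search in the embedding)."""
    from .graph import NeighbourGraph

    if not isinstance(graph, NeighbourGraph):
        raise TypeError("knn_preservation needs the NeighbourGraph (per-cell lists)")
    coords = np.asarray(coords, dtype=float)
    if k is None:
        k = graph.k
    if k != graph.k:
        raise ValueError(f"k={k} must equal the graph's k={graph.k}")
    nn = NearestNeighbors(algorithm="auto", metric="euclidean")
    nn.fit(coords)
    _, emb_idx = nn.kneighbors(coords, n_neighbors=k + 1)
    fracs = np.empty(coords.shape[0])
    for i in range(coords.shape[0]):
        emb_set = set(emb_idx[i].tolist()) - {i}
        fracs[i] = len(emb_set.intersection(graph.knn_idx[i].tolist())) / k
    return float(fracs.mean())


def cluster_similarity_spearman(
    graph_sim: ClusterSimilarityMatrix, embed_sim: ClusterSimilarityMatrix
) -> np.ndarray:
    """Per-cluster Spearman rho between matched log2 similarity columns.

    Both matrices get a +1 pseudo-count before log2 (zeros are legitimate
    for disconnected cluster pairs).  Requires >= 3 clusters, below which
    rank correlation is degenerate.
    """
    a = graph_sim.sim
    b = embed_sim.sim
    if a.shape != b.shape:
        raise ValueError("similarity matrices differ in shape")
    p = a.shape[0]
    if p < 3:
        raise ValueError(f"need >= 3 clusters for rank correlation, got {p}")
    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    return np.array([stats.spearmanr(la[:, j], lb[:, j]).statistic for j in range(p)])
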