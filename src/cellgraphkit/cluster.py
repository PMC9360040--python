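"""Flat and hierarchical clustering of the cell-cell graph, plus embedding.

Leiden clustering is delegated to an established community-detection engine
(python-igraph + leidenalg) under a deterministic-given-seed contract.

Paris hierarchical clustering is implemented here from scratch.  It
agglomerates graph nodes under the node-pair sampling distance

    d(a, b) = p(a) p(b) / p(a, b)

where, for a weighted graph with total node-weight w = sum_i w_i (w_i the
weighted degree), p(a) = w_a / w is the probability that a random edge
endpoint lands in cluster a and p(a, b) = w_ab / w the probability that a
random edge joins a and b (w_ab the summed inter-cluster edge weight).  A
low distance means a and b share far more edge mass than chance.  The
distance is *reducible* — merging two clusters never makes them closer to a
third than the nearer of the pair was — so the nearest-neighbour-chain
algorithm reproduces exact greedy agglomeration at O(m log n) cost instead
of O(n^2): follow nearest neighbours until a reciprocal pair is found,
merge it, and continue from the remaining chain.

The resulting binary dendrogram can be cut into any k nested flat
partitions by splitting the k-1 highest merges top-down.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .graph import InitEmbedding, NeighbourGraph

__all__ = [
    "ClusterLabels",
    "Dendrogram",
    "ClusterSimilarityMatrix",
    "EngineUnavailableError",
    "leiden_cluster",
    "paris_dendrogram",
    "cut_dendrogram",
    "cluster_similarity_graph",
    "embed",
    "as_adjacency",
    "relabel_by_size",
]


class EngineUnavailableError(RuntimeError):
    """Requested pluggable engine is not installed/usable."""


@dataclass
class ClusterLabels:
    """Per-cell labels, contiguous 0..n_clusters-1, every cluster non-empty."""

    label: np.ndarray
    n_clusters: int
    method: str = "external"

    def __post_init__(self):
        self.label = np.asarray(self.label, dtype=np.int64)
        uniq = np.unique(self.label)
        if uniq.size != self.n_clusters or uniq[0] != 0 or uniq[-1] != self.n_clusters - 1:
            raise ValueError("labels must be contiguous 0..n_clusters-1, all non-empty")

    def __len__(self):
        return self.label.shape[0]


@dataclass
class Dendrogram:
    """Binary merge tree: row t = (left, right, height), new id = n + t.

    Leaves are 0..n-1 in scipy linkage id convention.  Heights are
    non-decreasing in merge order (merges are replayed in height order
    after the chain algorithm, which reducibility makes valid).
    Multi-component graphs yield per-component trees joined under synthetic
    roots at height +inf.
    """

    merges: np.ndarray  # (n-1, 3) float: left id, right id, height
    n_leaves: int

    def children(self) -> dict:
        return {
            self.n_leaves + t: (int(l), int(r))
            for t, (l, r, _) in enumerate(self.merges)
        }

    def leaves_under(self, node: int) -> np.ndarray:
        kids = self.children()
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(kids[v])
        return np.asarray(sorted(out))


@dataclass
class ClusterSimilarityMatrix:
    """P x P symmetric matrix of summed inter-cluster edge weights.

    Off-diagonal [p, q]: total weight of edges with one endpoint in p and
    the other in q.  Diagonal [p, p]: total within-cluster edge weight.
    """

    sim: np.ndarray

    @property
    def n_clusters(self):
        return self.sim.shape[0]


def as_adjacency(graph, symmetrize: bool = True) -> sparse.csr_matrix:
    """Coerce a NeighbourGraph or sparse/dense matrix to CSR adjacency."""
    if isinstance(graph, NeighbourGraph):
        return graph.to_sparse(symmetrize=symmetrize)
    a = sparse.csr_matrix(graph)
    if symmetrize:
        a = a.maximum(a.T)
    return a


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel so cluster 0 is the largest, 1 the next, etc. (stable)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=np.int64)


# ---------------------------------------------------------------------------
# Leiden
# ---------------------------------------------------------------------------


def leiden_cluster(graph, resolution: float = 1.0, seed: int = 0) -> ClusterLabels:
    """Leiden community detection on the symmetrized weighted graph."""
    import igraph as ig
    import leidenalg

    adj = as_adjacency(graph).tocoo()
    n = adj.shape[0]
    if n == 0 or adj.nnz == 0:
        raise ValueError("cannot cluster an empty graph")
    upper = adj.row < adj.col
    edges = list(zip(adj.row[upper].tolist(), adj.col[upper].tolist()))
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=adj.data[upper].tolist(),
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = relabel_by_size(np.asarray(part.membership))
    return ClusterLabels(labels, int(labels.max()) + 1, method="leiden")


# ---------------------------------------------------------------------------
# Paris
# ---------------------------------------------------------------------------


def _paris_component(adj: sparse.csr_matrix, nodes: np.ndarray, wtot: float):
    """NN-chain agglomeration of one connected component.

    Returns merges as (local_left, local_right, height) triples over a
    local id space where 0..m-1 are ``nodes`` and m+t is the cluster from
    merge t.  ``wtot`` is the global total node weight, so heights are
    comparable across components.
    """
    m = nodes.size
    # cluster state: node weight and neighbour->edge-weight maps
    weight = {}
    nbrs = {}
    sub = adj[nodes][:, nodes].tocoo()
    for i in range(m):
        weight[i] = 0.0
        nbrs[i] = {}
    for r, c, v in zip(sub.row, sub.col, sub.data):
        if r == c:
            continue
        weight[r] += v
        nbrs[r][c] = nbrs[r].get(c, 0.0) + v

    def dist(a, b):
        return weight[a] * weight[b] / (wtot * nbrs[a][b])

    merges = []
    alive = set(range(m))
    next_id = m
    chain = []
    while len(alive) > 1:
        if not chain:
            chain.append(min(alive))  # deterministic restart
        a = chain[-1]
        # nearest neighbour of a among current clusters (ties: smallest id)
        best, best_d = None, np.inf
        for b in sorted(nbrs[a]):
            d = dist(a, b)
            if d < best_d * (1.0 - 1e-12):
                best, best_d = b, d
        prev = chain[-2] if len(chain) >= 2 else None
        if prev is not None and prev in nbrs[a] and dist(a, prev) <= best_d * (
            1.0 + 1e-12
        ):
            # reciprocal nearest pair (ties count): merge a and prev
            best, best_d = prev, dist(a, prev)
            chain.pop()
            chain.pop()
            u, v = (best, a) if best < a else (a, best)
            h = best_d
            new = next_id
            next_id += 1
            weight[new] = weight[u] + weight[v]
            merged = {}
            for src in (u, v):
                for b, w in nbrs[src].items():
                    if b in (u, v):
                        continue
                    merged[b] = merged.get(b, 0.0) + w
            nbrs[new] = merged
            for b, w in merged.items():
                del nbrs[b][u if u in nbrs[b] else v]
                nbrs[b].pop(u, None)
                nbrs[b].pop(v, None)
                nbrs[b][new] = w
            del nbrs[u], nbrs[v], weight[u], weight[v]
            alive.discard(u)
            alive.discard(v)
            alive.add(new)
            merges.append((u, v, h))
        else:
            chain.append(best)
    return merges


def _replay_by_height(merges, m):
    """Re-emit chain merges in height order (greedy order).

    Reducibility guarantees each parent's height is >= its children's, so
    picking the smallest-height merge whose children already exist replays
    exact greedy agglomeration.  Ids are remapped accordingly.
    """
    pending = [(h, i, l, r) for i, (l, r, h) in enumerate(merges)]
    heapq.heapify(pending)
    available = set(range(m))
    remap = {i: i for i in range(m)}
    out = []
    deferred = []
    while pending:
        h, i, l, r = heapq.heappop(pending)
        if l in available and r in available:
            out.append((remap[l], remap[r], h))
            available.discard(l)
            available.discard(r)
            available.add(m + i)
            remap[m + i] = m + len(out) - 1
            for item in deferred:
                heapq.heappush(pending, item)
            deferred.clear()
        else:
            deferred.append((h, i, l, r))
    if deferred:  # cannot happen for a reducible distance; fail loudly
        raise RuntimeError("dendrogram replay failed; heights are not reducible")
    return out


def paris_dendrogram(graph) -> Dendrogram:
    """Hierarchical clustering of a weighted graph (see module docstring).

    Works per connected component; a graph of several components yields a
    forest joined under synthetic roots at height +inf.  A graph with zero
    edges is an error.
    """
    adj = as_adjacency(graph)
    n = adj.shape[0]
    if adj.nnz == 0:
        raise ValueError("graph has no edges; nothing to agglomerate")
    n_comp, comp = connected_components(adj, directed=False)
    wtot = float(adj.sum())  # == sum of weighted degrees

    all_merges = []  # global-id triples
    comp_roots = []
    next_id = n
    for ci in range(n_comp):
        nodes = np.flatnonzero(comp == ci)
        if nodes.size == 1:
            comp_roots.append(int(nodes[0]))
            continue
        local = _paris_component(adj, nodes, wtot)
        local = _replay_by_height(local, nodes.size)
        base = {}
        for i, g in enumerate(nodes):
            base[i] = int(g)
        for t, (l, r, h) in enumerate(local):
            gl = base[l]
            gr = base[r]
            all_merges.append((gl, gr, h))
            base[nodes.size + t] = next_id
            next_id += 1
        comp_roots.append(base[nodes.size + len(local) - 1])

    # join component roots under +inf merges
    while len(comp_roots) > 1:
        a = comp_roots.pop(0)
        b = comp_roots.pop(0)
        all_merges.append((a, b, np.inf))
        comp_roots.insert(0, next_id)
        next_id += 1
    merges = np.asarray(all_merges, dtype=float).reshape(-1, 3)
    return Dendrogram(merges=merges, n_leaves=n)


def cut_dendrogram(tree: Dendrogram, k: int) -> ClusterLabels:
    """Cut into exactly k clusters by splitting the highest merges.

    Top-down: start from the root and, k-1 times, split the active
    internal node with the greatest merge height (ties: latest merge
    first).  Cuts are nested by construction.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    heights = {n + t: h for t, (_, _, h) in enumerate(tree.merges)}
    root = n + tree.merges.shape[0] - 1
    # max-heap on (height, merge index)
    active = []
    heapq.heappush(active, (-heights[root], -(root - n), root))
    leaves_only = []
    kids = tree.children()
    while len(active) + len(leaves_only) < k and active:
        _, _, node = heapq.heappop(active)
        for ch in kids[node]:
            if ch < n:
                leaves_only.append(ch)
            else:
                heapq.heappush(active, (-heights[ch], -(ch - n), ch))
    groups = leaves_only + [node for _, _, node in active]
    labels = np.empty(n, dtype=np.int64)
    for gi, node in enumerate(groups):
        labels[tree.leaves_under(node) if node >= n else [node]] = gi
    labels = relabel_by_size(labels)
    return ClusterLabels(labels, int(labels.max()) + 1, method="paris-cut")


# ---------------------------------------------------------------------------
# cluster similarity
# ---------------------------------------------------------------------------


def cluster_similarity_graph(graph, labels: ClusterLabels) -> ClusterSimilarityMatrix:
    """Summed edge weight between every pair of clusters (diagonal: within)."""
    adj = as_adjacency(graph)
    lab = labels.label
    if lab.shape[0] != adj.shape[0]:
        raise ValueError(
            f"labels cover {lab.shape[0]} cells but graph has {adj.shape[0]}"
        )
    p = labels.n_clusters
    ind = sparse.csr_matrix(
        (np.ones(lab.size), (np.arange(lab.size), lab)), shape=(lab.size, p)
    )
    sim = np.asarray((ind.T @ adj @ ind).todense())
    sim = (sim + sim.T) / 2.0  # exact symmetry under float addition order
    sim[np.diag_indices(p)] /= 2.0  # within-cluster edges were counted twice
    return ClusterSimilarityMatrix(sim=sim)


# ---------------------------------------------------------------------------
# embedding engine contract
# ---------------------------------------------------------------------------


def embed(
    graph,
    init: InitEmbedding,
    engine: str = "umap",
    n_iter: int = 250,
    params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Run a pluggable 2D/3D layout engine on the neighbourhood graph.

    The engine receives the (symmetrized) graph and the initial coordinates
    unchanged; neighbours are never recomputed here.  ``n_iter = 0``
    returns the initial coordinates untouched.  An unavailable engine
    raises :class:`EngineUnavailableError` rather than silently falling
    back.
    """
    params = dict(params or {})
    adj = as_adjacency(graph)
    coords0 = np.asarray(init.coords, dtype=np.float64)
    if adj.shape[0] != coords0.shape[0]:
        raise ValueError("init coordinates do not match graph size")
    if n_iter == 0:
        return coords0.copy()
    if engine == "umap":
        try:
            from umap.umap_ import find_ab_params, simplicial_set_embedding
        except Exception as exc:  # pragma: no cover
            raise EngineUnavailableError(f"umap engine unavailable: {exc}") from exc
        a, b = find_ab_params(
            params.pop("spread", 2.0), params.pop("min_dist", 0.5)
        )
        out = simplicial_set_embedding(
            data=coords0,
            graph=adj.tocoo(),
            n_components=coords0.shape[1],
            initial_alpha=params.pop("initial_alpha", 1.0),
            a=a,
            b=b,
            gamma=params.pop("gamma", 1.0),
            negative_sample_rate=params.pop("negative_sample_rate", 5),
            n_epochs=int(n_iter),
            init=coords0,
            random_state=np.random.RandomState(seed),
            metric="euclidean",
            metric_kwds={},
            densmap=False,
            densmap_kwds={},
            output_dens=False,
        )
        emb = out[0] if isinstance(out, tuple) else out
        return np.asarray(emb, dtype=np.float64)
    if engine == "graph-tsne":
        raise EngineUnavailableError(
            "graph-tsne engine requires the sgtsnepi library, which is not "
            "installed"
        )
    raise EngineUnavailableError(f"unknown embedding engine {engine!r}")
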