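"""Independent oracles used by the test suite.

Everything here is deliberately naive — brute force, exhaustive
enumeration, closed forms — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import sparse


def brute_force_knn(coords, k):
    """All-pairs Euclidean KNN by full distance matrix."""
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    idx = np.argsort(d, axis=1, kind="stable")[:, :k]
    return idx, np.take_along_axis(d, idx, axis=1)


def full_pca_components(x, d):
    """Full-batch PCA components of centred x via eigendecomposition."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / x.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, ::-1][:, :d].T  # d x features


def principal_angles(a, b):
    """Principal angles (radians) between the row spaces of a and b."""
    qa, _ = np.linalg.qr(np.asarray(a, float).T)
    qb, _ = np.linalg.qr(np.asarray(b, float).T)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s, -1.0, 1.0))


def greedy_paris(adj, tie_rtol=1e-9):
    """Exhaustive greedy agglomeration under the node-pair sampling
    distance d(a,b) = (w_a * w_b) / (w_tot * w_ab): at every step merge the
    globally closest connected pair.  O(n^3); ground truth for NN-chain.

    Returns (merges, had_tie): when two candidate pairs are within
    ``tie_rtol`` of the minimum at any step the greedy dendrogram is not
    unique and exact height comparison is ill-posed.
    """
    adj = sparse.csr_matrix(adj)
    n = adj.shape[0]
    wtot = float(adj.sum())
    weight = {i: float(adj[i].sum()) for i in range(n)}
    dense = adj.toarray()
    edge = {}
    for i in range(n):
        for j in range(i + 1, n):
            if dense[i, j] > 0:
                edge[(i, j)] = float(dense[i, j])
    merges = []
    had_tie = False
    nxt = n
    alive = set(range(n))
    while len(alive) > 1 and edge:
        dists = {
            pair: weight[pair[0]] * weight[pair[1]] / (wtot * w)
            for pair, w in edge.items()
        }
        (u, v), h = min(dists.items(), key=lambda kv: (kv[1], kv[0]))
        if sum(1 for d in dists.values() if d <= h * (1 + tie_rtol)) > 1:
            had_tie = True
        merges.append((u, v, h))
        new = nxt
        nxt += 1
        weight[new] = weight[u] + weight[v]
        upd = {}
        for (a, b), w in edge.items():
            if u in (a, b) and v in (a, b):
                continue
            if a in (u, v) or b in (u, v):
                other = b if a in (u, v) else a
                key = (min(new, other), max(new, other))
                upd[key] = upd.get(key, 0.0) + w
            else:
                upd[(a, b)] = upd.get((a, b), 0.0) + w
        edge = upd
        alive.discard(u)
        alive.discard(v)
        alive.add(new)
    return merges, had_tie


def pcst_brute_force(adj, prizes, penalties):
    """Optimal PCST objective by enumerating connected node subsets."""
    adj = sparse.csr_matrix(adj)
    pen = sparse.csr_matrix(penalties)
    n = adj.shape[0]
    dense_adj = (adj.toarray() > 0).astype(int)
    dense_pen = pen.toarray()
    best = 0.0
    for r in range(1, n + 1):
        for nodes in itertools.combinations(range(n), r):
            sub = dense_adj[np.ix_(nodes, nodes)]
            # connectivity via BFS
            seen = {0}
            stack = [0]
            while stack:
                i = stack.pop()
                for j in range(len(nodes)):
                    if sub[i, j] and j not in seen:
                        seen.add(j)
                        stack.append(j)
            if len(seen) != len(nodes):
                continue
            from scipy.sparse.csgraph import minimum_spanning_tree

            cost = minimum_spanning_tree(
                sparse.csr_matrix(dense_pen[np.ix_(nodes, nodes)])
            ).sum()
            obj = prizes[list(nodes)].sum() - cost
            best = max(best, float(obj))
    return best


def atlas_connected_graphs(max_nodes=7, min_nodes=2):
    """All non-isomorphic connected graphs with min..max nodes (networkx
    Graph Atlas covers everything up to 7 nodes)."""
    import networkx as nx

    out = []
    for g in nx.graph_atlas_g()[1:]:
        if min_nodes <= g.number_of_nodes() <= max_nodes and g.number_of_edges():
            if nx.is_connected(g):
                out.append(g)
    return out


def nx_to_weighted_adj(g, weights=None):
    """Symmetric CSR adjacency from a networkx graph with given or unit
    edge weights (weights: dict edge->w or an iterable in edge order)."""
    import networkx as nx

    n = g.number_of_nodes()
    mapping = {v: i for i, v in enumerate(sorted(g.nodes()))}
    rows, cols, vals = [], [], []
    edges = sorted((min(mapping[a], mapping[b]), max(mapping[a], mapping[b])) for a, b in g.edges())
    if weights is None:
        weights = [1.0] * len(edges)
    for (a, b), w in zip(edges, weights):
        rows += [a, b]
        cols += [b, a]
        vals += [w, w]
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
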