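"""Dimension reduction and the cell-cell neighbourhood graph.

The reduction step is linear and streamed: incremental PCA on
standard-scaled library-size-normalized counts for RNA, or latent semantic
indexing (truncated SVD of the TF-IDF matrix, accumulated as a Gram matrix
over chunks) for ATAC.  The neighbourhood graph links each cell to its k
nearest neighbours (Euclidean) in the reduced space; raw distances are then
converted to edge weights in (0, 1] by the UMAP smooth-knn calibration: per
cell, ``w_i = exp(-(max(0, d_i - rho)) / sigma)`` with ``rho`` the distance
to the nearest neighbour and ``sigma`` chosen by bisection so the weights
sum to ``log2(k)``.

Two KNN backends are provided: ``"exact"`` (brute force, the test oracle)
and ``"ann"`` (an approximate nearest-neighbour-descent index).  The recall
diagnostic is the fraction of cells that find themselves in their own query
result before self-removal — always 1 for the exact backend.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from sklearn.cluster import MiniBatchKMeans
from sklearn.decomposition import PCA, IncrementalPCA
from sklearn.neighbors import NearestNeighbors

from .preprocess import (
    NormalizationParams,
    TfidfStats,
    compute_tfidf_stats,
    normalize_library_size,
    normalize_tfidf,
)
from .store import AssayStore, iter_chunks

__all__ = [
    "Scaler",
    "ReducedMatrix",
    "NeighbourGraph",
    "InitEmbedding",
    "fit_incremental_pca",
    "fit_streaming_lsi",
    "build_knn_graph",
    "smooth_edge_weights",
    "smooth_knn_row",
    "initial_embedding",
]

SD_FLOOR = 1e-8  # standard deviations below this are treated as 1


@dataclass
class Scaler:
    """Per-feature standard scaler fitted on the training cells."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, block: np.ndarray) -> np.ndarray:
        return (block - self.mean) / self.sd


@dataclass
class ReducedMatrix:
    """Cells x d coordinates plus everything needed to project new cells."""

    coords: np.ndarray
    method: str  # "pca" | "lsi"
    scaler: Scaler | None = None
    components: np.ndarray | None = None  # d x n_features loadings
    feat_mask: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def transform(self, block: np.ndarray) -> np.ndarray:
        """Project new cells (already normalized, HVG-subset) into this space."""
        if self.components is None:
            raise ValueError("this reduction does not carry loadings")
        x = block if self.scaler is None else self.scaler.transform(block)
        return x @ self.components.T


@dataclass
class NeighbourGraph:
    """Per-cell KNN indices, raw distances and smoothed edge weights."""

    knn_idx: np.ndarray  # (n, k) int
    knn_dist: np.ndarray  # (n, k) float, non-decreasing per row
    weights: np.ndarray | None = None  # (n, k) in (0, 1] after smoothing
    recall: float = 1.0
    k: int = 0

    @property
    def n_cells(self) -> int:
        return self.knn_idx.shape[0]

    def to_sparse(self, symmetrize: bool = True, use_weights: bool = True):
        """CSR adjacency; symmetrized by the fuzzy union w1 + w2 - w1*w2."""
        n = self.n_cells
        vals = self.weights if (use_weights and self.weights is not None) else None
        if vals is None:
            vals = np.ones_like(self.knn_dist)
        rows = np.repeat(np.arange(n), self.k)
        a = sparse.csr_matrix(
            (vals.ravel(), (rows, self.knn_idx.ravel())), shape=(n, n)
        )
        if not symmetrize:
            return a
        t = a.T.tocsr()
        return (a + t - a.multiply(t)).tocsr()


@dataclass
class InitEmbedding:
    """k-means centroids projected to 2D/3D; cells inherit their centroid."""

    centroids: np.ndarray  # c x d
    coords: np.ndarray  # n x dim
    cluster_of_cell: np.ndarray  # n


# ---------------------------------------------------------------------------
# dimension reduction
# ---------------------------------------------------------------------------


def _norm_block(blk, params):
    if params is None:
        return np.asarray(blk, dtype=float)
    return normalize_library_size(blk, params)


def _fit_scaler(store, feat_mask, train_mask, params, row_block):
    n_train = 0
    s1 = s2 = 0.0
    offset = 0
    for blk in iter_chunks(store, row_block):
        tm = train_mask[offset : offset + blk.shape[0]]
        offset += blk.shape[0]
        if not tm.any():
            continue
        x = _norm_block(blk[tm], params)[:, feat_mask]
        n_train += x.shape[0]
        s1 = s1 + x.sum(axis=0)
        s2 = s2 + (x**2).sum(axis=0)
    mean = s1 / n_train
    var = np.maximum(s2 / n_train - mean**2, 0.0)
    sd = np.sqrt(var)
    sd = np.where(sd < SD_FLOOR, 1.0, sd)
    return Scaler(mean=mean, sd=sd)


def fit_incremental_pca(
    store: AssayStore,
    feat_mask,
    d: int,
    train_mask=None,
    params: NormalizationParams | None = None,
    row_block: int | None = None,
    normalize: bool = True,
) -> ReducedMatrix:
    """Streamed PCA of standard-scaled, library-size-normalized counts.

    Scaling and components are fitted on the training cells only (all cells
    by default); every cell — trained on or not — is then transformed into
    the fitted space.  Blocks are streamed via :func:`iter_chunks`, so the
    full matrix is never materialised.  ``normalize=False`` skips the
    library-size step for stores that already hold normalized values.
    """
    feat_mask = np.asarray(feat_mask, dtype=bool)
    nf = int(feat_mask.sum())
    if d >= nf:
        raise ValueError(f"d={d} must be smaller than n selected features ({nf})")
    if not normalize:
        params = None
    elif params is None:
        params = NormalizationParams(log_transform=True)
    if train_mask is None:
        train_mask = np.ones(store.n_cells, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if int(train_mask.sum()) <= d:
        raise ValueError("need more than d training cells")

    scaler = _fit_scaler(store, feat_mask, train_mask, params, row_block)

    ipca = IncrementalPCA(n_components=d)
    buf = []
    buf_n = 0
    offset = 0
    for blk in iter_chunks(store, row_block):
        tm = train_mask[offset : offset + blk.shape[0]]
        offset += blk.shape[0]
        if not tm.any():
            continue
        x = scaler.transform(_norm_block(blk[tm], params)[:, feat_mask])
        buf.append(x)
        buf_n += x.shape[0]
        # partial_fit needs at least d rows per batch
        if buf_n >= max(d + 1, 16):
            ipca.partial_fit(np.concatenate(buf, axis=0))
            buf, buf_n = [], 0
    if buf_n:
        leftover = np.concatenate(buf, axis=0)
        if not hasattr(ipca, "components_") or leftover.shape[0] >= d:
            ipca.partial_fit(leftover)
        # else: components already fitted and the sliver is smaller than d;
        # IncrementalPCA cannot absorb it, so it is left out of training
        # (it is still transformed below).

    comps = ipca.components_
    coords = np.empty((store.n_cells, d))
    offset = 0
    for blk in iter_chunks(store, row_block):
        x = scaler.transform(_norm_block(blk, params)[:, feat_mask])
        coords[offset : offset + blk.shape[0]] = (x - ipca.mean_) @ comps.T
        offset += blk.shape[0]
    return ReducedMatrix(
        coords=coords,
        method="pca",
        scaler=Scaler(mean=scaler.mean + ipca.mean_ * scaler.sd, sd=scaler.sd),
        components=comps,
        feat_mask=feat_mask,
    )


def fit_streaming_lsi(
    store: AssayStore,
    feat_mask,
    d: int,
    stats: TfidfStats | None = None,
    row_block: int | None = None,
) -> ReducedMatrix:
    """Latent semantic indexing of the TF-IDF matrix, streamed.

    Accumulates the feature-space Gram matrix ``X^T X`` chunk by chunk and
    takes its top-d eigenvectors — exactly the right singular vectors of X,
    so the result matches a full truncated SVD and is fully deterministic.
    """
    feat_mask = np.asarray(feat_mask, dtype=bool)
    nf = int(feat_mask.sum())
    if d >= nf:
        raise ValueError(f"d={d} must be smaller than n selected features ({nf})")
    if stats is None:
        stats = compute_tfidf_stats(store)
    gram = np.zeros((nf, nf))
    offset = 0
    for blk in iter_chunks(store, row_block):
        x = normalize_tfidf(blk, stats, row_offset=offset)[:, feat_mask]
        gram += x.T @ x
        offset += blk.shape[0]
    evals, evecs = np.linalg.eigh(gram)
    top = evecs[:, ::-1][:, :d]  # descending eigenvalue order
    # deterministic sign: largest-magnitude loading positive
    signs = np.sign(top[np.argmax(np.abs(top), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    top = top * signs
    coords = np.empty((store.n_cells, d))
    offset = 0
    for blk in iter_chunks(store, row_block):
        x = normalize_tfidf(blk, stats, row_offset=offset)[:, feat_mask]
        coords[offset : offset + blk.shape[0]] = x @ top
        offset += blk.shape[0]
    return ReducedMatrix(
        coords=coords, method="lsi", components=top.T, feat_mask=feat_mask
    )


# ---------------------------------------------------------------------------
# KNN graph
# ---------------------------------------------------------------------------


class ExactKnnIndex:
    """Brute-force Euclidean index (sklearn); the oracle backend."""

    def __init__(self, coords, seed=0):
        self._nn = NearestNeighbors(algorithm="brute", metric="euclidean")
        self._nn.fit(np.asarray(coords))

    def query(self, coords, k):
        dist, idx = self._nn.kneighbors(coords, n_neighbors=k)
        return idx, dist


class AnnKnnIndex:
    """Approximate index via nearest-neighbour descent (pynndescent)."""

    def __init__(self, coords, seed=0):
        from pynndescent import NNDescent

        self._index = NNDescent(
            np.asarray(coords),
            metric="euclidean",
            n_neighbors=48,
            random_state=seed,
            n_jobs=1,
        )
        self._index.prepare()

    def query(self, coords, k):
        idx, dist = self._index.query(np.asarray(coords), k=k)
        return idx, dist


_BACKENDS = {"exact": ExactKnnIndex, "ann": AnnKnnIndex}


def save_index(index, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(index, fh)


def load_index(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)


def build_knn_graph(
    reduced: ReducedMatrix,
    k: int,
    backend: str = "exact",
    seed: int = 0,
    index_path=None,
    return_index: bool = False,
):
    """Query each cell for its k nearest neighbours (self excluded).

    Each cell is queried for k+1 neighbours; its own entry is dropped.  If
    an approximate backend misses the self-hit, the last neighbour is
    dropped instead and the miss counts against the recall diagnostic.
    The fitted index can be persisted (``index_path``) for later reuse,
    e.g. reference mapping.
    """
    coords = np.asarray(reduced.coords, dtype=np.float64)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells={n}, got {k}")
    if backend not in _BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {sorted(_BACKENDS)}")
    index = _BACKENDS[backend](coords, seed=seed)
    idx, dist = index.query(coords, k + 1)
    knn_idx = np.empty((n, k), dtype=np.int64)
    knn_dist = np.empty((n, k))
    hits = 0
    rows = np.arange(n)
    for i in rows:
        pos = np.flatnonzero(idx[i] == i)
        if pos.size:
            hits += 1
            keep = np.delete(np.arange(k + 1), pos[0])
        else:
            keep = np.arange(k)
        knn_idx[i] = idx[i, keep]
        knn_dist[i] = dist[i, keep]
    graph = NeighbourGraph(
        knn_idx=knn_idx, knn_dist=knn_dist, recall=hits / n, k=k
    )
    if index_path is not None:
        save_index(index, index_path)
    if return_index:
        return graph, index
    return graph


def smooth_knn_row(dists: np.ndarray, tol: float = 1e-5, max_iter: int = 64):
    """UMAP smooth-knn calibration for one cell's sorted distance row.

    Returns weights ``exp(-(max(0, d - rho)) / sigma)`` with ``rho`` the
    smallest distance and ``sigma`` bisected so the weights sum to
    ``log2(k)``.  If even ``sigma -> 0`` cannot bring the sum down to the
    target (several ties at ``rho``), sigma is clamped and the tied
    neighbours keep weight 1.
    """
    d = np.asarray(dists, dtype=float)
    k = d.size
    target = np.log2(k) if k > 1 else 1.0
    rho = d[0]
    gaps = np.maximum(d - rho, 0.0)

    def total(sigma):
        return float(np.exp(-gaps / sigma).sum())

    if np.allclose(gaps, 0.0):
        return np.ones(k)  # degenerate: all distances equal, clamp
    lo, hi = 0.0, 1.0
    while total(hi) < target and hi < 1e12:
        hi *= 2.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if mid == 0.0:
            break
        s = total(mid)
        if abs(s - target) < tol:
            break
        if s > target:
            hi = mid
        else:
            lo = mid
    sigma = max((lo + hi) / 2.0, 1e-300)
    w = np.exp(-gaps / sigma)
    return np.maximum(w, np.finfo(float).tiny)


def smooth_edge_weights(graph: NeighbourGraph) -> NeighbourGraph:
    """Convert raw KNN distances to weights in (0, 1], per-cell calibrated."""
    weights = np.vstack([smooth_knn_row(row) for row in graph.knn_dist])
    return replace(graph, weights=weights)


# ---------------------------------------------------------------------------
# initial embedding
# ---------------------------------------------------------------------------


def initial_embedding(
    reduced: ReducedMatrix, c: int | None = None, dim: int = 2, seed: int = 0
) -> InitEmbedding:
    """Informed initial coordinates for UMAP / graph t-SNE.

    Mini-batch k-means partitions the reduced space into ``c`` centroids
    (default ``min(100, n_cells // 10)``, at least 2); a second PCA reduces
    the c x d centroid matrix to c x dim; each cell inherits its centroid's
    projected coordinates, so co-clustered cells start at the same spot.
    """
    coords = np.asarray(reduced.coords)
    n = coords.shape[0]
    if c is None:
        c = max(2, min(100, n // 10))
    if not 2 <= c <= n:
        raise ValueError(f"need 2 <= c <= n_cells={n}, got c={c}")
    if dim not in (2, 3):
        raise ValueError(f"dim must be 2 or 3, got {dim}")
    if c == n:
        centroids = coords.copy()
        labels = np.arange(n)
    else:
        km = MiniBatchKMeans(
            n_clusters=c, random_state=seed, n_init=5, batch_size=1024
        )
        labels = km.fit_predict(coords)
        centroids = km.cluster_centers_
    ncomp = min(dim, centroids.shape[0], centroids.shape[1])
    pca = PCA(n_components=ncomp, svd_solver="full", random_state=seed)
    proj = pca.fit_transform(centroids)
    if ncomp < dim:  # degenerate centroid matrix; pad with zeros
        proj = np.hstack([proj, np.zeros((proj.shape[0], dim - ncomp))])
    return InitEmbedding(
        centroids=centroids, coords=proj[labels], cluster_of_cell=labels
    )
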