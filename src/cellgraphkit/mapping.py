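"""Reference-anchored KNN mapping of one dataset onto another.

Workflow: both datasets are reduced to the reference's highly variable
genes and each cell is rescaled so its HVG values sum to a common total
(1000 by default), neutralising library-composition shifts between
batches.  Optionally the target is CORAL-corrected — whitened with its own
feature covariance and recoloured with the reference's, so second-order
feature statistics match.  Targets are then projected through the
*reference's* scaler and PCA loadings (never refit) and queried against
the reference's saved neighbour index.  Each target-reference distance
``D`` becomes an edge weight ``W = 1 / (ln(D + 1) + 1)``, the basis for

* the unified graph: the reference graph spiked with target nodes, each
  tied to its top-m reference neighbours at a constant weight;
* per-reference mapping scores ``M_r = (sum of incoming W) / N_T``;
* label transfer: a target adopts a reference class when that class holds
  at least half of its total edge weight (and is the unique maximum),
  otherwise NA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.decomposition import PCA

from .graph import NeighbourGraph, Scaler, _BACKENDS

__all__ = [
    "RescaledMatrix",
    "CoralTransform",
    "MappingResult",
    "ReferenceSpace",
    "rescale_to_common_total",
    "coral_correct",
    "fit_reference",
    "map_cells",
    "map_datasets",
    "unified_graph",
    "mapping_scores",
    "transfer_labels",
]

EIG_FLOOR = 1e-8


@dataclass
class RescaledMatrix:
    """Cells x HVG values, every row summing to ``total``."""

    values: np.ndarray
    total: float
    hvg_ids: np.ndarray | None = None
    kept_cells: np.ndarray | None = None  # original indices of retained rows


@dataclass
class CoralTransform:
    cov_S: np.ndarray
    cov_T: np.ndarray
    A: np.ndarray
    shrinkage: float


@dataclass
class MappingResult:
    """Target -> reference KNN edges with distances and weights."""

    ref_idx: np.ndarray  # (N_T, k)
    dist: np.ndarray  # (N_T, k)
    weights: np.ndarray  # (N_T, k) in (0, 1]
    n_ref: int

    @property
    def N_T(self) -> int:
        return self.ref_idx.shape[0]

    @property
    def k(self) -> int:
        return self.ref_idx.shape[1]


@dataclass
class ReferenceSpace:
    """Frozen reference transform: scaler + PCA loadings + KNN index."""

    scaler: Scaler
    pca_mean: np.ndarray
    components: np.ndarray  # d x F
    coords: np.ndarray  # reference cells x d
    index: object
    hvg_ids: np.ndarray | None = None

    def project(self, scaled_block: np.ndarray) -> np.ndarray:
        return (scaled_block - self.pca_mean) @ self.components.T


def rescale_to_common_total(
    block, hvg_mask=None, total: float = 1000.0, cell_ids=None, hvg_ids=None
) -> RescaledMatrix:
    """Scale each cell so its sum over the HVG set equals ``total``.

    Cells whose HVG sum is zero cannot be rescaled; they are excluded with
    a warning naming the first offender (``kept_cells`` records survivors).
    """
    block = np.asarray(block, dtype=float)
    if hvg_mask is not None:
        block = block[:, np.asarray(hvg_mask, dtype=bool)]
    sums = block.sum(axis=1)
    bad = sums == 0
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        name = cell_ids[i] if cell_ids is not None else f"row {i}"
        warnings.warn(
            f"{int(bad.sum())} cell(s) have zero HVG totals (first: {name}); "
            "excluded from the rescaled matrix"
        )
    kept = np.flatnonzero(~bad)
    vals = total * block[kept] / sums[kept, None]
    return RescaledMatrix(
        values=vals,
        total=total,
        hvg_ids=None if hvg_ids is None else np.asarray(hvg_ids),
        kept_cells=kept,
    )


def _sym_power(c: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh((c + c.T) / 2.0)
    vals = np.maximum(vals, EIG_FLOOR)
    return (vecs * vals**power) @ vecs.T


def _scale_cols(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < EIG_FLOOR, 1.0, sd)
    return (x - mu) / sd


def coral_correct(
    S_resc: RescaledMatrix,
    T_resc: RescaledMatrix,
    shrinkage: float = 1.0,
    literal_form: bool = False,
    return_transform: bool = False,
):
    """CORAL domain-shift correction of the target towards the reference.

    Both matrices are standard-scaled per feature (each with its own
    statistics); feature covariances get a ridge ``shrinkage * I``; the
    alignment ``A = Cov(S)^{1/2} Cov(T)^{-1/2}`` whitens the target and
    recolours it with the reference covariance, so afterwards
    ``cov(T_corrected) ~= cov(S_scaled)``.  ``literal_form=True`` instead
    applies ``A = Cov(S)^{1/2} Cov(T)^{+1/2}`` (no covariance-matching
    guarantee; provided for comparison).  Returns the corrected target in
    the reference-aligned scaled feature space.
    """
    if S_resc.hvg_ids is not None and T_resc.hvg_ids is not None:
        if list(S_resc.hvg_ids) != list(T_resc.hvg_ids):
            diff = set(map(str, S_resc.hvg_ids)) ^ set(map(str, T_resc.hvg_ids))
            raise ValueError(f"HVG sets differ between reference and target: {sorted(diff)}")
    if S_resc.values.shape[1] != T_resc.values.shape[1]:
        raise ValueError("reference and target have different feature counts")
    s = _scale_cols(S_resc.values)
    t = _scale_cols(T_resc.values)
    f = s.shape[1]
    cov_s = np.cov(s, rowvar=False) + shrinkage * np.eye(f)
    cov_t = np.cov(t, rowvar=False) + shrinkage * np.eye(f)
    t_power = 0.5 if literal_form else -0.5
    a = _sym_power(cov_s, 0.5) @ _sym_power(cov_t, t_power)
    corrected = t @ a.T
    if return_transform:
        return corrected, CoralTransform(cov_S=cov_s, cov_T=cov_t, A=a, shrinkage=shrinkage)
    return corrected


def fit_reference(
    S_resc: RescaledMatrix, d: int = 25, backend: str = "exact", seed: int = 0
) -> ReferenceSpace:
    """Fit the reference transform chain: scaler -> PCA -> KNN index."""
    x = S_resc.values
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < EIG_FLOOR, 1.0, sd)
    scaler = Scaler(mean=mu, sd=sd)
    z = scaler.transform(x)
    d = min(d, z.shape[1] - 1, z.shape[0] - 1)
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(z)
    index = _BACKENDS[backend](coords, seed=seed)
    return ReferenceSpace(
        scaler=scaler,
        pca_mean=pca.mean_,
        components=pca.components_,
        coords=coords,
        index=index,
        hvg_ids=S_resc.hvg_ids,
    )


def map_cells(ref: ReferenceSpace, T_scaled: np.ndarray, k: int = 11) -> MappingResult:
    """Query target cells (already in the reference scaled space) for k
    reference neighbours; weights ``W = 1 / (ln(D + 1) + 1)``."""
    T_scaled = np.asarray(T_scaled, dtype=float)
    if T_scaled.shape[1] != ref.components.shape[1]:
        raise ValueError(
            f"target has {T_scaled.shape[1]} features; reference transform "
            f"expects {ref.components.shape[1]}"
        )
    proj = ref.project(T_scaled)
    idx, dist = ref.index.query(proj, k)
    dist = np.maximum(dist, 0.0)
    weights = 1.0 / (np.log(dist + 1.0) + 1.0)
    return MappingResult(
        ref_idx=np.asarray(idx, dtype=np.int64),
        dist=dist,
        weights=weights,
        n_ref=ref.coords.shape[0],
    )


def map_datasets(
    S_resc: RescaledMatrix,
    T_resc: RescaledMatrix,
    d: int = 25,
    k: int = 11,
    coral: bool = True,
    backend: str = "exact",
    seed: int = 0,
):
    """Convenience: fit the reference space and map the target through it.

    With ``coral`` the target is whitened/recoloured against the scaled
    reference before projection; otherwise the reference scaler is applied
    to the raw rescaled target.  Returns ``(ReferenceSpace, MappingResult)``.
    """
    # the reference PCA always sees the standard-scaled reference matrix
    ref = fit_reference(S_resc, d=d, backend=backend, seed=seed)
    if coral:
        # the reference scaler reproduces the z-space CORAL aligns to, so
        # the corrected matrix feeds the projection directly
        corrected = coral_correct(S_resc, T_resc)
        mapping = map_cells(ref, corrected, k=k)
    else:
        mapping = map_cells(ref, ref.scaler.transform(T_resc.values), k=k)
    return ref, mapping


def unified_graph(
    ref_graph: NeighbourGraph,
    mapping: MappingResult,
    top_m: int = 3,
    spike_weight: float = 1.0,
) -> sparse.csr_matrix:
    """Spike the reference graph with target nodes.

    Returns a symmetric (n_ref + N_T)^2 adjacency: the reference block is
    the untouched symmetrized reference graph; each target node carries
    exactly ``top_m`` edges to its nearest reference cells, all at
    ``spike_weight``.
    """
    if top_m > mapping.k:
        raise ValueError(f"top_m={top_m} exceeds mapping k={mapping.k}")
    n_ref = mapping.n_ref
    n_t = mapping.N_T
    ref_adj = ref_graph.to_sparse(symmetrize=True).tocoo()
    rows = list(ref_adj.row)
    cols = list(ref_adj.col)
    vals = list(ref_adj.data)
    for t in range(n_t):
        for j in range(top_m):
            r = int(mapping.ref_idx[t, j])
            rows.extend([n_ref + t, r])
            cols.extend([r, n_ref + t])
            vals.extend([spike_weight, spike_weight])
    n = n_ref + n_t
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def mapping_scores(
    mapping: MappingResult, multiplier: float = 1000.0, log_transform: bool = False
) -> np.ndarray:
    """Per-reference score: summed incoming target weights over N_T.

    References never hit by any target score 0.  With ``log_transform`` the
    reported value is ``ln(multiplier * M_r + 1)``.
    """
    if mapping.N_T == 0:
        raise ValueError("mapping contains no target cells")
    scores = np.zeros(mapping.n_ref)
    np.add.at(scores, mapping.ref_idx.ravel(), mapping.weights.ravel())
    scores /= mapping.N_T
    if log_transform:
        scores = np.log(multiplier * scores + 1.0)
    return scores


def transfer_labels(
    mapping: MappingResult, ref_labels, threshold: float = 0.5
) -> np.ndarray:
    """Weighted-majority label transfer; NA when no class dominates.

    A target adopts class c iff c's share of its total edge weight is at
    least ``threshold`` *and* is the unique maximum; otherwise the target
    gets None.
    """
    ref_labels = np.asarray(ref_labels)
    out = np.empty(mapping.N_T, dtype=object)
    for t in range(mapping.N_T):
        labs = ref_labels[mapping.ref_idx[t]]
        w = mapping.weights[t]
        total = w.sum()
        classes, inv = np.unique(labs, return_inverse=True)
        sums = np.zeros(classes.size)
        np.add.at(sums, inv, w)
        frac = sums / total
        top = np.argmax(frac)
        is_unique = (frac >= frac[top] - 1e-12).sum() == 1
        out[t] = classes[top] if (frac[top] >= threshold and is_unique) else None
    return out
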