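"""Synthetic single-cell data and toy graphs for testing and benchmarks.

Three generators emulate the structures the pipeline must handle, without
any external download:

* :func:`make_clustered_counts` — negative-binomial scRNA counts for a set
  of clusters (optionally including a rare one); each cluster up-regulates
  its own fraction of genes by a fixed fold, and per-cell library sizes
  vary log-normally;
* :func:`make_trajectory_counts` — a continuum: gene programs interpolate
  linearly between successive stage archetypes along pseudotime, so the
  KNN graph is dominated by pseudotime-adjacent cells;
* :func:`make_atac_counts` — binary-ish scATAC peak counts (clustered
  counts binarised at > 0 over an inflated feature space) for the
  TF-IDF / LSI path.

Every generator is a pure function of its parameters plus ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "SynthSpec",
    "make_clustered_counts",
    "make_trajectory_counts",
    "make_atac_counts",
    "make_toy_graph",
]


@dataclass
class SynthSpec:
    """Parameters of the clustered negative-binomial generator.

    ``nb_mean`` is the expected base count per gene per cell before
    library-size variation; ``nb_dispersion`` is the NB dispersion (larger
    = noisier); ``de_fraction`` of genes per cluster are up-regulated
    ``de_fold``-fold.  Library sizes vary log-normally with sigma 0.3.
    """

    n_cells: int = 1000
    n_genes: int = 500
    cluster_props: tuple = (0.5, 0.5)
    de_fraction: float = 0.1
    de_fold: float = 4.0
    nb_mean: float = 1.0
    nb_dispersion: float = 0.5
    libsize_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.cluster_props) - 1.0) > 1e-9:
            raise ValueError(
                f"cluster proportions must sum to 1, got {sum(self.cluster_props)}"
            )


def _nb_draw(rng, mean, dispersion):
    """Negative binomial with given mean matrix and dispersion."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def make_clustered_counts(spec: SynthSpec):
    """Clustered NB counts; returns (counts, labels) with labels 0..P-1."""
    rng = np.random.default_rng(spec.seed)
    p = len(spec.cluster_props)
    sizes = rng.multinomial(spec.n_cells, spec.cluster_props)
    labels = np.repeat(np.arange(p), sizes)
    base = spec.nb_mean * rng.lognormal(0.0, 0.5, size=spec.n_genes)
    n_de = int(round(spec.de_fraction * spec.n_genes))
    cluster_means = np.tile(base, (p, 1))
    for c in range(p):
        de_genes = rng.choice(spec.n_genes, size=n_de, replace=False)
        cluster_means[c, de_genes] *= spec.de_fold
    lib = rng.lognormal(0.0, spec.libsize_sigma, size=spec.n_cells)
    mean = cluster_means[labels] * lib[:, None]
    counts = _nb_draw(rng, mean, spec.nb_dispersion).astype(np.int32)
    return counts, labels


def make_trajectory_counts(
    n_cells: int = 1000,
    n_genes: int = 500,
    n_stages: int = 5,
    nb_mean: float = 1.0,
    nb_dispersion: float = 0.5,
    libsize_sigma: float = 0.3,
    seed: int = 0,
    return_programs: bool = False,
):
    """Continuum counts; returns (counts, pseudotime in [0, 1]).

    Stage archetypes are independent log-normal gene programs; a cell at
    pseudotime t draws NB counts around the linear interpolation of the
    two flanking archetypes, so expression changes smoothly along t.
    With ``return_programs`` the (n_stages x n_genes) archetype matrix is
    returned as a third element.
    """
    if n_stages < 2:
        raise ValueError(f"need n_stages >= 2, got {n_stages}")
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.0, 1.0, size=n_cells))
    stage_means = nb_mean * rng.lognormal(0.0, 0.7, size=(n_stages, n_genes))
    pos = t * (n_stages - 1)
    lo = np.minimum(pos.astype(int), n_stages - 2)
    frac = pos - lo
    mean = (1 - frac)[:, None] * stage_means[lo] + frac[:, None] * stage_means[lo + 1]
    lib = rng.lognormal(0.0, libsize_sigma, size=n_cells)
    counts = _nb_draw(rng, mean * lib[:, None], nb_dispersion).astype(np.int32)
    if return_programs:
        return counts, t, stage_means
    return counts, t


def make_atac_counts(spec: SynthSpec, feature_inflation: int = 4):
    """Binary-ish peak counts: clustered counts binarised at > 0 over an
    inflated feature space; returns (counts, labels)."""
    wide = SynthSpec(
        n_cells=spec.n_cells,
        n_genes=spec.n_genes * feature_inflation,
        cluster_props=spec.cluster_props,
        de_fraction=spec.de_fraction,
        de_fold=spec.de_fold,
        nb_mean=spec.nb_mean / feature_inflation,
        nb_dispersion=spec.nb_dispersion,
        libsize_sigma=spec.libsize_sigma,
        seed=spec.seed,
    )
    counts, labels = make_clustered_counts(wide)
    return (counts > 0).astype(np.int32), labels


def make_toy_graph(topology: str, *sizes, weight: float = 1.0) -> sparse.csr_matrix:
    """Symmetric weighted adjacency of a named toy topology.

    Topologies: ``clique(n)``, ``star(n_leaves)``, ``path(n)``,
    ``two-cliques-bridge(n1, n2)`` (bridge between node 0 of each clique),
    ``grid(rows, cols)`` (4-neighbour lattice).
    """
    edges = []
    if topology == "clique":
        (n,) = sizes
        nodes = n
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif topology == "star":
        (leaves,) = sizes
        nodes = leaves + 1
        edges = [(0, i) for i in range(1, nodes)]
    elif topology == "path":
        (n,) = sizes
        nodes = n
        edges = [(i, i + 1) for i in range(n - 1)]
    elif topology == "two-cliques-bridge":
        n1, n2 = sizes
        nodes = n1 + n2
        edges = [(i, j) for i in range(n1) for j in range(i + 1, n1)]
        edges += [
            (n1 + i, n1 + j) for i in range(n2) for j in range(i + 1, n2)
        ]
        edges.append((0, n1))
    elif topology == "grid":
        r, c = sizes
        nodes = r * c
        for i in range(r):
            for j in range(c):
                v = i * c + j
                if j + 1 < c:
                    edges.append((v, v + 1))
                if i + 1 < r:
                    edges.append((v, v + c))
    else:
        raise ValueError(f"unknown topology {topology!r}")
    rows = [u for u, v in edges] + [v for u, v in edges]
    cols = [v for u, v in edges] + [u for u, v in edges]
    vals = [weight] * (2 * len(edges))
    return sparse.csr_matrix((vals, (rows, cols)), shape=(nodes, nodes))
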