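"""End-to-end convenience workflows built from the module primitives.

These are thin orchestration helpers (normalize -> HVG -> PCA -> graph ->
Leiden) used by the CLI, the test-suite smoke tests and the reproduction
script; every step is an ordinary call into the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cluster, graph, metrics, preprocess, store, synth, topacedo

__all__ = [
    "GraphPipelineResult",
    "rna_graph_pipeline",
    "clustered_sketch_study",
    "trajectory_sketch_study",
]


@dataclass
class GraphPipelineResult:
    store: store.AssayStore
    hvg_mask: np.ndarray
    reduced: graph.ReducedMatrix
    knn: graph.NeighbourGraph
    labels: cluster.ClusterLabels


def rna_graph_pipeline(
    counts: np.ndarray,
    n_hvgs: int = 2500,
    d: int = 25,
    k: int = 21,
    resolution: float = 1.0,
    backend: str = "exact",
    seed: int = 0,
    chunk_rows: int = 2000,
) -> GraphPipelineResult:
    """Counts -> library-size norm -> HVGs -> PCA -> KNN graph -> Leiden."""
    st = store.AssayStore(np.asarray(counts), chunk_shape=(chunk_rows, counts.shape[1]))
    mean, var = preprocess.mean_var_stream(st)
    n_hvgs = min(n_hvgs, max(2, int((mean > 0).sum()) - 1))
    hvg = preprocess.select_hvgs(mean, var, n_top=n_hvgs)
    d_eff = min(d, int(hvg.selected_mask.sum()) - 1)
    reduced = graph.fit_incremental_pca(
        st, hvg.selected_mask, d=d_eff, row_block=chunk_rows
    )
    knn = graph.build_knn_graph(reduced, k=k, backend=backend, seed=seed)
    knn = graph.smooth_edge_weights(knn)
    labels = cluster.leiden_cluster(knn, resolution=resolution, seed=seed)
    return GraphPipelineResult(
        store=st, hvg_mask=hvg.selected_mask, reduced=reduced, knn=knn, labels=labels
    )


# ---------------------------------------------------------------------------
# sketching studies: fixed designs reused by the evaluation suite
# ---------------------------------------------------------------------------

# eight clusters, one rare at 1% abundance
CLUSTER_PROPS_8 = (0.30, 0.20, 0.15, 0.12, 0.10, 0.07, 0.05, 0.01)


def clustered_sketch_study(seed: int, n_cells: int = 5000, n_genes: int = 4000):
    """Sketch clustered data and report selection quality.

    Simulates ``n_cells`` over eight negative-binomial clusters (rarest at
    1%), builds the graph (2,500 HVGs, 25 PCA dims, k = 21), clusters with
    Leiden and runs the sketcher at a 1% max rate with default prizes and
    penalties.  Returns a dict with the non-zero-degree percentage of the
    sketch, per-cluster log2 enrichment on the true labels, and sizes.
    """
    spec = synth.SynthSpec(
        n_cells=n_cells, n_genes=n_genes, cluster_props=CLUSTER_PROPS_8, seed=seed
    )
    counts, truth = synth.make_clustered_counts(spec)
    res = rna_graph_pipeline(counts, n_hvgs=2500, d=25, k=21, seed=seed)
    sk = topacedo.subsample(
        res.knn, res.labels, res.reduced, max_rate=0.01, seed=seed
    )
    mask = np.zeros(n_cells, dtype=bool)
    mask[sk.selected] = True
    truth_labels = cluster.ClusterLabels(truth, len(CLUSTER_PROPS_8))
    return {
        "nonzero_degree_pct": metrics.nonzero_degree_fraction(res.knn, mask),
        "enrichment": metrics.cluster_enrichment(truth_labels, mask),
        "cluster_sizes": np.bincount(truth, minlength=len(CLUSTER_PROPS_8)),
        "n_selected": sk.n_selected,
        "sketch": sk,
        "pipeline": res,
    }


def trajectory_sketch_study(seed: int, n_cells: int = 3500, n_genes: int = 1000):
    """Sketch continuum (trajectory) data; same protocol, 5 stages."""
    counts, t = synth.make_trajectory_counts(
        n_cells, n_genes, n_stages=5, seed=seed
    )
    res = rna_graph_pipeline(counts, n_hvgs=n_genes, d=25, k=21, seed=seed)
    sk = topacedo.subsample(
        res.knn, res.labels, res.reduced, max_rate=0.01, seed=seed
    )
    mask = np.zeros(n_cells, dtype=bool)
    mask[sk.selected] = True
    return {
        "nonzero_degree_pct": metrics.nonzero_degree_fraction(res.knn, mask),
        "n_selected": sk.n_selected,
        "pseudotime": t,
        "sketch": sk,
        "pipeline": res,
    }
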