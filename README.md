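# cellgraphkit

Graph-centric, memory-frugal single-cell analysis for scRNA-seq and
scATAC-seq count matrices.

Modern single-cell experiments produce matrices of hundreds of thousands to
millions of cells, which most analysis toolkits hold fully in memory.
`cellgraphkit` instead streams the count matrix in compressed, chunked row
blocks through every step of a standard workflow — filtering,
normalisation, feature selection, linear dimension reduction, cell–cell
KNN graph construction — and then performs everything downstream
(clustering, embedding, subsampling, dataset mapping, evaluation) on the
graph, which is small even when the matrix is not.  It is written for
computational biologists who need atlas-style analyses on desk-scale
hardware, and for methods work that needs each pipeline stage available as
a tested, composable function.

## What it computes

**Normalisation.** For RNA, library-size scaling
`y_fc = S · x_fc / Σ_f' x_f'c` (default `S = 1000`), optionally `ln(1+y)`.
For ATAC peaks, TF-IDF:
`y_fc = (x_fc / n_Fc) · ln(1 + N_C / n_Cf)`, with `n_Fc` the number of
accessible peaks in cell *c*, `n_Cf` the number of cells where peak *f* is
accessible, and `N_C` the number of cells.

**Feature selection.** Highly variable genes by trend-corrected variance:
per-gene log-mean and log-variance, a lowess trend fitted through per-bin
representative genes, and ranking by observed − expected variance
(mitochondrial/ribosomal/cell-cycle gene families disqualified by default).
For ATAC, peak prevalence = TF-IDF column sums.

**Graph.** Incremental PCA (or streamed LSI for TF-IDF data) on standard-
scaled values; per-cell k nearest neighbours (Euclidean; exact or
approximate backend) with a recall diagnostic; distances calibrated to
edge weights in (0, 1] by the UMAP smooth-knn scheme — per cell,
`w_i = exp(−max(0, d_i − ρ)/σ)` with `ρ` the nearest-neighbour distance
and `σ` bisected so `Σ w_i = log2(k)`.

**Clustering.** Leiden (delegated to leidenalg) and Paris hierarchical
clustering, implemented here via the nearest-neighbour-chain algorithm
under the node-pair sampling distance `d(a,b) = p(a)p(b)/p(a,b)`; the
binary dendrogram cuts into any k nested flat partitions in milliseconds.

**TopACeDo sketching.** Per-node n-neighbourhood degree (NND) and
neighbourhood connectedness (NC) set per-cluster sampling rates; seed
cells are chosen by k-means sub-clustering; a prize-collecting Steiner
tree (seed prize 10; edge penalty `E_p = E_cm · E_bw^(−E_w)`, defaults
`E_cm = 1`, `E_bw = 10`) connects the seeds so the sketch covers every
cluster — rare ones included — and stays internally connected.

**Reference mapping.** Cells rescaled to a common total (1000) over the
reference's HVGs; optional CORAL correction
(`A = Cov(S)^{1/2} · Cov(T)^{−1/2}`, whiten-then-recolour) aligns target
covariance to the reference; targets are projected through the reference's
frozen scaler/PCA and queried against its saved KNN index.  Edge weights
`W_rt = 1/(ln(D_rt + 1) + 1)` drive unified-graph embedding, per-reference
mapping scores `M_r = Σ_t W_rt / N_T`, and ≥ 50 % weighted-majority label
transfer.

**Evaluation.** Rank-based marker scores; average centroid distance (ACD);
log2 cluster enrichment; non-zero-degree fraction of a selection; KNN
preservation of an embedding; per-cluster Spearman correlation of
cluster-similarity matrices.

## Worked example

```python
import numpy as np
from cellgraphkit import synth, pipeline, topacedo, metrics, cluster

spec = synth.SynthSpec(
    n_cells=2000, n_genes=1000,
    cluster_props=(0.35, 0.25, 0.2, 0.12, 0.07, 0.01),  # one rare cluster
    seed=0,
)
counts, truth = synth.make_clustered_counts(spec)

res = pipeline.rna_graph_pipeline(counts, n_hvgs=600, d=20, k=15, seed=0)
print(f"graph: {res.knn.n_cells} cells, k={res.knn.k}, recall={res.knn.recall:.2f}")
print(f"Leiden found {res.labels.n_clusters} clusters")

from sklearn.metrics import adjusted_rand_score
print(f"ARI vs simulated labels: {adjusted_rand_score(truth, res.labels.label):.3f}")

sk = topacedo.subsample(res.knn, res.labels, res.reduced, max_rate=0.02, seed=0)
mask = np.zeros(2000, bool); mask[sk.selected] = True
print(f"sketch: {sk.n_selected} cells ({sk.seeds.size} seeds)")
print(f"non-zero-degree fraction: {metrics.nonzero_degree_fraction(res.knn, mask):.1f}%")
enr = metrics.cluster_enrichment(cluster.ClusterLabels(truth, 6), mask)
print("log2 enrichment by true cluster:", np.round(enr, 2))
```

Output:

```
graph: 2000 cells, k=15, recall=1.00
Leiden found 6 clusters
ARI vs simulated labels: 1.000
sketch: 38 cells (21 seeds)
non-zero-degree fraction: 100.0%
log2 enrichment by true cluster: [ 0.02 -0.41  0.09  0.18 -0.32  2.19]
```

Reading the numbers: recall 1.00 means every cell found itself in its own
KNN query (the exact backend guarantees this); Leiden recovers the six
simulated populations perfectly (adjusted Rand index 1.0); the 2 % sketch
keeps 38 of 2000 cells, every one of them connected to another sketched
cell (non-zero-degree 100 %); and the rarest cluster (1 % of cells) is
over-represented 2.19 log2-fold in the sketch while the two largest
clusters shrink — the behaviour that distinguishes topology-aware
sketching from random downsampling.

The same workflow is scriptable from the shell:

```sh
cgk synth --preset clusters --n-cells 2000 --out data/
cgk import --in data/matrix.mtx --format mtx --out store/
cgk graph --store store/ --dims 20 --k 15 --out graphdir/
cgk subsample --graphdir graphdir/ --labels graphdir/labels.tsv --out sketch.tsv
```

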