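# Methods

This note documents the models and procedures implemented in
`cellgraphkit`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not establish about real data.

## Chunked storage and streaming

Count matrices are held cells-as-rows, dense, in compressed chunked Zarr
arrays (default chunk 2000 × 2000; the chunk size trades I/O speed against
peak memory and is freely configurable).  Every statistic that feeds a
transform (library sizes per cell, TF-IDF document frequencies, per-gene
means and variances, the PCA scaler) is accumulated in a single streaming
pass over row blocks, and per-block transforms use only those global
statistics.  Consequently results are exactly independent of the chunking
— the suite checks block sizes 1, 7 and n against the in-memory
computation at 1e-10.  Indices are 0-based internally and 1-based only in
Matrix Market I/O.  Multi-assay experiments store one matrix + feature
table per assay under a shared cell table, with a designated default
assay.

## Cell filtering

`auto_filter_cells` fits a normal distribution to any numeric per-cell
attribute by maximum likelihood (sample mean/SD) and removes cells outside
the [x, 1−x] quantile band (default x = 0.01, two-sided).  A zero-variance
attribute keeps every cell and warns rather than failing: a degenerate fit
is a data property, not a usage error.

## Normalisation

Library-size scaling to S = 1000 per cell (optionally ln(1+y)); TF-IDF for
peak matrices as `y_fc = (x_fc / n_Fc) · ln(1 + N_C / n_Cf)`.  Natural
logarithms are used throughout the package.  TF-IDF statistics are always
global (whole-matrix), never per-chunk.  A cell with zero counts (RNA) or
zero accessible peaks (ATAC) is reported by id and treated as an error —
silent zero-filling would propagate NaNs into the reduction.

## Highly variable genes

Per-gene means and variances of normalized values are log-transformed.
Genes are split into `n_bins = 20` equal-count bins on log-mean
(equal-count rather than equal-width, which can produce empty bins); one
representative per bin anchors a lowess trend (span 0.4, 3 robustifying
iterations; prediction by linear interpolation between fitted points).
The representative is the bin's lowest-variance gene by default — anchoring
the trend to the quietest genes per expression stratum gives a baseline
that other genes exceed by genuine variability — with
`bin_pick="lowest_mean"` available as an alternative reading.  Corrected
variance = observed − expected (log scale); the top `n_top` genes win,
after optional mean/variance constraints and after disqualifying
mitochondrial (MT-), ribosomal (RPS/RPL/MRPS/MRPL) and a short cell-cycle
panel — families that track technical covariates more than identity.  The
list is configurable and deliberately minimal.

## Dimension reduction

RNA: scikit-learn IncrementalPCA over standard-scaled blocks (SDs below
1e-8 are clipped to 1).  Scaling and components are fitted on the training
cells only (all cells by default; any subset via `train_mask`), then every
cell is transformed.  A trailing block smaller than d cannot be absorbed
by an incremental update and is left out of training (it is still
transformed).  The streamed fit equals full-batch PCA exactly for
single-chunk data, and recovers the full-batch subspace to principal
angles < 1e-3 when d matches the data's effective rank — the acceptance
test uses exactly rank-d data for this reason; on generic full-rank noise
the incremental subspace differs from batch PCA by design of the
algorithm, not by an implementation fault.

ATAC: streamed LSI.  The feature-space Gram matrix X^T X of the TF-IDF
matrix is accumulated chunk-wise and eigendecomposed; the top-d
eigenvectors are the exact right singular vectors of X, so the result
matches a full truncated SVD, is deterministic (no randomised solver), and
needs one pass plus an F × F matrix — fine for feature counts up to a few
tens of thousands.  Component signs are fixed by making each component's
largest-magnitude loading positive.

## Neighbourhood graph

k nearest neighbours (Euclidean) in the reduced space; default k = 21 for
de-novo analysis, k = 11 for reference mapping.  Backends: `exact`
(brute force; the oracle in every test) and `ann` (pynndescent
nearest-neighbour descent, graph degree 48, seeded).  Each cell queries
k+1 neighbours and drops itself; if an approximate backend misses the
self-hit the last neighbour is dropped instead and the miss counts against
the *recall* diagnostic (defined pre-self-removal).  Distances are
converted to weights by the UMAP smooth-knn calibration with local
connectivity 1: ρ = nearest distance, σ bisected (tolerance 1e-5, ≤ 64
iterations) so weights sum to log2(k); ties at ρ keep weight 1 and the
degenerate all-equal row clamps to all-ones.  Directed weights are stored;
consumers needing an undirected graph get the fuzzy union
w∪ = w1 + w2 − w1·w2.

The initial embedding for layout engines is informed rather than random:
mini-batch k-means (c = min(100, n/10) centroids by default) in the
reduced space, PCA of the c × d centroid matrix to 2 or 3 dimensions, and
every cell inherits its centroid's projected coordinates.

## Clustering

Leiden is delegated to leidenalg (RB-configuration objective, resolution
parameter, seeded, labels relabelled by decreasing size).  Paris is
implemented from scratch: with w_i the weighted degree, w the total
weight, p(a) = w_a/w and p(a,b) = w_ab/w, clusters merge greedily under
the distance d(a,b) = p(a)p(b)/p(a,b).  Because this distance is
*reducible* (the mediant inequality: merging two clusters never brings the
union closer to a third than the nearer of the pair), the
nearest-neighbour-chain algorithm reproduces exact greedy agglomeration at
near-linear cost; the chain's out-of-order merges are replayed in height
order afterwards, which reducibility makes valid.  Ties (e.g. several
leaves on one hub, whose distances are structurally equal) make the greedy
dendrogram non-unique; the implementation breaks them deterministically by
smallest cluster id, and the oracle tests compare exact heights only on
tie-free instances.  Multi-component graphs yield per-component trees
joined under synthetic roots at +∞.  Cuts are top-down — split the active
node with the greatest merge height, k−1 times — so cut(k) always refines
cut(k−1).  Paris runs on the symmetrized fuzzy-union weights.

Cluster-similarity matrices sum edge weights between every pair of
clusters; the diagonal counts each within-cluster edge once.

The 2D/3D layout engine is pluggable and receives the graph and the
initial coordinates unchanged (neighbours are never recomputed).  `umap`
calls the simplicial-set embedding directly (defaults min_dist 0.5,
spread 2.0); `n_iter = 0` returns the initial coordinates; an unavailable
engine (e.g. graph t-SNE, whose library is not a dependency) raises a
capability error instead of silently substituting.

## TopACeDo sketching

Node scores: NND (n-step summed degree, default n = 2 — one step measures
immediate density, two steps the density of the surrounding region) and NC
(summed Jaccard overlap of raw neighbour lists along each edge; on a
triangle each pair shares one of three list members, giving J = 1/3).
Per-cluster medians of both are rescaled to [1, 2] across clusters and the
sampling rate is `clip(base_rate/(s(nnd)·s(nc)), min_rate, max_rate)` —
any form monotone decreasing in both scores satisfies the intent; this one
is the simplest, and `base_rate` defaults to `max_rate` so the sparsest
cluster samples at the cap (defaults: max 1 %, min 0.1 %).  Quotas are at
least one cell per cluster.  Seeds are the medoids of a per-cluster
k-means sub-clustering into quota-many groups, so they tile each cluster.

The PCST instance gives every seed prize 10 and every edge penalty
`E_cm · E_bw^(−E_w)` (defaults 1 and 10): strong edges are cheap, so the
tree follows the manifold's backbone.  The solver builds the classic
metric-closure Steiner approximation (multi-source shortest paths between
seeds, MST of the seed-to-seed closure, expansion to real paths, re-MST)
and then strong-prunes the candidate tree from every seed root, keeping
the best objective Σ prizes − Σ penalties.  On tree graphs this is exactly
optimal (verified against exhaustive subset enumeration); on general small
graphs it stays within factor 2 of the optimum in the suite's enumeration.
An exact solver (`run_pcst_exact`) ships for instances up to 15 nodes.

Two orchestration guards keep the sketch contract airtight: if pruning
ever empties a cluster, that component's unpruned candidate tree is used
instead; and a component whose tree is a single node (one seed, nothing
worth connecting) gets that cell's strongest neighbour added, so every
sketched cell has non-zero degree inside the sketch without breaking
per-component connectivity.

## Reference mapping

Both datasets are reduced to the reference's HVGs and rescaled so each
cell's HVG values sum to 1000 — composition shifts between technologies
(e.g. ribosomal capture differences) largely cancel, under the usual
assumption that the batch effect is orthogonal to the heterogeneity the
HVGs encode.  CORAL correction standard-scales each matrix per feature
with its own statistics, adds a ridge of 1 to each covariance (matrix
square roots via symmetric eigendecomposition, eigenvalue floor 1e-8), and
applies A = Cov(S)^{1/2} Cov(T)^{−1/2} — whitening the target and
recolouring it with the reference covariance, which is the transform whose
defining property cov(T_corrected) ≈ cov(S) the tests verify.  The
literal variant with both exponents +1/2 is available behind
`literal_form=True` for comparison; it does not match covariances and is
not the default.  Targets are projected with the reference's frozen scaler
and PCA loadings (never refit) and queried against the reference's saved
index.

Distances become weights W = 1/(ln(D+1)+1) (W = 1 iff D = 0).  The unified
graph spikes the untouched reference graph with one node per target, each
carrying exactly top_m = 3 edges at constant weight 1; unified embeddings
run the engine for 100 iterations with targets initialised at the mean of
their top-m reference neighbours' initial coordinates.  Mapping scores
M_r = Σ_t W_rt / N_T (optionally ln(1000·M+1)).  Label transfer sums W per
reference class over all k neighbours and assigns the class holding ≥ 50 %
of total weight when it is also the unique maximum; exact ties and
sub-threshold maxima give NA.

## Markers and evaluation statistics

Marker scores rank each feature's normalized values across cells (average
ranks on ties — the only reading under which per-cluster mean ranks and
the [0, 1] normalisation cohere; ranking within cells instead would erase
the cluster signal), average the ranks per cluster and normalise the
cluster means to sum to 1.  ACD is the mean distance to the own-cluster
centroid in embedding space.  Log2 enrichment compares a cluster's share
among selected cells to its overall share (−∞ sentinel for clusters absent
from a selection).  Non-zero-degree fraction restricts the original graph
to the selection.  KNN preservation compares graph neighbours with exact
Euclidean neighbours in the embedding.  Cluster-similarity Spearman
correlates matched columns of the two P × P similarity matrices after
log2(x+1) — the pseudo-count keeps legitimately zero (disconnected)
entries finite — and requires P ≥ 3, below which rank correlation is
degenerate.  All metrics are pure functions.

## Synthetic data

`make_clustered_counts` draws negative-binomial counts (parameterised by
mean and dispersion; Var = m + dispersion·m²) around per-cluster mean
programs: a shared log-normal base expression, with each cluster
up-regulating its own `de_fraction` (default 10 %) of genes by a fixed
fold (default 4), multiplicative log-normal library sizes (σ = 0.3), and
multinomial cluster sizes.  `make_trajectory_counts` interpolates
independent log-normal stage archetypes linearly along pseudotime.
`make_atac_counts` binarises clustered counts over an inflated feature
space.  All generators are pure functions of their parameters and seed.

What these emulate: overdispersed counts, library-size variation, rare
populations, smooth state continua, and near-binary accessibility.  What
they do not: ambient RNA, doublets, batch-specific dropout structure,
zero-inflation beyond NB, or realistic gene-gene correlation within a
cluster (genes are conditionally independent given the cluster).  Passing
tests therefore demonstrate correctness of the algorithms under clean,
identifiable structure — not robustness to every artefact of real
libraries.

## Study designs fixed in the evaluation suite

* Sketch connectivity: clustered runs use 5,000 cells over eight clusters
  (30/20/15/12/10/7/5/1 %), 4,000 genes with 2,500 HVGs, 25 PCA
  dimensions, k = 21, 1 % max sampling rate; trajectory runs use 3,500
  cells, 5 stages, 1,000 genes, the same graph settings.  Ten simulation
  seeds each.
* Two-batch mapping: 1,500 cells, three clusters (40/35/25 %), 600 genes
  with 300 HVGs, de_fraction 0.05 at fold 3, and a per-feature
  multiplicative distortion drawn log-uniformly from [0.25, 4] — a strong
  but realistic batch effect; moderate cluster margins make the benefit of
  covariance alignment visible while the empirical covariances stay
  well-conditioned (5 cells per feature).
* The enrichment-direction study uses 2,000 cells over abundances
  40/20/15/10/8/4/2/1 % at a 2 % rate, ten seeds.

These sizes keep the whole suite to a few minutes while leaving every
claim at a scale where the measured quantity is stable across seeds.

## Known limitations

* Dense chunk storage: a very sparse atlas pays the dense-row memory cost
  per chunk (compression recovers the disk cost, not the RAM cost of a
  single block).
* The PCST solver is a constant-factor approximation on cyclic graphs;
  the factor-2 bound is verified only on small enumerable instances.
* LSI's Gram-matrix route is quadratic in the feature count; beyond ~30k
  features a randomised sketch would be preferable.
* CORAL is a linear (second-moment) correction; nonlinear batch effects
  are out of scope, as are bidirectional integration methods.
* Paris dendrograms on tied graphs are one of several equally valid
  trees; downstream cuts are stable but not canonical there.
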