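import numpy as np
import pytest
from _oracles import brute_force_knn, full_pca_components, principal_angles

from cellgraphkit import graph, preprocess, store
from cellgraphkit.preprocess import NormalizationParams


def _normalized(counts, feat_mask, params):
    norm = preprocess.normalize_library_size(counts.astype(float), params)
    return norm[:, feat_mask]


class TestIncrementalPca:
    params = NormalizationParams(S=1000, log_transform=True)

    def _setup(self, rng, n=100, f=20):
        counts = rng.integers(1, 40, size=(n, f)).astype(float)
        st = store.AssayStore(counts)
        mask = np.ones(f, dtype=bool)
        return counts, st, mask

    def test_single_chunk_matches_full_pca(self, rng):
        counts, st, mask = self._setup(rng)
        red = graph.fit_incremental_pca(st, mask, d=5, params=self.params, row_block=100)
        x = _normalized(counts, mask, self.params)
        xs = (x - x.mean(0)) / np.where(x.std(0) < 1e-8, 1, x.std(0))
        oracle = full_pca_components(xs, 5)
        assert principal_angles(red.components, oracle).max() < 1e-6

    def test_training_mean_maps_to_origin(self, rng):
        counts, st, mask = self._setup(rng)
        red = graph.fit_incremental_pca(st, mask, d=5, params=self.params, row_block=100)
        mean_vec = _normalized(counts, mask, self.params).mean(axis=0, keepdims=True)
        assert np.abs(red.transform(mean_vec)).max() < 1e-8

    def test_chunked_close_to_full_batch(self, rng):
        # rank-5 data: the d=5 streamed fit can shed nothing, so the
        # incremental subspace must coincide with the full-batch one
        u = rng.normal(size=(500, 5))
        v = rng.normal(size=(5, 50))
        x = u @ np.diag([40.0, 25.0, 15.0, 8.0, 5.0]) @ v
        x -= x.min()  # keep the store's non-negativity contract
        st = store.AssayStore(x)
        mask = np.ones(50, dtype=bool)
        red = graph.fit_incremental_pca(st, mask, d=5, row_block=7, normalize=False)
        z = x.astype(float)
        zs = (z - z.mean(0)) / np.where(z.std(0) < 1e-8, 1, z.std(0))
        oracle = full_pca_components(zs, 5)
        assert principal_angles(red.components, oracle).max() < 1e-3

    def test_train_subset_transforms_all(self, rng):
        counts, st, mask = self._setup(rng)
        train = np.zeros(100, dtype=bool)
        train[:60] = True
        red = graph.fit_incremental_pca(
            st, mask, d=4, train_mask=train, params=self.params, row_block=100
        )
        assert red.coords.shape == (100, 4)
        assert np.isfinite(red.coords).all()

    def test_d_too_large_raises(self, rng):
        _, st, mask = self._setup(rng)
        with pytest.raises(ValueError, match="d="):
            graph.fit_incremental_pca(st, mask, d=20, params=self.params)


class TestStreamingLsi:
    def test_rank1_energy(self):
        # binary rank-1-ish pattern: one shared accessibility program
        base = np.array([1, 1, 1, 0, 0, 0, 1, 0], dtype=float)
        x = np.tile(base, (20, 1))
        st = store.AssayStore(x)
        red = graph.fit_streaming_lsi(st, np.ones(8, bool), d=2, row_block=6)
        energy = (red.coords**2).sum(axis=0)
        assert energy[0] / energy.sum() > 0.99

    def test_duplicated_cells_identical_coords(self, rng):
        x = (rng.random((15, 10)) < 0.5).astype(float)
        x[x.sum(axis=1) == 0, 0] = 1
        x[7] = x[3]
        st = store.AssayStore(x)
        red = graph.fit_streaming_lsi(st, np.ones(10, bool), d=3)
        assert np.allclose(red.coords[7], red.coords[3], atol=1e-10)

    def test_two_blocks_linearly_separable(self, rng):
        a = np.zeros((30, 20))
        a[:15, :10] = 1.0
        a[15:, 10:] = 1.0
        flip = rng.random((30, 20)) < 0.05
        x = np.clip(a + flip, 0, 1)
        st = store.AssayStore(x)
        red = graph.fit_streaming_lsi(st, np.ones(20, bool), d=2)
        labels = np.repeat([0, 1], 15)
        from sklearn.linear_model import LogisticRegression

        acc = LogisticRegression().fit(red.coords, labels).score(red.coords, labels)
        assert acc == 1.0

    def test_chunking_invariance(self, rng):
        x = (rng.random((25, 12)) < 0.4).astype(float)
        x[x.sum(axis=1) == 0, 0] = 1
        st = store.AssayStore(x)
        r1 = graph.fit_streaming_lsi(st, np.ones(12, bool), d=3, row_block=25)
        r7 = graph.fit_streaming_lsi(st, np.ones(12, bool), d=3, row_block=7)
        assert np.allclose(r1.coords, r7.coords, atol=1e-8)


class TestKnnGraph:
    def test_exact_backend_recall_one(self, rng):
        coords = rng.normal(size=(50, 4))
        g = graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=5)
        assert g.recall == 1.0
        assert (g.knn_idx != np.arange(50)[:, None]).all()

    def test_duplicated_pair_distance_zero(self, rng):
        coords = rng.normal(size=(20, 3))
        coords[11] = coords[4]
        g = graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=3)
        assert g.knn_idx[4, 0] == 11 and g.knn_idx[11, 0] == 4
        assert g.knn_dist[4, 0] == 0.0

    def test_grid_matches_brute_force(self):
        xs, ys = np.meshgrid(np.arange(6.0), np.arange(5.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        coords += np.random.default_rng(1).normal(0, 1e-6, coords.shape)  # break ties
        g = graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=4)
        idx_oracle, _ = brute_force_knn(coords, 4)
        for i in range(coords.shape[0]):
            assert set(g.knn_idx[i]) == set(idx_oracle[i])

    def test_distances_sorted(self, rng):
        coords = rng.normal(size=(40, 3))
        g = graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=6)
        assert (np.diff(g.knn_dist, axis=1) >= -1e-12).all()

    def test_k_too_large_raises(self, rng):
        coords = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="k must"):
            graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=5)

    def test_ann_backend_agrees_on_small_data(self, rng):
        coords = rng.normal(size=(300, 5))
        ge = graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=5, backend="exact")
        ga = graph.build_knn_graph(
            graph.ReducedMatrix(coords, "pca"), k=5, backend="ann", seed=0
        )
        overlap = np.mean(
            [len(set(a) & set(b)) / 5 for a, b in zip(ge.knn_idx, ga.knn_idx)]
        )
        assert overlap > 0.95
        assert ga.recall > 0.95

    def test_reproducible_given_seed(self, rng):
        coords = rng.normal(size=(200, 4))
        g1 = graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=4, backend="ann", seed=7)
        g2 = graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=4, backend="ann", seed=7)
        assert (g1.knn_idx == g2.knn_idx).all()

    def test_index_persistence(self, tmp_path, rng):
        coords = rng.normal(size=(30, 3))
        g, index = graph.build_knn_graph(
            graph.ReducedMatrix(coords, "pca"),
            k=3,
            index_path=tmp_path / "knn.idx",
            return_index=True,
        )
        reloaded = graph.load_index(tmp_path / "knn.idx")
        idx1, _ = index.query(coords[:5], 3)
        idx2, _ = reloaded.query(coords[:5], 3)
        assert (idx1 == idx2).all()


class TestSmoothing:
    def test_two_distance_row(self):
        w = graph.smooth_knn_row(np.array([1.0, 2.0]))
        assert np.isclose(w[0], 1.0)
        assert w[1] < 1e-3  # sigma -> 0 to hit target log2(2) = 1

    def test_nearest_neighbour_weight_one(self, rng):
        coords = rng.normal(size=(30, 3))
        g = graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=5)
        g = graph.smooth_edge_weights(g)
        assert np.allclose(g.weights[:, 0], 1.0)

    def test_all_equal_distances_clamped(self):
        assert (graph.smooth_knn_row(np.full(6, 2.5)) == 1.0).all()

    def test_weight_sums_near_log2k(self, rng):
        coords = rng.normal(size=(60, 4))
        g = graph.smooth_edge_weights(
            graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=8)
        )
        assert (g.weights > 0).all() and (g.weights <= 1).all()
        sums = g.weights.sum(axis=1)
        assert np.abs(sums - np.log2(8)).max() < 1e-3

    def test_symmetrized_fuzzy_union(self, rng):
        coords = rng.normal(size=(25, 3))
        g = graph.smooth_edge_weights(
            graph.build_knn_graph(graph.ReducedMatrix(coords, "pca"), k=4)
        )
        adj = g.to_sparse(symmetrize=True)
        assert (np.abs(adj - adj.T)).max() < 1e-12
        assert adj.max() <= 1.0 + 1e-12


class TestInitialEmbedding:
    def test_two_point_masses(self):
        coords = np.vstack([np.zeros((10, 3)), np.ones((10, 3)) * 5])
        red = graph.ReducedMatrix(coords, "pca")
        init = graph.initial_embedding(red, c=2, dim=2, seed=0)
        uniq = np.unique(init.coords, axis=0)
        assert uniq.shape[0] == 2
        assert (init.coords[:10] == init.coords[0]).all()

    def test_c_equals_n_matches_pca(self, rng):
        coords = rng.normal(size=(20, 5))
        red = graph.ReducedMatrix(coords, "pca")
        init = graph.initial_embedding(red, c=20, dim=2, seed=0)
        oracle = full_pca_components(coords, 2)
        # same 2D subspace content: distances preserved up to rotation/sign
        from scipy.spatial.distance import pdist

        proj = (coords - coords.mean(0)) @ oracle.T
        assert np.allclose(pdist(init.coords), pdist(proj), atol=1e-8)

    def test_seed_determinism(self, rng):
        coords = rng.normal(size=(80, 6))
        red = graph.ReducedMatrix(coords, "pca")
        a = graph.initial_embedding(red, c=8, dim=2, seed=3)
        b = graph.initial_embedding(red, c=8, dim=2, seed=3)
        assert (a.coords == b.coords).all()

    def test_c_out_of_range(self, rng):
        red = graph.ReducedMatrix(rng.normal(size=(10, 3)), "pca")
        with pytest.raises(ValueError):
            graph.initial_embedding(red, c=11, dim=2)
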