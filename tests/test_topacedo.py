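import numpy as np
import pytest
from scipy import sparse

from _oracles import atlas_connected_graphs, nx_to_weighted_adj, pcst_brute_force

from cellgraphkit import topacedo, synth
from cellgraphkit.cluster import ClusterLabels
from cellgraphkit.topacedo import NodeTopology, PcstInstance


class TestNeighbourhoodDegree:
    def test_star_hand_count(self):
        adj = synth.make_toy_graph("star", 3)
        nnd = topacedo.neighbourhood_degree(adj, n_steps=1)
        assert nnd[0] == 3.0  # centre: three leaves of degree 1
        assert (nnd[1:] == 3.0).all()  # each leaf sees the centre's degree

    def test_regular_graph_uniform(self):
        adj = synth.make_toy_graph("clique", 5)  # 4-regular
        nnd = topacedo.neighbourhood_degree(adj, n_steps=1)
        assert (nnd == 16.0).all()

    def test_isolated_node_zero(self):
        adj = sparse.block_diag(
            [synth.make_toy_graph("clique", 3), sparse.csr_matrix((1, 1))]
        ).tocsr()
        nnd = topacedo.neighbourhood_degree(adj, n_steps=2)
        assert nnd[3] == 0.0

    def test_bad_steps_raise(self):
        with pytest.raises(ValueError):
            topacedo.neighbourhood_degree(synth.make_toy_graph("path", 3), n_steps=0)


class TestNeighbourhoodConnectedness:
    def test_triangle(self):
        nc = topacedo.neighbourhood_connectedness(synth.make_toy_graph("clique", 3))
        assert np.allclose(nc, 2.0 / 3.0)  # two edges x Jaccard 1/3

    def test_star_zero(self):
        nc = topacedo.neighbourhood_connectedness(synth.make_toy_graph("star", 3))
        assert (nc == 0.0).all()

    def test_k4(self):
        nc = topacedo.neighbourhood_connectedness(synth.make_toy_graph("clique", 4))
        assert np.allclose(nc, 1.5)  # three edges x Jaccard 2/4


class TestSamplingPlan:
    def _topo(self, nnd, nc):
        return NodeTopology(nnd=np.asarray(nnd, float), nc=np.asarray(nc, float), n_steps=1)

    def test_identical_topology_equal_rates(self):
        labels = ClusterLabels(np.repeat([0, 1], 50), 2)
        topo = self._topo(np.full(100, 8.0), np.full(100, 2.0))
        plan = topacedo.sampling_plan(labels, topo, max_rate=0.1)
        assert np.allclose(plan.table["rate"], 0.1)

    def test_max_rate_cap(self):
        labels = ClusterLabels(np.repeat([0, 1], 50), 2)
        topo = self._topo(
            np.r_[np.full(50, 1.0), np.full(50, 9.0)],
            np.r_[np.full(50, 1.0), np.full(50, 9.0)],
        )
        plan = topacedo.sampling_plan(labels, topo, base_rate=0.5, max_rate=0.01)
        assert (plan.table["rate"] <= 0.01 + 1e-12).all()

    def test_denser_cluster_lower_rate(self):
        labels = ClusterLabels(np.repeat([0, 1], 50), 2)
        topo = self._topo(
            np.r_[np.full(50, 2.0), np.full(50, 10.0)],
            np.r_[np.full(50, 1.0), np.full(50, 5.0)],
        )
        plan = topacedo.sampling_plan(labels, topo, max_rate=0.5)
        assert plan.table["rate"][1] < plan.table["rate"][0]

    def test_every_cluster_gets_a_seed(self):
        labels = ClusterLabels(np.r_[np.zeros(995, int), np.ones(5, int)], 2)
        topo = self._topo(np.ones(1000), np.ones(1000))
        plan = topacedo.sampling_plan(labels, topo, max_rate=0.01)
        assert (plan.table["n_to_sample"] >= 1).all()


class TestSelectSeeds:
    def test_full_quota_takes_all(self, rng):
        coords = rng.normal(size=(20, 3))
        labels = ClusterLabels(np.zeros(20, int), 1)
        topo = NodeTopology(np.ones(20), np.ones(20), 1)
        plan = topacedo.sampling_plan(labels, topo, max_rate=1.0, base_rate=1.0)
        seeds = topacedo.select_seeds(coords, labels, plan, seed=0)
        assert seeds.size == 20

    def test_seeds_carry_own_cluster(self, rng):
        coords = rng.normal(size=(60, 2))
        lab = np.repeat([0, 1, 2], 20)
        labels = ClusterLabels(lab, 3)
        topo = NodeTopology(np.ones(60), np.ones(60), 1)
        plan = topacedo.sampling_plan(labels, topo, max_rate=0.2)
        seeds = topacedo.select_seeds(coords, labels, plan, seed=0)
        per = np.bincount(lab[seeds], minlength=3)
        assert (per == plan.table["n_to_sample"].to_numpy()).all()

    def test_two_blobs_one_seed_each(self):
        coords = np.vstack([np.zeros((10, 2)), np.full((10, 2), 100.0)])
        coords += np.random.default_rng(0).normal(0, 0.1, coords.shape)
        labels = ClusterLabels(np.zeros(20, int), 1)
        plan = topacedo.SamplingPlan(
            __import__("pandas").DataFrame(
                {"cluster": [0], "size": [20], "median_nnd": [1.0],
                 "median_nc": [1.0], "rate": [0.1], "n_to_sample": [2]}
            )
        )
        seeds = topacedo.select_seeds(coords, labels, plan, seed=0)
        assert seeds.size == 2
        assert (seeds < 10).sum() == 1 and (seeds >= 10).sum() == 1


class TestEdgePenalties:
    def test_zero_weight_gives_ecm(self):
        adj = synth.make_toy_graph("path", 3, weight=1e-300)  # ~0 weight edges
        pen = topacedo.edge_penalties(adj, E_cm=2.5, E_bw=10.0)
        assert np.allclose(pen.data, 2.5)

    def test_printed_parameters(self):
        # E_cm = 1, E_bw = 10, E_w = 1 -> penalty 0.1
        adj = synth.make_toy_graph("path", 2, weight=1.0)
        pen = topacedo.edge_penalties(adj, E_cm=1.0, E_bw=10.0)
        assert np.allclose(pen.data, 0.1)

    def test_monotone_decreasing_in_weight(self):
        rows, cols = [0, 1, 1, 2], [1, 0, 2, 1]
        adj = sparse.csr_matrix(([0.9, 0.9, 0.3, 0.3], (rows, cols)), shape=(3, 3))
        pen = topacedo.edge_penalties(adj, 1.0, 10.0)
        assert pen[0, 1] < pen[1, 2]

    def test_bad_bandwidth_raises(self):
        with pytest.raises(ValueError, match="E_bw"):
            topacedo.edge_penalties(synth.make_toy_graph("path", 2), 1.0, 1.0)


def _instance(adj, seed_nodes, prize=10.0, E_cm=1.0, E_bw=10.0):
    prizes = np.zeros(adj.shape[0])
    prizes[list(seed_nodes)] = prize
    pen = topacedo.edge_penalties(adj, E_cm, E_bw)
    return PcstInstance(prizes=prizes, penalties=pen, E_cm=E_cm, E_bw=E_bw)


class TestRunPcst:
    def test_path_collects_both_seeds(self):
        adj = synth.make_toy_graph("path", 3, weight=1.0)
        inst = _instance(adj, [0, 2])
        res = topacedo.run_pcst(adj, inst)
        assert set(res.selected) == {0, 1, 2}
        assert np.isclose(res.objective, 20.0 - 0.2)  # two 0.1 penalties

    def test_all_zero_prizes_empty(self):
        adj = synth.make_toy_graph("clique", 4)
        inst = _instance(adj, [])
        with pytest.warns(UserWarning, match="no seeds"):
            res = topacedo.run_pcst(adj, inst)
        assert res.selected.size == 0

    def test_one_tree_per_component(self):
        a = synth.make_toy_graph("path", 3)
        b = synth.make_toy_graph("path", 3)
        adj = sparse.block_diag([a, b]).tocsr()
        inst = _instance(adj, [0, 2, 3, 5])
        res = topacedo.run_pcst(adj, inst)
        assert set(res.selected) == {0, 1, 2, 3, 4, 5}
        assert all(
            (u < 3) == (v < 3) for u, v in res.selected_edges
        )  # no cross-component edges

    def test_matches_exact_solver_on_trees(self, rng):
        """Strong pruning is optimal on tree graphs."""
        import networkx as nx

        for nodes in (4, 5, 6, 7):
            for trial in range(5):
                t = nx.random_labeled_tree(nodes, seed=int(rng.integers(1 << 30)))
                weights = rng.uniform(0.1, 1.0, size=nodes - 1)
                adj = nx_to_weighted_adj(t, weights)
                n_seeds = int(rng.integers(1, nodes + 1))
                seeds = rng.choice(nodes, size=n_seeds, replace=False)
                # low prize so pruning decisions actually matter
                inst = _instance(adj, seeds, prize=0.6)
                approx = topacedo.run_pcst(adj, inst)
                exact = topacedo.run_pcst_exact(adj, inst)
                assert np.isclose(approx.objective, exact.objective, atol=1e-9)

    def test_half_optimal_on_atlas_graphs(self, rng):
        """On general small graphs the approximation stays within factor 2."""
        graphs = atlas_connected_graphs(max_nodes=7)
        sample = graphs[:: max(1, len(graphs) // 60)]
        for g in sample:
            n = g.number_of_nodes()
            weights = rng.uniform(0.1, 1.0, size=g.number_of_edges())
            adj = nx_to_weighted_adj(g, weights)
            seeds = rng.choice(n, size=int(rng.integers(1, n + 1)), replace=False)
            inst = _instance(adj, seeds, prize=1.0)
            approx = topacedo.run_pcst(adj, inst)
            opt = pcst_brute_force(adj, inst.prizes, inst.penalties)
            assert approx.objective >= 0.5 * opt - 1e-9


class TestSubsample:
    def _pipeline(self, n=400, props=(0.5, 0.3, 0.2), seed=0):
        from cellgraphkit import pipeline

        spec = synth.SynthSpec(n_cells=n, n_genes=200, cluster_props=props, seed=seed)
        counts, truth = synth.make_clustered_counts(spec)
        res = pipeline.rna_graph_pipeline(counts, n_hvgs=150, d=10, k=10, seed=seed)
        return res

    def test_saturation_selects_all(self, rng):
        coords = rng.normal(size=(30, 3))
        from cellgraphkit import graph as g_mod

        g = g_mod.smooth_edge_weights(
            g_mod.build_knn_graph(g_mod.ReducedMatrix(coords, "pca"), k=5)
        )
        labels = ClusterLabels(np.zeros(30, int), 1)
        sk = topacedo.subsample(
            g, labels, coords, max_rate=1.0, base_rate=1.0, min_rate=1.0
        )
        assert sk.selected.size == 30

    def test_selection_connected_within_components(self):
        res = self._pipeline()
        sk = topacedo.subsample(res.knn, res.labels, res.reduced, max_rate=0.05)
        # union-find over selected edges: one tree per graph component
        parent = {int(v): int(v) for v in sk.selected}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in sk.selected_edges:
            parent[find(int(u))] = find(int(v))
        from scipy.sparse.csgraph import connected_components

        adj = res.knn.to_sparse()
        _, comp = connected_components(adj, directed=False)
        for ci in np.unique(comp[sk.selected]):
            roots = {find(int(v)) for v in sk.selected if comp[v] == ci}
            assert len(roots) == 1

    def test_every_cluster_represented(self):
        res = self._pipeline(props=(0.6, 0.25, 0.1, 0.05))
        sk = topacedo.subsample(res.knn, res.labels, res.reduced, max_rate=0.05)
        covered = np.unique(res.labels.label[sk.selected])
        assert covered.size == res.labels.n_clusters

    def test_rare_cluster_enriched(self):
        """Sampling a rare population at the capped rate raises its share."""
        from cellgraphkit import metrics, pipeline

        spec = synth.SynthSpec(
            n_cells=1500,
            n_genes=300,
            cluster_props=(0.5, 0.3, 0.17, 0.03),
            seed=1,
        )
        counts, truth = synth.make_clustered_counts(spec)
        res = pipeline.rna_graph_pipeline(counts, n_hvgs=200, d=15, k=15, seed=1)
        sk = topacedo.subsample(res.knn, res.labels, res.reduced, max_rate=0.05, seed=1)
        mask = np.zeros(1500, bool)
        mask[sk.selected] = True
        truth_labels = ClusterLabels(truth, 4)
        enr = metrics.cluster_enrichment(truth_labels, mask)
        rare = np.argmin(np.bincount(truth))
        assert enr[rare] > 0
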