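"""Depth scaling, variable genes, PCA, SNN graph, and resolution search."""

import igraph as ig
import numpy as np
import pytest
import scipy.sparse as sp

from conftest import toy_matrix
from crossimmune.clustering import (
    Embedding,
    SnnGraph,
    build_snn_graph,
    cluster_at_resolution,
    depth_scale,
    iterative_cluster,
    partition_quality,
    pca_embed,
    resolution_search,
    select_variable_genes,
    snn_graph_brute_force,
)


def _embedding(coords):
    coords = np.asarray(coords, dtype=float)
    var = coords.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return Embedding(
        cells=np.arange(len(coords)).astype(object),
        coordinates=coords[:, order],
        variance_explained=np.sort(var)[::-1] / max(var.sum(), 1e-12),
    )


class TestDepthScale:
    def test_column_sums_equal_after_scaling(self, small_clustered):
        m, _ = small_clustered
        scaled = depth_scale(m)
        sums = np.asarray(scaled.sum(axis=0)).ravel()
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)

    def test_doubling_a_barcode_leaves_profile_unchanged(self):
        counts = np.array([[4, 8], [6, 12], [10, 20]])
        m = toy_matrix(counts)
        scaled = np.asarray(depth_scale(m).todense())
        np.testing.assert_allclose(scaled[:, 0], scaled[:, 1])

    def test_zero_total_barcode_rejected(self):
        m = toy_matrix(np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValueError):
            depth_scale(m)


class TestVariableGenes:
    def test_planted_markers_recovered(self, small_clustered):
        m, _ = small_clustered
        scaled = depth_scale(m)
        mask = select_variable_genes(scaled)
        assert mask.sum() >= 10

    def test_marker_genes_preferentially_selected(self):
        from crossimmune.synthetic_data import DropletSimConfig, simulate_droplet_experiment

        # markers must stay a small minority of genes: the within-bin z
        # cutoff can only ever select the upper tail of each bin
        cfg = DropletSimConfig(
            n_cells=800, n_empty=10, n_genes=600, k_clusters=4,
            markers_per_cluster=10, marker_logfc=2.0, seed=13,
        )
        m, truth = simulate_droplet_experiment(cfg)
        mc = m.subset_barcodes(truth.barcode_class == "cell")
        mask = select_variable_genes(depth_scale(mc))
        selected = set(mc.genes[mask])
        planted = set(np.concatenate(list(truth.marker_genes.values())))
        recall = len(planted & selected) / len(planted)
        assert recall >= 0.9

    def test_iid_poisson_null_matches_z_tail(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(5.0, size=(2000, 300))
        frac = select_variable_genes(sp.csr_matrix(counts * 1.0)).mean()
        from scipy.stats import norm

        expected = norm.sf(1.0)
        assert abs(frac - expected) <= 0.03

    def test_constant_gene_never_selected(self):
        counts = np.vstack([np.full(50, 3.0), np.random.default_rng(0).poisson(3, 50)])
        mask = select_variable_genes(sp.csr_matrix(counts))
        assert not mask[0]

    def test_equal_means_falls_back_to_global_scoring(self):
        rng = np.random.default_rng(9)
        x = rng.permuted(np.tile(np.arange(40.0), (30, 1)), axis=1)
        mask = select_variable_genes(sp.csr_matrix(x))
        assert mask.shape == (30,)  # documented fallback path runs


class TestPca:
    def test_rank_three_data_has_three_components(self):
        rng = np.random.default_rng(10)
        basis = rng.uniform(0, 2, size=(3, 80))
        loads = rng.uniform(0.5, 1.5, size=(200, 3))
        x = sp.csr_matrix(np.expm1(loads @ basis).T)  # genes x cells, positive
        e = pca_embed(x, np.arange(200), n_components=50, scale_genes=False)
        assert e.variance_explained[:3].sum() > 0.999
        assert np.all(e.variance_explained[4:] < 1e-6)

    def test_deterministic_under_seed(self, small_clustered):
        m, _ = small_clustered
        scaled = depth_scale(m)
        e1 = pca_embed(scaled, m.barcodes, seed=5)
        e2 = pca_embed(scaled, m.barcodes, seed=5)
        np.testing.assert_array_equal(e1.coordinates, e2.coordinates)

    def test_component_count_clamped(self):
        x = sp.csr_matrix(np.random.default_rng(1).poisson(4, size=(10, 8)) * 1.0)
        e = pca_embed(x, np.arange(8), n_components=50)
        assert e.coordinates.shape[1] <= 7


class TestSnnGraph:
    def test_identical_coordinates_give_weight_one(self):
        coords = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5.1], [9, 9]])
        e = _embedding(coords)
        g = build_snn_graph(e, k=2, prune=0.0)
        tbl = g.edge_table().set_index(["source", "target"])
        assert tbl.loc[(0, 1), "weight"] == 1.0

    def test_full_k_saturates_jaccard(self):
        rng = np.random.default_rng(11)
        e = _embedding(rng.normal(size=(12, 3)))
        g = build_snn_graph(e, k=11, prune=0.0)
        w = np.array(g.graph.es["weight"])
        np.testing.assert_allclose(w, 1.0)  # full neighbor sets coincide

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(50, 5))
        e = _embedding(coords)
        g = build_snn_graph(e, k=8)
        oracle = snn_graph_brute_force(coords[:, np.argsort(-coords.var(axis=0),
                                                            kind="stable")], 8)
        got = {
            (min(s, t), max(s, t)): w
            for s, t, w in g.edge_table().itertuples(index=False)
        }
        assert set(got) == set(oracle)
        for edge, w in oracle.items():
            assert got[edge] == pytest.approx(w)


class TestModularityClustering:
    def _two_cliques(self):
        g = ig.Graph.Full(10) + ig.Graph.Full(10)
        g.es["weight"] = 1.0
        return SnnGraph(graph=g, k=9, prune=0.0)

    def test_disconnected_cliques_resolve_exactly(self):
        g = self._two_cliques()
        for res in (0.1, 0.5, 1.0):
            labels = cluster_at_resolution(g, res, seed=1)
            assert len(np.unique(labels)) == 2
            assert len(np.unique(labels[:10])) == 1

    def test_tiny_resolution_merges_connected_component(self):
        g = ig.Graph.Erdos_Renyi(n=30, p=0.4)
        g.es["weight"] = 1.0
        labels = cluster_at_resolution(SnnGraph(g, k=5, prune=0.0), 1e-4, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic_under_seed(self):
        g = ig.Graph.Erdos_Renyi(n=60, p=0.2)
        g.es["weight"] = 1.0
        sg = SnnGraph(g, k=5, prune=0.0)
        l1 = cluster_at_resolution(sg, 0.8, seed=3)
        l2 = cluster_at_resolution(sg, 0.8, seed=3)
        np.testing.assert_array_equal(l1, l2)


class TestResolutionSearch:
    def _blobs(self, seed=0, n=60, k=3, sep=8.0):
        rng = np.random.default_rng(seed)
        coords = np.concatenate(
            [rng.normal(size=(n, 2)) + sep * np.array([i, i % 2]) for i in range(k)]
        )
        return _embedding(coords), np.repeat(np.arange(k), n)

    def test_planted_blobs_recovered(self):
        e, truth = self._blobs()
        g = build_snn_graph(e, k=15)
        labels, res, metric = resolution_search(g, e, seed=1)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) >= 0.9
        assert metric > 0.5

    def test_good_partition_beats_random_bipartition(self):
        e, truth = self._blobs(seed=2, k=2)
        from sklearn.metrics import pairwise_distances

        d = pairwise_distances(e.coordinates)
        rng = np.random.default_rng(3)
        random_split = rng.integers(0, 2, size=len(truth))
        assert partition_quality(truth, d) > partition_quality(random_split, d)

    def test_merging_planted_clusters_never_raises_metric(self):
        e, truth = self._blobs(seed=4, k=3)
        from sklearn.metrics import pairwise_distances

        d = pairwise_distances(e.coordinates)
        merged = np.where(truth == 2, 1, truth)
        assert partition_quality(merged, d) < partition_quality(truth, d)

    def test_noise_returns_single_cluster(self):
        single = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            e = _embedding(rng.normal(size=(150, 10)))
            g = build_snn_graph(e, k=20)
            labels, _, _ = resolution_search(g, e, seed=seed)
            single += len(np.unique(labels)) == 1
        assert single >= 4


class TestIterativeClustering:
    def test_homogeneous_data_converges_to_one_cluster(self):
        rng = np.random.default_rng(14)
        counts = rng.poisson(4.0, size=(120, 200))
        m = toy_matrix(counts)
        asn = iterative_cluster(m, seed=2)
        assert set(asn.converged) == {"0"}
        assert set(asn.first_iteration) == {"0"}

    def test_converged_labels_refine_first_iteration(self, small_clustered):
        m, _ = small_clustered
        asn = iterative_cluster(m, seed=3)
        for first, conv in zip(asn.first_iteration, asn.converged):
            assert conv == first or conv.startswith(first + ".")

    def test_planted_clusters_recovered(self, small_clustered):
        m, truth = small_clustered
        asn = iterative_cluster(m, seed=3)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, asn.first_iteration) >= 0.9

    def test_deterministic_end_to_end(self, small_clustered):
        m, _ = small_clustered
        a1 = iterative_cluster(m, seed=9)
        a2 = iterative_cluster(m, seed=9)
        np.testing.assert_array_equal(a1.converged, a2.converged)
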