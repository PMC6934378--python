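"""KNN graph construction, Louvain modularity, shuffled-null resolution scan."""

import igraph
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from scrobust.clustering import (build_knn_graph, cluster_matrix,
                                 graph_modularity, leiden_cluster, louvain_cluster,
                                 purge_contaminant_cells, select_resolution,
                                 shuffle_within_cells)
from scrobust.io_qc import filter_cells, normalize
from scrobust.synthetic import CohortConfig, generate_cohort, spike_contaminants

from conftest import dense_normalized


def brute_force_modularity(graph: igraph.Graph, labels) -> float:
    """Sum over communities of (within-weight/total − (degree/2·total)²)."""
    w = np.asarray(graph.es["weight"], float)
    total = w.sum()
    if total == 0:
        return 0.0
    labels = np.asarray(labels)
    q = 0.0
    strength = np.zeros(graph.vcount())
    for e, weight in zip(graph.es, w):
        a, b = e.tuple
        strength[a] += weight
        strength[b] += weight
    for c in np.unique(labels):
        members = set(np.flatnonzero(labels == c))
        w_in = sum(weight for e, weight in zip(graph.es, w)
                   if e.source in members and e.target in members)
        s_c = strength[sorted(members)].sum()
        q += w_in / total - (s_c / (2 * total)) ** 2
    return q


class TestKnnGraph:
    def test_three_equidistant_points(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        g = build_knn_graph(pts, k=2)
        assert g.ecount() == 3
        np.testing.assert_allclose(g.es["weight"], 1.0)

    def test_full_overlap_weight_one(self):
        # two mutual neighbors sharing every other neighbor
        pts = np.array([[0.0, 0], [0.001, 0], [1, 0], [0, 1]])
        g = build_knn_graph(pts, k=3)  # every node's set is all four nodes
        eid = g.get_eid(0, 1)
        assert g.es[eid]["weight"] == pytest.approx(1.0)

    def test_separated_blobs_no_cross_edges(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.5, size=(50, 3))
        b = rng.normal(100, 0.5, size=(50, 3))
        g = build_knn_graph(np.vstack([a, b]), k=5)
        for e in g.es:
            s, t = e.tuple
            assert (s < 50) == (t < 50)

    def test_invalid_k(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            build_knn_graph(pts, 0)
        with pytest.raises(ValueError):
            build_knn_graph(pts, 5)


class TestLouvain:
    def _clique_pair(self, size=8):
        g = igraph.Graph()
        g.add_vertices(2 * size)
        edges = [(i, j) for i in range(size) for j in range(i + 1, size)]
        edges += [(size + i, size + j) for i in range(size) for j in range(i + 1, size)]
        g.add_edges(edges)
        g.es["weight"] = [1.0] * len(edges)
        return g

    def test_two_disconnected_cliques_modularity_half(self):
        g = self._clique_pair()
        res = louvain_cluster(g, seed=0)
        assert res.n_clusters == 2
        assert res.modularity == pytest.approx(0.5, abs=1e-12)

    def test_uniform_complete_graph_modularity_zero(self):
        n = 10
        g = igraph.Graph.Full(n)
        g.es["weight"] = [1.0] * g.ecount()
        labels = np.zeros(n, dtype=int)
        assert graph_modularity(g, labels) == pytest.approx(0.0, abs=1e-12)
        assert brute_force_modularity(g, labels) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_modularity_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 120)
        g = igraph.Graph.Erdos_Renyi(n=int(n), p=0.08)
        g.es["weight"] = list(rng.uniform(0.1, 1.0, g.ecount()))
        for fn in (louvain_cluster, leiden_cluster):
            res = fn(g, seed=seed)
            assert res.modularity == pytest.approx(
                brute_force_modularity(g, res.labels), abs=1e-10)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        g = igraph.Graph.Erdos_Renyi(n=80, p=0.1)
        g.es["weight"] = list(rng.uniform(0.5, 1.0, g.ecount()))
        a = louvain_cluster(g, seed=5)
        b = louvain_cluster(g, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_edgeless_graph_singletons(self):
        g = igraph.Graph()
        g.add_vertices(4)
        res = louvain_cluster(g, seed=0)
        assert res.n_clusters == 4
        assert res.modularity == 0.0


class TestShuffle:
    def test_per_cell_sums_and_sorted_values_preserved(self, small_cohort):
        norm = small_cohort["norm"]
        out = shuffle_within_cells(norm, seed=1)
        X0 = norm.to_dense()
        X1 = out.to_dense()
        np.testing.assert_allclose(X1.sum(axis=1), X0.sum(axis=1), rtol=1e-12)
        np.testing.assert_allclose(np.sort(X1, axis=1), np.sort(X0, axis=1))

    def test_different_seeds_differ(self, small_cohort):
        norm = small_cohort["norm"]
        a = shuffle_within_cells(norm, seed=1).to_dense()
        b = shuffle_within_cells(norm, seed=2).to_dense()
        assert not np.array_equal(a, b)

    def test_single_gene_matrix_identity(self):
        X = np.arange(5.0).reshape(5, 1)
        out = shuffle_within_cells(dense_normalized(X), seed=0)
        np.testing.assert_array_equal(out.to_dense(), X)

    def test_structure_collapses(self):
        # groups differ in *which* genes are high, not in per-cell totals,
        # since within-cell shuffling deliberately preserves coverage
        rng = np.random.default_rng(0)
        a = np.hstack([rng.normal(4, 1, (40, 15)), rng.normal(0, 1, (40, 15))])
        b = np.hstack([rng.normal(0, 1, (40, 15)), rng.normal(4, 1, (40, 15))])
        X = np.vstack([a, b])
        labels = np.array([0] * 40 + [1] * 40)
        before = silhouette_score(X, labels)
        after = silhouette_score(
            shuffle_within_cells(dense_normalized(X), seed=0).to_dense(), labels)
        assert before > 0.3
        assert after < before / 3


class TestSelectResolution:
    def test_recovers_planted_programs(self, small_cohort):
        norm = small_cohort["norm"]
        truth = small_cohort["truth"]
        scan = select_resolution(norm, [10, 20], n_shuffles=3, seed=0)
        assert scan.chosen_k is not None
        true = truth.cells.loc[norm.obs.index, "program"].to_numpy()
        assert adjusted_rand_score(true, scan.chosen.labels) >= 0.9

    def test_null_input_chooses_none(self, small_cohort):
        shuffled = shuffle_within_cells(small_cohort["norm"], seed=42)
        scan = select_resolution(shuffled, [10, 20], n_shuffles=3, seed=0)
        assert scan.chosen_k is None

    def test_observed_exceeds_null_for_structure(self, small_cohort):
        scan = select_resolution(small_cohort["norm"], [10, 20], n_shuffles=3, seed=0)
        assert (scan.table["observed"] > scan.table["null_mean"]).all()

    def test_single_shuffle_legal(self, small_cohort):
        scan = select_resolution(small_cohort["norm"], [15], n_shuffles=1, seed=0)
        assert len(scan.null_samples[15]) == 1

    def test_invalid_inputs(self, small_cohort):
        with pytest.raises(ValueError):
            select_resolution(small_cohort["norm"], [10], n_shuffles=0)
        with pytest.raises(ValueError):
            select_resolution(small_cohort["norm"], [10**6], n_shuffles=1)

    def test_determinism(self, small_cohort):
        a = select_resolution(small_cohort["norm"], [15], n_shuffles=2, seed=3)
        b = select_resolution(small_cohort["norm"], [15], n_shuffles=2, seed=3)
        assert a.table.equals(b.table)
        np.testing.assert_array_equal(a.chosen.labels if a.chosen else [],
                                      b.chosen.labels if b.chosen else [])


class TestPurge:
    def test_no_markers_identity(self, small_cohort):
        norm = small_cohort["norm"]
        res, pca = cluster_matrix(norm, 15, seed=0)
        keep, report = purge_contaminant_cells(
            norm, res, pca, marker_symbols=("NotAGene",))
        assert keep.all()
        assert report["markers"] == []

    def test_spiked_contaminants_removed(self):
        cfg = CohortConfig(n_datasets=1, replicates_per_dataset=1,
                           cells_per_dataset=800, n_genes=1000, n_programs=3,
                           doublet_rate=0.0, seed=13)
        (matrix, truth), = generate_cohort(cfg)
        matrix, truth = spike_contaminants(matrix, truth, rate=0.05, seed=1)
        filtered, _ = filter_cells(matrix)
        norm = normalize(filtered)
        res, pca = cluster_matrix(norm, 20, seed=0)
        keep, report = purge_contaminant_cells(filtered, res, pca)
        contaminant = truth.cells.loc[filtered.obs.index, "contaminant"].to_numpy()
        removed = ~keep
        assert removed[contaminant].mean() >= 0.9
        assert removed[~contaminant].mean() <= 0.01

    def test_pure_cluster_rule(self):
        # one cluster expressing the marker in every cell, pc rule disabled
        rng = np.random.default_rng(0)
        import pandas as pd
        import scipy.sparse as sp
        from scrobust.io_qc import CountMatrix
        from scrobust.clustering import ClusteringResult
        from scrobust.reduction import PCAResult

        X = rng.poisson(2, (60, 20))
        X[:20, 0] = 5  # cluster 0 all marker-positive
        X[20:, 0] = 0
        m = CountMatrix(sp.csr_matrix(X),
                        pd.DataFrame(index=[f"c{i}" for i in range(60)]),
                        pd.DataFrame({"mito": False},
                                     index=["Cd79a"] + [f"G{i}" for i in range(19)]))
        labels = np.array([0] * 20 + [1] * 20 + [2] * 20)
        res = ClusteringResult(labels, k=5, modularity=0.5, seed=0,
                               n_nodes=60, n_edges=0)
        pca = PCAResult(scores=np.zeros((60, 2)), loadings=np.zeros((20, 2)),
                        explained_variance=np.ones(2),
                        explained_variance_ratio=np.ones(2) / 2,
                        genes=[f"X{i}" for i in range(20)],
                        barcodes=list(m.obs.index))
        keep, report = purge_contaminant_cells(m, res, pca, marker_symbols=("Cd79a",))
        assert report["removed_clusters"] == [0]
        assert set(np.flatnonzero(~keep)) == set(range(20))
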