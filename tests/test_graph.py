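"""Graph metrics, null models, modularity detection, permutation testing."""

import numpy as np
import pytest

from conftest import exhaustive_best_q
from netsig.graph import (
    Partition,
    characteristic_path_length,
    clustering_coefficient,
    detect_modules,
    global_efficiency,
    modularity_q,
    permutation_compare,
    rewire_null,
    small_worldness,
    threshold_at_density,
)
from netsig.roi import RoiSet


def adj_from_edges(n, edges, weight=1.0):
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = weight
    return a


def ring_lattice(n=20, k=4):
    a = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            a[i, j] = a[j, i] = 1.0
    return a


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        _, c = clustering_coefficient(adj_from_edges(3, [(0, 1), (0, 2), (1, 2)]))
        assert c == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        star = adj_from_edges(5, [(0, i) for i in range(1, 5)])
        per_node, c = clustering_coefficient(star)
        assert c == 0.0 and (per_node == 0).all()

    def test_k4_minus_one_edge(self):
        # hand enumeration: the two degree-3 nodes see 1 of 3 pairs closed
        # plus the edge between them -> c = 2/3; the two degree-2 nodes are
        # in one triangle each -> c = 1. mean = (2/3 + 2/3 + 1 + 1)/4 = 5/6
        adj = adj_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        _, c = clustering_coefficient(adj)
        assert c == pytest.approx(5 / 6)

    def test_weighted_onnela_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        w = rng.uniform(0, 1, (8, 8)) * (rng.random((8, 8)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        per_node, _ = clustering_coefficient(w, mode="weighted")
        g = nx.from_numpy_array(w)
        expected = nx.clustering(g, weight="weight")
        for i in range(8):
            assert per_node[i] == pytest.approx(expected[i], abs=1e-12)

    def test_negative_weights_rejected(self):
        adj = adj_from_edges(3, [(0, 1)], weight=-1.0)
        with pytest.raises(ValueError, match="negative"):
            clustering_coefficient(adj, mode="weighted")


class TestPathLengthAndEfficiency:
    def test_path_graph_enumeration(self):
        path = adj_from_edges(3, [(0, 1), (1, 2)])
        assert characteristic_path_length(path) == pytest.approx(4 / 3)
        assert global_efficiency(path) == pytest.approx(5 / 6)

    def test_complete_graph(self):
        k5 = 1.0 - np.eye(5)
        assert characteristic_path_length(k5) == pytest.approx(1.0)
        assert global_efficiency(1.0 - np.eye(3)) == pytest.approx(1.0)

    def test_disjoint_edges_exclude_disconnected_pairs(self):
        adj = adj_from_edges(4, [(0, 1), (2, 3)])
        with pytest.warns(UserWarning, match="disconnected"):
            l = characteristic_path_length(adj)
        assert l == pytest.approx(1.0)

    def test_edgeless_graph(self):
        with pytest.raises(ValueError, match="edgeless"):
            characteristic_path_length(np.zeros((4, 4)))
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_weighted_mode_uses_inverse_weight_lengths(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 0.5   # length 2
        adj[1, 2] = adj[2, 1] = 0.25  # length 4
        # distances: d01=2, d12=4, d02=6 -> mean = 4
        assert characteristic_path_length(adj, mode="weighted") == pytest.approx(4.0)


class TestRewireNull:
    def test_degree_sequence_preserved(self, two_k3):
        ens = rewire_null(ring_lattice(), n=20, seed=1)
        want = sorted(ring_lattice().sum(axis=1))
        for h in ens.graphs:
            assert sorted(h.sum(axis=1)) == want
            assert np.allclose(h, h.T) and (np.diag(h) == 0).all()

    def test_complete_graph_returns_copies_with_warning(self):
        k4 = 1.0 - np.eye(4)
        with pytest.warns(UserWarning, match="no double-edge swap"):
            ens = rewire_null(k4, n=3, seed=0)
        for h in ens.graphs:
            np.testing.assert_array_equal(h, k4)

    def test_rewiring_destroys_lattice_clustering(self):
        lattice = ring_lattice(20, 4)
        _, c0 = clustering_coefficient(lattice)
        ens = rewire_null(lattice, n=20, seed=42)
        lower = sum(clustering_coefficient(h)[1] < c0 for h in ens.graphs)
        assert lower >= 19

    def test_weighted_graph_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            rewire_null(adj_from_edges(4, [(0, 1), (2, 3)], weight=0.5))


class TestSmallWorldness:
    def test_identity_ensemble_gives_unit_ratios(self, two_k3):
        from netsig.graph import NullEnsemble

        lattice = ring_lattice()
        ens = NullEnsemble(graphs=[lattice.copy()], seed=0)
        gamma, lam, sigma = small_worldness(lattice, ens)
        assert gamma == lam == sigma == 1.0

    def test_ring_lattice_is_small_world_like_vs_rewired(self):
        lattice = ring_lattice(20, 4)
        ens = rewire_null(lattice, n=20, seed=11)
        gamma, lam, sigma = small_worldness(lattice, ens)
        assert gamma > 1.0 and sigma > 1.0

    def test_random_graph_sigma_near_one(self):
        import networkx as nx

        sigmas = []
        for seed in range(50):
            g = nx.gnp_random_graph(24, 0.3, seed=seed)
            if not nx.is_connected(g):
                continue
            adj = nx.to_numpy_array(g)
            ens = rewire_null(adj, n=10, seed=seed)
            sigmas.append(small_worldness(adj, ens)[2])
        assert abs(np.mean(sigmas) - 1.0) < 0.2


class TestDetectModules:
    def test_two_cliques_found_exactly(self, two_k3, rs6):
        part = detect_modules(two_k3, rs6, n_iter=200, seed=0)
        assert part.q == pytest.approx(0.5, abs=1e-12)
        labels = part.labels_array()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_complete_graph_single_module_zero_q(self):
        part = detect_modules(1.0 - np.eye(5), RoiSet.default(5), n_iter=50, seed=0)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_bridged_cliques_still_split(self, two_k3, rs6):
        bridged = two_k3.copy()
        bridged[2, 3] = bridged[3, 2] = 1.0
        part = detect_modules(bridged, rs6, n_iter=200, seed=0)
        labels = part.labels_array()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    @pytest.mark.parametrize("graph_id", ["two_k3", "bridge", "k5", "path7",
                                          "star8", "weighted_blocks"])
    def test_matches_exhaustive_search_on_small_graphs(self, graph_id, two_k3):
        rng = np.random.default_rng(9)
        graphs = {
            "two_k3": two_k3,
            "bridge": None,
            "k5": 1.0 - np.eye(5),
            "path7": adj_from_edges(7, [(i, i + 1) for i in range(6)]),
            "star8": adj_from_edges(8, [(0, i) for i in range(1, 8)]),
        }
        bridged = two_k3.copy()
        bridged[2, 3] = bridged[3, 2] = 1.0
        graphs["bridge"] = bridged
        w = rng.uniform(0.5, 1.0, (6, 6))
        blocks = two_k3 * w
        blocks = np.triu(blocks, 1) + np.triu(blocks, 1).T
        graphs["weighted_blocks"] = blocks
        adj = graphs[graph_id]
        n = adj.shape[0]
        mode = "weighted" if graph_id == "weighted_blocks" else "binary"
        part = detect_modules(adj, RoiSet.default(n), mode=mode, n_iter=300, seed=1)
        best_q, _ = exhaustive_best_q(adj)
        assert part.q == pytest.approx(best_q, abs=1e-12)

    def test_reported_q_equals_independent_recomputation(self, two_k3, rs6):
        part = detect_modules(two_k3, rs6, n_iter=50, seed=3)
        assert part.q == pytest.approx(modularity_q(two_k3, part.labels_array()),
                                       abs=1e-12)
        assert -1.0 <= part.q <= 1.0

    def test_all_zero_matrix_single_module_with_warning(self, rs6):
        with pytest.warns(UserWarning, match="all-zero"):
            part = detect_modules(np.zeros((6, 6)), rs6)
        assert part.n_modules == 1 and part.q == 0.0

    def test_deterministic_under_seed(self, two_k3, rs6):
        p1 = detect_modules(two_k3, rs6, n_iter=20, seed=5)
        p2 = detect_modules(two_k3, rs6, n_iter=20, seed=5)
        assert p1.assignment == p2.assignment and p1.q == p2.q


class TestThresholdAtDensity:
    def test_density_one_keeps_all_positive_edges(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (6, 6))
        w = np.triu(w, 1) + np.triu(w, 1).T
        out = threshold_at_density(w, 1.0)
        np.testing.assert_array_equal(out, (w > 0).astype(float))

    def test_keeps_exactly_the_largest_k(self):
        w = np.zeros((5, 5))
        vals = [0.9, 0.7, 0.5, 0.3, 0.1]
        pairs = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2)]
        for v, (i, j) in zip(vals, pairs):
            w[i, j] = w[j, i] = v
        out = threshold_at_density(w, 0.3)  # floor(0.3 * 10) = 3 edges
        assert out.sum() / 2 == 3
        for v, (i, j) in zip(vals[:3], pairs[:3]):
            assert out[i, j] == 1.0

    def test_tied_weights_break_lexicographically_and_deterministically(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 2), (2, 3)]:
            w[i, j] = w[j, i] = 0.5
        out1 = threshold_at_density(w, 2 / 6)  # keep 2 of 4 tied edges
        out2 = threshold_at_density(w, 2 / 6)
        np.testing.assert_array_equal(out1, out2)
        assert out1[0, 1] == 1.0 and out1[0, 2] == 1.0  # earliest pairs win
        assert out1.sum() / 2 == 2


class TestPermutationCompare:
    def _cohort(self, seed, n=4):
        rng = np.random.default_rng(seed)
        mats = []
        for _ in range(n):
            r = rng.uniform(-0.2, 0.8, (10, 10))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 0)
            mats.append(r)
        return mats

    def test_identical_cohorts_give_zero_difference_and_p_one(self):
        cohort = self._cohort(1)
        res = permutation_compare(cohort, list(cohort), metric="clustering",
                                  densities=[0.3], n_perm=50, seed=0)
        assert res[0.3].observed == pytest.approx(0.0)
        assert res[0.3].p_value == pytest.approx(1.0)

    def test_all_metrics_produce_results(self):
        res = permutation_compare(self._cohort(1), self._cohort(2),
                                  metric="efficiency", densities=[0.2, 0.4],
                                  n_perm=20, seed=0)
        for d in (0.2, 0.4):
            assert res[d].ci_low <= res[d].ci_high
            assert 0 < res[d].p_value <= 1

    def test_consistency_builder_requires_binary(self):
        with pytest.raises(ValueError, match="binary"):
            permutation_compare(self._cohort(1), self._cohort(2),
                                densities=[None], builder="consistency", n_perm=5)

    def test_cohort_difference_detected_via_consistency_builder(self):
        import dataclasses

        from netsig import demo_design
        from netsig import simulate as sim
        from netsig.connectome import PoissonThresholdConfig, combine_directional, \
            poisson_threshold

        base = demo_design(seed=0)
        cfg = PoissonThresholdConfig()

        def binary_cohort(design):
            return [poisson_threshold(combine_directional(s), cfg)
                    for s in sim.generate_structural_cohort(design)]

        hits = 0
        for rep in range(10):
            d1 = dataclasses.replace(base, seed=80_000 + 2 * rep, n_subjects=12,
                                     within_edge_prob=0.9)
            d2 = dataclasses.replace(base, seed=80_001 + 2 * rep, n_subjects=12,
                                     within_edge_prob=0.4)
            res = permutation_compare(binary_cohort(d1), binary_cohort(d2),
                                      metric="clustering", densities=[None],
                                      n_perm=200, seed=rep, builder="consistency")
            if res[None].p_value < 0.05:
                hits += 1
        assert hits >= 9


class TestPartitionInvariants:
    def test_partition_validates_contiguous_ids(self, rs6):
        with pytest.raises(ValueError, match="contiguous"):
            Partition(assignment={l: 3 for l in rs6}, q=0.0, roi_set=rs6)

    def test_modularity_q_bounds_on_random_partitions(self, two_k3):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = rng.integers(0, 3, 6)
            assert -1.0 <= modularity_q(two_k3, labels) <= 1.0
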