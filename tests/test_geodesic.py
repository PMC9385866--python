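import numpy as np
import pytest

from finnet.fisher import SegmentDistanceSpec
from finnet.geodesic import (
    GeodesicDistances,
    NeighbourGraph,
    all_pairs_geodesic,
    build_graph,
)

from _utils import IdentityFieldModel, brute_force_shortest_paths, is_connected


def random_connected_graph(rng, n):
    while True:
        mask = rng.random((n, n)) < 0.4
        iu = np.triu_indices(n, k=1)
        edges = np.array([(i, j) for i, j in zip(*iu) if mask[i, j]])
        if len(edges) and is_connected(n, edges):
            weights = rng.uniform(0.1, 5.0, size=len(edges))
            return edges, weights


class TestBuildGraph:
    def test_collinear_chain_under_identity_metric(self):
        model = IdentityFieldModel(n_inputs=2)
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        graph = build_graph(pts, model, k=1, spec=SegmentDistanceSpec(n_steps=4))
        assert graph.n_nodes == 3
        edge_set = {tuple(e) for e in graph.edges}
        assert edge_set == {(0, 1), (1, 2)}
        assert np.allclose(graph.weights, 1.0, atol=1e-10)

    def test_duplicate_points_zero_weight_edge(self):
        model = IdentityFieldModel(n_inputs=2)
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0]])
        graph = build_graph(pts, model, k=1)
        weight_01 = graph.weights[
            [i for i, e in enumerate(graph.edges.tolist()) if e == [0, 1]][0]
        ]
        assert weight_01 == 0.0

    def test_random_points_connected_with_min_degree(self, rng):
        model = IdentityFieldModel(n_inputs=3)
        pts = rng.standard_normal((20, 3))
        graph = build_graph(pts, model, k=4)
        assert np.all(graph.degrees() >= 4)
        assert is_connected(graph.n_nodes, graph.edges)  # brute-force oracle

    def test_component_bridging_recorded(self, trained_mlp):
        # two far-apart clusters with k=1 disconnect; augmentation bridges
        model = IdentityFieldModel(n_inputs=2)
        pts = np.vstack(
            [
                np.random.default_rng(0).normal(0, 0.1, (5, 2)),
                np.random.default_rng(1).normal(50, 0.1, (5, 2)),
            ]
        )
        graph = build_graph(pts, model, k=1)
        assert is_connected(graph.n_nodes, graph.edges)
        assert len(graph.augmented_edges) >= 1
        for i, j, w in graph.augmented_edges:
            assert w >= 0

    @pytest.mark.parametrize("k", [0, -1, 20, 25])
    def test_invalid_k_rejected(self, rng, k):
        model = IdentityFieldModel(n_inputs=2)
        with pytest.raises(ValueError):
            build_graph(rng.standard_normal((20, 2)), model, k=k)

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = IdentityFieldModel(n_inputs=2)
        graph = build_graph(rng.standard_normal((10, 2)), model, k=3)
        graph.save(tmp_path / "g.json")
        back = NeighbourGraph.load(tmp_path / "g.json")
        assert np.array_equal(back.edges, graph.edges)
        assert np.array_equal(back.weights, graph.weights)
        assert back.k_neighbours == graph.k_neighbours


class TestAllPairsGeodesic:
    def test_chain_distances(self):
        graph = NeighbourGraph(
            n_nodes=3, edges=[[0, 1], [1, 2]], weights=[1.0, 2.0], k_neighbours=1
        )
        d = all_pairs_geodesic(graph)
        assert d.matrix[0, 2] == 3.0
        assert d.matrix[0, 1] == 1.0

    def test_zero_diagonal_and_symmetry(self, rng):
        edges, weights = random_connected_graph(rng, 7)
        graph = NeighbourGraph(n_nodes=7, edges=edges, weights=weights, k_neighbours=3)
        d = all_pairs_geodesic(graph).matrix
        assert np.all(np.diag(d) == 0)
        assert np.array_equal(d, d.T)

    def test_exact_against_path_enumeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 9))
            edges, weights = random_connected_graph(rng, n)
            graph = NeighbourGraph(n_nodes=n, edges=edges, weights=weights, k_neighbours=1)
            d = all_pairs_geodesic(graph).matrix
            oracle = brute_force_shortest_paths(n, edges, weights)
            assert np.allclose(d, oracle, atol=1e-12)

    def test_triangle_inequality(self, rng):
        edges, weights = random_connected_graph(rng, 8)
        graph = NeighbourGraph(n_nodes=8, edges=edges, weights=weights, k_neighbours=3)
        d = all_pairs_geodesic(graph).matrix
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_never_exceeds_direct_edge(self, rng):
        edges, weights = random_connected_graph(rng, 8)
        graph = NeighbourGraph(n_nodes=8, edges=edges, weights=weights, k_neighbours=3)
        d = all_pairs_geodesic(graph).matrix
        for (i, j), w in zip(edges, weights):
            assert d[i, j] <= w + 1e-12

    def test_adding_edge_never_increases_distances(self, rng):
        edges, weights = random_connected_graph(rng, 7)
        graph = NeighbourGraph(n_nodes=7, edges=edges, weights=weights, k_neighbours=3)
        before = all_pairs_geodesic(graph).matrix
        # add a new shortcut edge
        existing = {tuple(e) for e in edges.tolist()}
        candidates = [
            (i, j) for i in range(7) for j in range(i + 1, 7) if (i, j) not in existing
        ]
        if candidates:
            i, j = candidates[0]
            graph2 = NeighbourGraph(
                n_nodes=7,
                edges=np.vstack([edges, [i, j]]),
                weights=np.append(weights, 0.05),
                k_neighbours=3,
            )
            after = all_pairs_geodesic(graph2).matrix
            assert np.all(after <= before + 1e-12)

    def test_identity_metric_complete_graph_equals_euclidean(self, rng):
        model = IdentityFieldModel(n_inputs=3)
        pts = rng.standard_normal((12, 3))
        graph = build_graph(pts, model, k=11, spec=SegmentDistanceSpec(n_steps=2))
        d = all_pairs_geodesic(graph).matrix
        euclid = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        assert np.allclose(d, euclid, atol=1e-8)

    def test_floyd_warshall_and_dijkstra_identical(self, rng):
        edges, weights = random_connected_graph(rng, 8)
        graph = NeighbourGraph(n_nodes=8, edges=edges, weights=weights, k_neighbours=3)
        fw = all_pairs_geodesic(graph, method="floyd-warshall").matrix
        dj = all_pairs_geodesic(graph, method="dijkstra").matrix
        assert np.allclose(fw, dj, atol=1e-12)

    def test_disconnected_graph_rejected(self):
        graph = NeighbourGraph(
            n_nodes=4, edges=[[0, 1], [2, 3]], weights=[1.0, 1.0], k_neighbours=1
        )
        with pytest.raises(ValueError, match="component"):
            all_pairs_geodesic(graph)

    def test_unknown_method_rejected(self):
        graph = NeighbourGraph(n_nodes=2, edges=[[0, 1]], weights=[1.0], k_neighbours=1)
        with pytest.raises(ValueError, match="method"):
            all_pairs_geodesic(graph, method="bellman")

    def test_csv_roundtrip(self, rng, tmp_path):
        edges, weights = random_connected_graph(rng, 6)
        graph = NeighbourGraph(n_nodes=6, edges=edges, weights=weights, k_neighbours=2)
        d = all_pairs_geodesic(graph)
        d.to_csv(tmp_path / "d.csv")
        back = GeodesicDistances.from_csv(tmp_path / "d.csv")
        assert np.allclose(back.matrix, d.matrix, atol=1e-12)


class TestNeighbourGraphValidation:
    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            NeighbourGraph(n_nodes=2, edges=[[0, 1]], weights=[-1.0], k_neighbours=1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            NeighbourGraph(n_nodes=2, edges=[[0, 1]], weights=[1.0, 2.0], k_neighbours=1)
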