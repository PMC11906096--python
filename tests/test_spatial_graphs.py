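import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay, Voronoi

from spagnn3d.spatial_graphs import (PatchGraph, astrocyte_neighborhood,
                                     combine_graphs, delaunay_cell_graph,
                                     intercellular_ccc_edges, label_homo_hetero,
                                     microenvironment, nearest_patches,
                                     patch_knn_graph, voronoi_interactions)
from tests.conftest import brute_force_knn_edges


def patch_frame(points, cell_ids=None, patch_ids=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return pd.DataFrame({
        "patch_id": patch_ids if patch_ids is not None else np.arange(n),
        "cell_id": cell_ids if cell_ids is not None else np.zeros(n, dtype=int),
        "x_um": points[:, 0], "y_um": points[:, 1],
        "z_um": points[:, 2] if points.shape[1] > 2 else 0.0,
    })


class TestPatchKnnGraph:
    def test_three_patches_k2_triangle(self):
        g = patch_knn_graph(patch_frame([[0, 0, 0], [1, 0, 0], [0, 1, 0]]), k=2)
        assert g.edge_set() == {(0, 1), (0, 2), (1, 2)}

    def test_two_patches_single_edge(self):
        g = patch_knn_graph(patch_frame([[0, 0, 0], [3, 0, 0]]), k=2)
        assert g.edge_set() == {(0, 1)}

    def test_matches_brute_force_on_random_centers(self, rng):
        pts = rng.uniform(0, 50, size=(30, 3))
        g = patch_knn_graph(patch_frame(pts), k=2)
        assert g.edge_set() == brute_force_knn_edges(pts, 2)

    def test_no_self_loops_allowed(self):
        with pytest.raises(ValueError, match="self-loops"):
            PatchGraph(patch_frame([[0, 0, 0], [1, 1, 1]]), np.array([[0, 0]]))


class TestCombineGraphs:
    def test_two_triangles_disjoint_union(self):
        t1 = patch_knn_graph(patch_frame([[0, 0, 0], [1, 0, 0], [0, 1, 0]]), k=2)
        t2 = patch_knn_graph(patch_frame([[9, 9, 0], [10, 9, 0], [9, 10, 0]],
                                         cell_ids=[1, 1, 1], patch_ids=[3, 4, 5]), k=2)
        combined, maps = combine_graphs([t1, t2])
        assert combined.n_nodes == 6 and combined.n_edges == 6
        assert nx.number_connected_components(combined.to_networkx()) == 2

    def test_empty_list(self):
        g, maps = combine_graphs([])
        assert g.n_nodes == 0 and maps == []

    def test_feature_rows_recoverable_via_index_map(self, rng):
        graphs = []
        for c in range(3):
            pts = rng.uniform(0, 10, size=(4, 3)) + 20 * c
            X = rng.normal(size=(4, 6))
            graphs.append(patch_knn_graph(
                patch_frame(pts, cell_ids=[c] * 4, patch_ids=np.arange(4) + 10 * c),
                k=2, X=X))
        combined, maps = combine_graphs(graphs)
        for g, m in zip(graphs, maps):
            np.testing.assert_array_equal(combined.X[m], g.X)


class TestVoronoiInteractions:
    def test_single_cell_no_borders(self, rng):
        pts = rng.uniform(0, 10, size=(12, 3))
        borders, pairs = voronoi_interactions(patch_frame(pts))
        assert len(borders) == 0 and pairs == set()

    def test_two_side_by_side_cells_symmetric_interaction(self, rng):
        left = rng.uniform([0, 0, 0], [10, 10, 2], size=(10, 3))
        right = rng.uniform([12, 0, 0], [22, 10, 2], size=(10, 3))
        frame = patch_frame(np.vstack([left, right]), cell_ids=[0] * 10 + [1] * 10)
        borders, pairs = voronoi_interactions(frame)
        assert pairs == {(0, 1)}
        per_cell = borders.groupby("cell_id").size()
        assert per_cell.get(0, 0) >= 1 and per_cell.get(1, 0) >= 1

    def test_matches_voronoi_ridge_oracle(self, rng):
        """Finite-Voronoi-ridge adjacency across cells equals the qhull
        Voronoi ridge list with unbounded ridges removed."""
        for trial in range(5):
            pts = rng.uniform(0, 40, size=(40, 3))
            cells = rng.integers(0, 4, size=40)
            frame = patch_frame(pts, cell_ids=cells)
            borders, _ = voronoi_interactions(frame)
            got = set(map(tuple, borders[["patch_id", "partner_cell_id"]].to_numpy()))
            vor = Voronoi(pts[:, :2])
            expect = set()
            for (u, v), rv in zip(vor.ridge_points, vor.ridge_vertices):
                if -1 in rv:
                    continue
                cu, cv = int(cells[u]), int(cells[v])
                if cu != cv:
                    expect.add((int(u), cv))
                    expect.add((int(v), cu))
            assert got == expect

    def test_collinear_input_jittered_with_warning(self):
        pts = np.column_stack([np.arange(6, dtype=float), np.zeros(6), np.zeros(6)])
        with pytest.warns(UserWarning, match="jitter"):
            voronoi_interactions(patch_frame(pts, cell_ids=[0, 0, 0, 1, 1, 1]))


class TestHomoHetero:
    def test_same_and_different_cluster(self):
        borders = pd.DataFrame(dict(patch_id=[0, 5], cell_id=[0, 1],
                                    partner_cell_id=[1, 0]))
        lab = label_homo_hetero(borders, {0: "A", 1: "A"})
        assert set(lab.interaction_type) == {"homotypic"}
        lab = label_homo_hetero(borders, {0: "A", 1: "B"})
        assert set(lab.interaction_type) == {"heterotypic"}

    def test_invariant_under_cluster_relabeling(self):
        borders = pd.DataFrame(dict(patch_id=[0, 1, 2], cell_id=[0, 1, 2],
                                    partner_cell_id=[1, 2, 0]))
        l1 = label_homo_hetero(borders, {0: 0, 1: 0, 2: 1})
        l2 = label_homo_hetero(borders, {0: 7, 1: 7, 2: 3})  # permuted names
        assert l1.interaction_type.tolist() == l2.interaction_type.tolist()


class TestMicroenvironment:
    def test_closed_ball_boundary(self):
        t = pd.DataFrame(dict(transcript_id=[0, 1, 2], gene="G", cell_id=0, fov_id=0,
                              x_um=[29.9, 30.1, 30.0], y_um=0.0, z_um=0.0))
        sub = microenvironment(t, (0, 0, 0), radius_um=30.0)
        assert sub.transcript_id.tolist() == [0, 2]  # 30.0 included (closed)

    def test_monotone_in_radius_and_matches_brute_force(self, rng):
        pts = rng.uniform(-50, 50, size=(500, 3))
        t = pd.DataFrame(dict(transcript_id=np.arange(500), gene="G",
                              x_um=pts[:, 0], y_um=pts[:, 1], z_um=np.abs(pts[:, 2]),
                              cell_id=rng.integers(-1, 3, size=500), fov_id=0))
        center = (5.0, -3.0, 20.0)
        prev = set()
        for r in (10.0, 30.0, 60.0):
            got = set(microenvironment(t, center, r).transcript_id)
            d = np.linalg.norm(t[["x_um", "y_um", "z_um"]].to_numpy() - center, axis=1)
            assert got == set(t.transcript_id[d <= r])
            assert prev <= got
            prev = got


class TestNearestPatches:
    def test_five_of_twenty_sorted(self, rng):
        pts = rng.uniform(0, 30, size=(20, 3))
        frame = patch_frame(pts)
        got = nearest_patches(frame, (0, 0, 0), n=5)
        assert len(got) == 5
        d = np.linalg.norm(pts - 0.0, axis=1)
        expect = frame.iloc[np.lexsort((frame.patch_id, d))[:5]].patch_id.tolist()
        assert got.patch_id.tolist() == expect

    def test_n_exceeding_count_returns_all(self):
        frame = patch_frame([[0, 0, 0], [1, 1, 1]])
        assert len(nearest_patches(frame, (0, 0, 0), n=10)) == 2


class TestDelaunayCellGraph:
    def test_four_noncoplanar_points_complete(self):
        cc = patch_frame([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]).rename(
            columns={"patch_id": "cell_id2"})
        cc = cc.rename(columns={"cell_id": "drop"}).rename(columns={"cell_id2": "cell_id"})
        g = delaunay_cell_graph(cc[["cell_id", "x_um", "y_um", "z_um"]])
        assert g.number_of_edges() == 6

    def test_two_points_fallback_edge(self):
        cc = pd.DataFrame(dict(cell_id=[0, 1], x_um=[0.0, 5.0], y_um=0.0, z_um=0.0))
        g = delaunay_cell_graph(cc)
        assert g.has_edge(0, 1)

    def test_matches_simplex_enumeration_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(30, 3))
        cc = pd.DataFrame(dict(cell_id=np.arange(30), x_um=pts[:, 0],
                               y_um=pts[:, 1], z_um=pts[:, 2]))
        g = delaunay_cell_graph(cc)
        tri = Delaunay(pts)
        expect = set()
        for simplex in tri.simplices:
            for a in range(4):
                for b in range(a + 1, 4):
                    u, v = sorted((int(simplex[a]), int(simplex[b])))
                    expect.add((u, v))
        assert {tuple(sorted(e)) for e in g.edges()} == expect

    def test_max_edge_pruning(self):
        cc = pd.DataFrame(dict(cell_id=[0, 1, 2], x_um=[0.0, 1.0, 100.0],
                               y_um=0.0, z_um=0.0))
        g = delaunay_cell_graph(cc, max_edge_um=10.0)
        assert g.has_edge(0, 1) and not g.has_edge(1, 2)


class TestNeighborhoodAndCCCEdges:
    def test_astrocyte_neighborhood_closed_one_hop(self):
        g = nx.star_graph(5)  # center 0
        assert astrocyte_neighborhood(g, 0) == set(range(6))
        assert astrocyte_neighborhood(g, 1) == {0, 1}
        g.add_node(99)
        assert astrocyte_neighborhood(g, 99) == {99}

    def test_three_shortest_intercellular_edges(self, rng):
        pts = rng.uniform(0, 30, size=(25, 3))
        cells = np.array([0] * 10 + [1] * 8 + [2] * 7)
        frame = patch_frame(pts, cell_ids=cells)
        got = intercellular_ccc_edges(frame, central_cell=0, n_edges=3)
        assert len(got) == 3
        assert got.length_um.is_monotonic_increasing
        # brute-force oracle: Delaunay edges, one endpoint in cell 0, 3 shortest
        tri = Delaunay(pts)
        cand = set()
        for s in tri.simplices:
            for a in range(4):
                for b in range(a + 1, 4):
                    u, v = sorted((int(s[a]), int(s[b])))
                    cand.add((u, v))
        lengths = sorted((np.linalg.norm(pts[u] - pts[v]), u, v) for u, v in cand
                         if (cells[u] == 0) != (cells[v] == 0))
        expect = [l for l, _, _ in lengths[:3]]
        assert np.allclose(sorted(got.length_um), expect)

    def test_partner_type_filter_can_empty(self, rng):
        pts = rng.uniform(0, 10, size=(12, 3))
        cells = np.array([0] * 6 + [1] * 6)
        frame = patch_frame(pts, cell_ids=cells)
        got = intercellular_ccc_edges(frame, central_cell=0, n_edges=3,
                                      partner_cells=[2])
        assert len(got) == 0
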