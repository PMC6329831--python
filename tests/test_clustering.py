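"""Louvain-Jaccard scan, silhouettes and outlier-reassignment refinement."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from conftest import brute_force_silhouette, gaussian_blobs
from cortexpipe.clustering import (
    ClusterAssignment,
    NeighborGraph,
    build_jaccard_knn,
    detect_communities,
    refine_assignments,
    scan_neighborhood_sizes,
    silhouette_widths,
    spearman_distance_matrix,
)


class TestSpearmanDistance:
    def test_identical_and_reversed_vectors(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        coords = np.vstack([v, v, v[::-1]])
        d = spearman_distance_matrix(coords)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_matches_naive_oracle(self, rng):
        coords = rng.normal(size=(10, 7))
        d = spearman_distance_matrix(coords)
        for i in range(10):
            for j in range(10):
                rho = spearmanr(coords[i], coords[j]).statistic
                assert d[i, j] == pytest.approx(1.0 - rho, abs=1e-12)

    def test_constant_vector_distance_one(self, rng):
        coords = rng.normal(size=(4, 5))
        coords[1] = 2.0
        d = spearman_distance_matrix(coords)
        assert np.allclose(d[1, [0, 2, 3]], 1.0)

    def test_too_few_dims_rejected(self):
        with pytest.raises(ValueError):
            spearman_distance_matrix(np.zeros((5, 2)))


class TestJaccardKnn:
    def test_identical_neighbor_sets_weight_one(self):
        # two coincident points inside a far-apart trio share all neighbors
        pts = np.array(
            [[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [10.1, 0.0], [20.0, 5.0]]
        )
        g = build_jaccard_knn(pts, k=3)
        weights = {tuple(e): w for e, w in zip(map(tuple, g.edges), g.weights)}
        assert weights[(0, 1)] == pytest.approx(1.0)

    def test_two_blob_toy_graph_splits(self, rng):
        coords, labels = gaussian_blobs(rng, (6, 6), n_dims=3, noise=0.05)
        g = build_jaccard_knn(coords, k=3)
        cross = [
            (i, j) for i, j in g.edges if labels[i] != labels[j]
        ]
        assert cross == []
        comm = detect_communities(g, seed=0)
        assert adjusted_rand_score(labels, comm) == 1.0

    def test_weights_in_unit_interval_and_no_self_loops(self, rng):
        coords = rng.normal(size=(40, 4))
        g = build_jaccard_knn(coords, k=5)
        assert np.all((g.weights > 0) & (g.weights <= 1))
        assert np.all(g.edges[:, 0] != g.edges[:, 1])

    def test_bad_k_rejected(self, rng):
        coords = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            build_jaccard_knn(coords, k=0)
        with pytest.raises(ValueError):
            build_jaccard_knn(coords, k=10)


def _clique_graph(sizes, bridges=()):
    """Union of cliques with optional weak bridge edges between them."""
    edges, weights = [], []
    offsets = np.cumsum([0] + list(sizes))
    for b, size in enumerate(sizes):
        lo = offsets[b]
        for i in range(lo, lo + size):
            for j in range(i + 1, lo + size):
                edges.append((i, j))
                weights.append(1.0)
    for i, j in bridges:
        edges.append((i, j))
        weights.append(0.05)
    return NeighborGraph(
        n_cells=offsets[-1],
        edges=np.array(edges),
        weights=np.array(weights),
        k_neighbors=max(sizes),
    )


class TestDetectCommunities:
    def test_disconnected_cliques(self):
        g = _clique_graph((10, 10))
        labels = detect_communities(g, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:10])) == 1
        assert len(np.unique(labels[10:])) == 1

    def test_single_clique(self):
        g = _clique_graph((8,))
        assert len(np.unique(detect_communities(g, seed=0))) == 1

    def test_ring_of_bridged_cliques_beats_single_community(self):
        sizes = (8, 8, 8, 8)
        bridges = [(7, 8), (15, 16), (23, 24), (31, 0)]
        g = _clique_graph(sizes, bridges)
        labels = detect_communities(g, seed=0)
        assert len(np.unique(labels)) == 4
        ig = g.to_igraph()
        q_found = ig.modularity(list(labels), weights="weight")
        q_single = ig.modularity([0] * g.n_cells, weights="weight")
        assert q_found >= q_single

    def test_deterministic_under_seed(self, rng):
        coords, _ = gaussian_blobs(rng, (30, 30, 30), n_dims=5)
        g = build_jaccard_knn(coords, k=10)
        l1 = detect_communities(g, seed=5)
        l2 = detect_communities(g, seed=5)
        assert np.array_equal(l1, l2)


class TestSilhouetteWidths:
    def test_duplicated_point_clusters_width_one(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 5.0
        d[3:, :3] = 5.0
        labels = np.array([0, 0, 0, 1, 1, 1])
        widths, neighbor = silhouette_widths(d, labels)
        assert np.allclose(widths, 1.0)
        assert np.array_equal(neighbor, np.array([1, 1, 1, 0, 0, 0]))

    def test_misplaced_cell_negative(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 5.0
        d[3:, :3] = 5.0
        labels = np.array([0, 0, 1, 1, 1, 1])  # cell 2 put in the far cluster
        widths, _ = silhouette_widths(d, labels)
        assert widths[2] < 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            coords = rng.normal(size=(30, 4))
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
            labels = rng.integers(0, 3, size=30)
            if len(np.unique(labels)) < 2:
                continue
            widths, _ = silhouette_widths(d, labels)
            assert np.allclose(widths, brute_force_silhouette(d, labels), atol=1e-12)

    def test_matches_sklearn_on_multi_member_clusters(self, rng):
        coords = rng.normal(size=(40, 4))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        labels = np.repeat([0, 1, 2, 3], 10)
        widths, _ = silhouette_widths(d, labels)
        assert np.allclose(widths, silhouette_samples(d, labels, metric="precomputed"), atol=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_widths(np.zeros((4, 4)), np.zeros(4))

    def test_singleton_cluster_width_zero(self):
        d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        widths, _ = silhouette_widths(d, np.array([0, 0, 1]))
        assert widths[2] == 0.0


class TestScan:
    def test_three_blob_recovery(self, rng):
        coords, labels = gaussian_blobs(rng, (100, 100, 100))
        scan = scan_neighborhood_sizes(coords, k_min=10, k_max=40, k_step=5, seed=0)
        assert adjusted_rand_score(labels, scan.assignment.labels) == 1.0
        eligible = [r for r in scan.records if not np.isnan(r["mean_silhouette"])]
        best = max(eligible, key=lambda r: r["mean_silhouette"])
        assert scan.selected_k == best["k"]

    def test_reported_mean_silhouette_self_consistent(self, rng):
        coords, _ = gaussian_blobs(rng, (50, 50))
        scan = scan_neighborhood_sizes(coords, k_min=10, k_max=20, k_step=5, seed=0)
        widths, _ = silhouette_widths(scan.distance, scan.assignment.labels)
        assert scan.assignment.mean_silhouette == pytest.approx(widths.mean(), abs=1e-12)

    def test_stride_touches_only_grid_ks(self, rng):
        coords, _ = gaussian_blobs(rng, (40, 40))
        scan = scan_neighborhood_sizes(coords, k_min=10, k_max=30, k_step=5, seed=0)
        assert [r["k"] for r in scan.records] == [10, 15, 20, 25, 30]

    def test_k_max_bounded_by_cells(self, rng):
        coords, _ = gaussian_blobs(rng, (10, 10))
        with pytest.raises(ValueError):
            scan_neighborhood_sizes(coords, k_min=10, k_max=25, seed=0)


def _two_blob_distance(rng, n_per_blob=20):
    coords, labels = gaussian_blobs(rng, (n_per_blob, n_per_blob), n_dims=6)
    return spearman_distance_matrix(coords), labels, coords


class TestRefineAssignments:
    def test_no_outliers_is_identity(self, rng):
        d, labels, _ = _two_blob_distance(rng)
        widths, _ = silhouette_widths(d, labels)
        initial = ClusterAssignment(
            labels=labels.copy(), silhouettes=widths, flags=np.zeros(len(labels), bool)
        )
        out = refine_assignments(d, initial)
        assert np.array_equal(out.labels, labels)
        assert out.history == []

    def test_misassigned_cells_move_to_neighbor_cluster(self, rng):
        d, truth, _ = _two_blob_distance(rng)
        labels = truth.copy()
        labels[:5] = 1  # five blob-0 cells planted in cluster 1
        widths, _ = silhouette_widths(d, labels)
        initial = ClusterAssignment(
            labels=labels, silhouettes=widths, flags=np.zeros(len(labels), bool)
        )
        out = refine_assignments(d, initial)
        assert adjusted_rand_score(truth, out.labels) == 1.0
        moved = {h["cell"] for h in out.history if h["event"] == "move"}
        assert moved == set(range(5))
        assert np.all(out.silhouettes[:5] >= -0.1)

    def test_coherent_outlier_group_forms_novel_cluster(self, rng):
        # a tight 12-cell blob sits near cluster 1 but is labeled cluster 0,
        # so its cells are extreme outliers; pooled, they clear the novel
        # cluster rule (>= 10 cells, positive tentative silhouette)
        base = np.arange(1.0, 7.0)
        c0, c1 = base, base[::-1]
        c2 = c1.copy()
        c2[[0, 1]] = c2[[1, 0]]  # near-c1 rank pattern, still distinct
        centers = [c0, c1, c2]
        sizes = (20, 20, 12)
        coords = np.vstack(
            [centers[b] + rng.normal(0, 0.02, size=(s, 6)) for b, s in enumerate(sizes)]
        )
        truth = np.repeat([0, 1, 2], sizes)
        d = spearman_distance_matrix(coords)
        labels = truth.copy()
        labels[truth == 2] = 0  # the 12-cell blob mislabeled into cluster 0
        widths, _ = silhouette_widths(d, labels)
        initial = ClusterAssignment(
            labels=labels, silhouettes=widths, flags=np.zeros(len(labels), bool)
        )
        out = refine_assignments(d, initial)
        novel_events = [h for h in out.history if h["event"] == "novel"]
        assert len(novel_events) >= 12
        assert adjusted_rand_score(truth, out.labels) == 1.0

    def test_conservation_and_flag_permanence(self, rng):
        coords, truth = gaussian_blobs(rng, (15, 15, 15), n_dims=6, noise=1.0)
        d = spearman_distance_matrix(coords)
        rng2 = np.random.default_rng(1)
        labels = truth.copy()
        scramble = rng2.choice(45, size=10, replace=False)
        labels[scramble] = rng2.integers(0, 3, size=10)
        widths, _ = silhouette_widths(d, labels)
        initial = ClusterAssignment(
            labels=labels.copy(), silhouettes=widths, flags=np.zeros(45, bool)
        )
        out = refine_assignments(d, initial)
        assert len(out.labels) == 45  # no cell dropped or duplicated
        flagged = np.flatnonzero(out.flags)
        for cell in flagged:
            assert out.labels[cell] == labels[cell]  # flagged -> original label
            later_moves = [
                h for h in out.history
                if h["cell"] == cell and h["event"] != "revert_flag"
                and h["iter"] > max(
                    hh["iter"] for hh in out.history
                    if hh["cell"] == cell and hh["event"] == "revert_flag"
                )
            ]
            assert later_moves == []

    def test_outlier_count_does_not_increase(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            coords, truth = gaussian_blobs(r, (25, 25, 25), n_dims=6, noise=0.8)
            d = spearman_distance_matrix(coords)
            labels = truth.copy()
            idx = r.choice(75, size=8, replace=False)
            labels[idx] = (truth[idx] + 1) % 3
            widths, _ = silhouette_widths(d, labels)
            before = int((widths < -0.1).sum())
            initial = ClusterAssignment(
                labels=labels, silhouettes=widths, flags=np.zeros(75, bool)
            )
            out = refine_assignments(d, initial)
            after = int((out.silhouettes < -0.1).sum())
            assert after <= before

    def test_invalid_iterations_rejected(self, rng):
        d, labels, _ = _two_blob_distance(rng)
        widths, _ = silhouette_widths(d, labels)
        initial = ClusterAssignment(
            labels=labels, silhouettes=widths, flags=np.zeros(len(labels), bool)
        )
        with pytest.raises(ValueError):
            refine_assignments(d, initial, n_iter=0)
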