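"""Bipartite graph assembly, kNN graphs, normalization and augmentation."""

import numpy as np
import pytest

from dreamgnn.datasets_io import AssociationTable, EmbeddingMatrix, SimilarityTable
from dreamgnn.graph_construction import (
    BipartiteAssociationGraph,
    SimilarityGraph,
    build_bipartite_graph,
    edge_dropout,
    gaussian_perturb,
    knn_similarity_graph,
    normalize_adjacency,
)


@pytest.fixture
def assoc22():
    return AssociationTable(["d0", "d1"], ["m0", "m1"], np.array([[1, 0], [0, 0]]))


class TestBuildBipartiteGraph:
    def test_sampled_unknown_comes_from_training_unknowns(self, assoc22):
        g = build_bipartite_graph(assoc22, np.ones((2, 2)), 1, rng=0)
        assert len(g.known) == 1 and tuple(g.known[0]) == (0, 0)
        assert len(g.unknown) == 1
        assert tuple(g.unknown[0]) in {(0, 1), (1, 0), (1, 1)}

    def test_zero_sample_leaves_known_intact(self, assoc22):
        g = build_bipartite_graph(assoc22, np.ones((2, 2)), 0, rng=0)
        assert len(g.unknown) == 0 and len(g.known) == 1

    def test_test_fold_pairs_never_become_edges(self, rng):
        m = (rng.random((8, 6)) < 0.4).astype(int)
        m[0, 0] = 1
        assoc = AssociationTable(
            [f"d{i}" for i in range(8)], [f"m{j}" for j in range(6)], m
        )
        mask = np.ones((8, 6), dtype=bool)
        test_pairs = [(0, 0), (3, 2), (5, 5)]
        for i, j in test_pairs:
            mask[i, j] = False
        for seed in range(5):
            g = build_bipartite_graph(assoc, mask, 10, rng=seed)
            edges = {tuple(e) for e in g.known} | {tuple(e) for e in g.unknown}
            assert edges.isdisjoint(test_pairs)

    def test_oversized_sample_errors(self, assoc22):
        with pytest.raises(ValueError, match="unknown"):
            build_bipartite_graph(assoc22, np.ones((2, 2)), 99, rng=0)


class TestKnnGraph:
    def test_k_equals_n_minus_1_gives_complete_graph(self, rng):
        emb = EmbeddingMatrix(list("abcde"), rng.normal(size=(5, 3)) + 3.0)
        g = knn_similarity_graph(emb, 4, metric="cosine")
        off_diag = g.weights[~np.eye(5, dtype=bool)]
        assert (off_diag > 0).all()

    def test_neighbor_sets_match_bruteforce_sort(self, rng):
        # 6 points in 2 tight clusters
        centers = np.array([[5.0, 0.0], [0.0, 5.0]])
        pts = np.vstack([centers[i % 2] + rng.normal(0, 0.2, 2) for i in range(6)])
        emb = EmbeddingMatrix([f"e{i}" for i in range(6)], pts)
        k = 2
        g = knn_similarity_graph(emb, k, metric="cosine", symmetrize="union")
        unit = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        sim = np.clip(unit @ unit.T, 0, None)
        np.fill_diagonal(sim, -np.inf)
        select = np.zeros((6, 6), dtype=bool)
        for i in range(6):
            select[i, np.argsort(-sim[i])[:k]] = True
        keep = select | select.T
        assert ((g.weights > 0) == keep).all()
        np.testing.assert_allclose(g.weights[keep], np.maximum(sim, sim.T)[keep])

    def test_weights_are_verbatim_similarities_not_binarized(self, rng):
        base = rng.random((7, 7))
        sim = np.clip((base + base.T) / 2, 0, 1)
        np.fill_diagonal(sim, 1.0)
        table = SimilarityTable([f"e{i}" for i in range(7)], sim)
        g = knn_similarity_graph(table, 3, metric="precomputed")
        nz = g.weights > 0
        assert set(np.round(g.weights[nz], 12)) <= set(np.round(sim[~np.eye(7, dtype=bool)], 12))

    def test_zero_norm_row_names_entity(self):
        emb = EmbeddingMatrix(["ok", "bad"], np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="bad"):
            knn_similarity_graph(emb, 1, metric="cosine")

    def test_mutual_symmetrization_is_subset_of_union(self, rng):
        emb = EmbeddingMatrix([f"e{i}" for i in range(9)], rng.normal(size=(9, 4)))
        gu = knn_similarity_graph(emb, 2, symmetrize="union")
        gm = knn_similarity_graph(emb, 2, symmetrize="mutual")
        assert ((gm.weights > 0) <= (gu.weights > 0)).all()


class TestNormalizeAdjacency:
    def test_empty_graph_normalizes_to_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((3, 3))), np.eye(3))

    def test_two_node_path_closed_form(self):
        np.testing.assert_allclose(
            normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]])),
            np.full((2, 2), 0.5),
        )

    def test_weighted_triangle_matches_elementwise_formula(self, rng):
        w = np.array([[0, 0.5, 0.2], [0.5, 0, 0.9], [0.2, 0.9, 0]])
        out = normalize_adjacency(w)
        a = w + np.eye(3)
        d = a.sum(axis=1)
        for i in range(3):
            for j in range(3):
                assert out[i, j] == pytest.approx(a[i, j] / np.sqrt(d[i] * d[j]))

    def test_spectral_radius_at_most_one(self, rng):
        for _ in range(5):
            base = rng.random((6, 6))
            w = (base + base.T) / 2
            np.fill_diagonal(w, 0)
            eig = np.linalg.eigvalsh(normalize_adjacency(w))
            assert np.abs(eig).max() <= 1 + 1e-10


class TestAugmentation:
    def test_edge_dropout_limits(self, rng):
        g = BipartiteAssociationGraph(3, 3, [[0, 0], [1, 1]], [[2, 2]])
        same = edge_dropout(g, 0.0, rng)
        assert len(same.known) == 2 and len(same.unknown) == 1
        none = edge_dropout(g, 1.0, rng)
        assert len(none.known) == 0 and len(none.unknown) == 0

    def test_edge_dropout_retention_rate_is_binomial(self):
        n = 10_000
        pairs = np.column_stack([np.arange(n) % 500, np.arange(n) // 500])
        m = np.zeros((500, 20), dtype=int)
        m[pairs[:, 0], pairs[:, 1]] = 1
        g = BipartiteAssociationGraph(500, 20, pairs, np.empty((0, 2), dtype=int))
        kept = len(edge_dropout(g, 0.10, np.random.default_rng(0)).known)
        se = np.sqrt(n * 0.9 * 0.1)
        assert abs(kept - 0.9 * n) < 3 * se

    def test_gaussian_perturb_moments_and_identity(self, rng):
        x = np.zeros((300, 300))
        noisy = gaussian_perturb(x, 0.05, rng)
        assert np.std(noisy - x) == pytest.approx(0.05, rel=0.02)
        np.testing.assert_array_equal(gaussian_perturb(x, 0.0, rng), x)
        with pytest.raises(ValueError):
            gaussian_perturb(x, -0.1, rng)

    def test_dropout_probability_validated(self, rng):
        g = BipartiteAssociationGraph(2, 2, [[0, 0]], [])
        with pytest.raises(ValueError):
            edge_dropout(g, 1.5, rng)


def test_duplicate_pair_across_relations_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        BipartiteAssociationGraph(2, 2, [[0, 0]], [[0, 0]])
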