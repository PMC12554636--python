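"""Relational message passing: basis composition, normalization, layer averaging."""

import numpy as np
import pytest

from dreamgnn import nn
from dreamgnn.graph_construction import BipartiteAssociationGraph, normalize_adjacency
from dreamgnn.topology_encoder import (
    RelationBasisWeights,
    basis_compose,
    relation_norm_matrices,
    topology_encode,
    topology_layer,
)


def naive_layer(h, g, w_known, w_unknown, activation=lambda x: np.maximum(x, 0)):
    """Double-loop reference implementation of the message-passing rule."""
    n = g.n_nodes
    out = np.zeros((n, w_known.shape[1]))
    for rel, w in (("known", w_known), ("unknown", w_unknown)):
        adj = g.adjacency(rel)
        deg = adj.sum(axis=1)
        for v in range(n):
            for u in range(n):
                if adj[v, u]:
                    out[v] += (h[u] @ w) / np.sqrt(deg[u] * deg[v])
    return activation(out)


def identity_weights(dim, n_layers=1):
    bases = [nn.Tensor(np.eye(dim)[None, :, :]) for _ in range(n_layers)]
    coeffs = [nn.Tensor(np.ones((2, 1))) for _ in range(n_layers)]
    return RelationBasisWeights(bases, coeffs)


class TestBasisCompose:
    def test_single_basis_unit_coefficient_returns_basis(self, rng):
        v = rng.normal(size=(1, 3, 4))
        w = basis_compose(np.ones((2, 1)), v)
        np.testing.assert_allclose(w[0], v[0])
        np.testing.assert_allclose(w[1], v[0])

    def test_identity_coefficients_recover_unrestricted_weights(self, rng):
        v = rng.normal(size=(2, 3, 3))
        w = basis_compose(np.eye(2), v)
        np.testing.assert_allclose(w, v)

    def test_matches_explicit_three_term_sum(self, rng):
        a = rng.normal(size=(2, 3))
        v = rng.normal(size=(3, 4, 5))
        w = basis_compose(a, v)
        for r in range(2):
            expected = sum(a[r, b] * v[b] for b in range(3))
            np.testing.assert_allclose(w[r], expected, atol=1e-12)

    def test_count_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            basis_compose(np.ones((2, 2)), rng.normal(size=(3, 2, 2)))


class TestTopologyLayer:
    def test_single_edge_normalization_is_one(self, rng):
        g = BipartiteAssociationGraph(1, 1, [[0, 0]], [])
        h = rng.normal(size=(2, 3))
        w = rng.normal(size=(3, 3))
        weights = RelationBasisWeights([nn.Tensor(w[None])], [nn.Tensor(np.ones((2, 1)))])
        out = topology_layer(nn.Tensor(h), g, weights, 0, activation="identity")
        np.testing.assert_allclose(out.data[0], h[1] @ w, atol=1e-12)
        np.testing.assert_allclose(out.data[1], h[0] @ w, atol=1e-12)

    def test_isolated_node_preactivation_is_zero(self, toy):
        h = nn.Tensor(np.ones((7, 2)))
        g = BipartiteAssociationGraph(4, 3, [[0, 0]], [])
        weights = identity_weights(2)
        out = topology_layer(h, g, weights, 0, activation="identity")
        np.testing.assert_array_equal(out.data[2], 0.0)  # drug 2 has no edges

    def test_star_matches_naive_double_loop(self, rng):
        g = BipartiteAssociationGraph(3, 1, [[0, 0], [1, 0], [2, 0]], [])
        h = rng.normal(size=(4, 3))
        w = rng.normal(size=(3, 3))
        weights = RelationBasisWeights([nn.Tensor(w[None])], [nn.Tensor(np.ones((2, 1)))])
        out = topology_layer(nn.Tensor(h), g, weights, 0)
        np.testing.assert_allclose(out.data, naive_layer(h, g, w, w), atol=1e-10)

    def test_toy_example_identity_weights_matches_hand_computation(self, toy):
        weights = identity_weights(2)
        out = topology_layer(
            nn.Tensor(toy.node_features), toy.graph, weights, 0, activation="identity"
        )
        np.testing.assert_allclose(out.data, toy.expected_layer_identity, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        g = BipartiteAssociationGraph(3, 2, [[0, 0], [1, 1], [2, 0]], [[1, 0]])
        h = rng.normal(size=(5, 4))
        w = rng.normal(size=(2, 4, 4))
        weights = RelationBasisWeights([nn.Tensor(w)], [nn.Tensor(np.eye(2))])
        out = topology_layer(nn.Tensor(h), g, weights, 0).data
        # permute drugs [0,1,2] -> [2,0,1] and diseases [0,1] -> [1,0]
        drug_perm, dis_perm = np.array([2, 0, 1]), np.array([1, 0])
        inv_d = np.argsort(drug_perm)
        inv_m = np.argsort(dis_perm)
        known_p = [[inv_d[i], inv_m[j]] for i, j in g.known]
        unknown_p = [[inv_d[i], inv_m[j]] for i, j in g.unknown]
        gp = BipartiteAssociationGraph(3, 2, known_p, unknown_p)
        node_perm = np.concatenate([drug_perm, dis_perm + 3])
        out_p = topology_layer(nn.Tensor(h[node_perm]), gp, weights, 0).data
        np.testing.assert_allclose(out_p, out[node_perm], atol=1e-10)

    def test_unrestricted_basis_reduction_matches_direct_relational_layer(self, rng):
        # B = |R| with identity coefficients reproduces independent W_r exactly
        g = BipartiteAssociationGraph(2, 2, [[0, 0], [1, 1]], [[0, 1]])
        h = rng.normal(size=(4, 3))
        w_known, w_unknown = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        weights = RelationBasisWeights(
            [nn.Tensor(np.stack([w_known, w_unknown]))], [nn.Tensor(np.eye(2))]
        )
        out = topology_layer(nn.Tensor(h), g, weights, 0)
        np.testing.assert_allclose(out.data, naive_layer(h, g, w_known, w_unknown), atol=1e-10)

    def test_identity_single_relation_equals_normalized_adjacency_product(self, rng):
        # sigma=identity, one relation, unit weights: layer = A_hat_no_selfloop @ h
        g = BipartiteAssociationGraph(2, 2, [[0, 0], [0, 1], [1, 1]], [])
        h = rng.normal(size=(4, 2))
        weights = identity_weights(2)
        out = topology_layer(nn.Tensor(h), g, weights, 0, activation="identity")
        adj = g.adjacency("known")
        deg = adj.sum(axis=1)
        inv = np.where(deg > 0, 1 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
        a_hat = adj * inv[:, None] * inv[None, :]
        np.testing.assert_allclose(out.data, a_hat @ h, atol=1e-12)


class TestTopologyEncode:
    def test_single_layer_average_is_that_layer(self, toy):
        weights = identity_weights(2, n_layers=1)
        emb = topology_encode(nn.Tensor(toy.node_features), toy.graph, weights,
                              activation="identity")
        np.testing.assert_allclose(emb.z_topo.data, emb.per_layer[0].data)

    def test_two_layer_average_matches_sequential_application(self, toy, rng):
        w = [rng.normal(size=(1, 2, 2)) for _ in range(2)]
        weights = RelationBasisWeights(
            [nn.Tensor(wi) for wi in w],
            [nn.Tensor(np.ones((2, 1))) for _ in range(2)],
        )
        emb = topology_encode(nn.Tensor(toy.node_features), toy.graph, weights)
        h1 = naive_layer(toy.node_features, toy.graph, w[0][0], w[0][0])
        h2 = naive_layer(h1, toy.graph, w[1][0], w[1][0])
        np.testing.assert_allclose(emb.z_topo.data, (h1 + h2) / 2, atol=1e-10)

    def test_gradients_flow_to_bases_and_coefficients(self, toy):
        rng = np.random.default_rng(0)
        weights = RelationBasisWeights.init(2, 4, 2, 3, rng)
        emb = topology_encode(nn.Tensor(toy.node_features), toy.graph, weights)
        nn.sum_(emb.z_topo).backward()
        assert weights.bases[0].grad is not None and np.abs(weights.bases[0].grad).sum() > 0
        assert weights.coeffs[0].grad is not None
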