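"""Relation-aware message passing on the bipartite interaction graph.

The encoder is a multilayer graph-convolutional matrix-completion operator:
at every layer each node aggregates messages from its neighbors under each
relation (known / unknown association), normalized by the geometric mean of
the two endpoint degrees under that relation,

    h_v <- sigma( sum_r sum_{u in N_r(v)} W_r h_u / sqrt(|N_r(u)| |N_r(v)|) ),

with the relation weight matrices factorized through a shared basis,
W_r = sum_b a_rb V_b. The final topology embedding is the arithmetic mean of
the L layer outputs, a multiscale summary over neighborhood depths.

Functions accept either numpy arrays or :mod:`dreamgnn.nn` tensors, so the
same code path serves training (with gradients) and plain inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .graph_construction import RELATIONS, BipartiteAssociationGraph

__all__ = [
    "RelationBasisWeights",
    "TopologyEmbedding",
    "basis_compose",
    "relation_norm_matrices",
    "topology_layer",
    "topology_encode",
]

_ACTIVATIONS = {"relu": nn.relu, "tanh": nn.tanh, "identity": nn.identity}


@dataclass
class RelationBasisWeights:
    """Per-layer shared bases and per-relation mixing coefficients.

    ``bases[l]`` has shape (B, d_in_l, d_out_l); ``coeffs[l]`` has shape
    (R_eff, B) where R_eff is the number of effective relations: 2 when the
    drug->disease and disease->drug directions share parameters, 4 when the
    sharing ablation unties them (each relation splits by message-source
    entity type).
    """

    bases: list          # list over layers of Tensor/ndarray (B, d_in, d_out)
    coeffs: list         # list over layers of Tensor/ndarray (R_eff, B)
    share_direction_params: bool = True

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.coeffs):
            raise ValueError("bases and coeffs must have one entry per layer")
        expected_r = 2 if self.share_direction_params else 4
        for l, (v, a) in enumerate(zip(self.bases, self.coeffs)):
            v_shape = v.shape if hasattr(v, "shape") else np.shape(v)
            a_shape = a.shape if hasattr(a, "shape") else np.shape(a)
            if len(v_shape) != 3:
                raise ValueError(f"layer {l}: bases must be (B, d_in, d_out)")
            if a_shape != (expected_r, v_shape[0]):
                raise ValueError(
                    f"layer {l}: coeffs shape {a_shape} != ({expected_r}, {v_shape[0]})"
                )

    @property
    def n_layers(self) -> int:
        return len(self.bases)

    @classmethod
    def init(
        cls,
        d_in: int,
        hidden: int,
        n_layers: int,
        n_bases: int,
        rng: np.random.Generator,
        share_direction_params: bool = True,
    ) -> "RelationBasisWeights":
        r_eff = 2 if share_direction_params else 4
        bases, coeffs = [], []
        for l in range(n_layers):
            din = d_in if l == 0 else hidden
            bases.append(nn.parameter((n_bases, din, hidden), rng=rng,
                                      scale=float(np.sqrt(2.0 / (din + hidden)))))
            coeffs.append(nn.parameter(
                np.ones((r_eff, n_bases)) / n_bases
                + rng.normal(0, 0.1, size=(r_eff, n_bases))))
        return cls(bases, coeffs, share_direction_params)

    def parameters(self) -> list:
        return [*self.bases, *self.coeffs]


@dataclass
class TopologyEmbedding:
    per_layer: list       # L matrices over all nodes
    z_topo: object        # mean over layers

    def __post_init__(self) -> None:
        if not self.per_layer:
            raise ValueError("at least one layer output is required")


def basis_compose(coeffs, bases):
    """W_r = sum_b a_rb V_b for every relation r.

    ``coeffs`` is (R, B), ``bases`` is (B, d_in, d_out); returns (R, d_in, d_out).
    Implemented as a matmul over flattened bases so it is differentiable.
    """
    b_shape = bases.shape
    if coeffs.shape[-1] != b_shape[0]:
        raise ValueError(
            f"coefficient count {coeffs.shape[-1]} != basis count {b_shape[0]}"
        )
    flat = bases.reshape(b_shape[0], b_shape[1] * b_shape[2])
    mixed = nn.matmul(coeffs, flat)
    return mixed.reshape(coeffs.shape[0], b_shape[1], b_shape[2])


def relation_norm_matrices(g: BipartiteAssociationGraph) -> dict[str, np.ndarray]:
    """Per-relation message-normalization matrices on the realized graph.

    ``C_r[v, u] = 1/sqrt(|N_r(u)| |N_r(v)|)`` for u in N_r(v), else 0. Nodes
    isolated under a relation simply receive/send nothing (their rows and
    columns are zero), which yields a pre-activation of exactly 0.
    """
    out = {}
    for rel in RELATIONS:
        a = g.adjacency(rel)
        deg = a.sum(axis=1)
        inv_sqrt = np.zeros_like(deg)
        nz = deg > 0
        inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
        out[rel] = a * inv_sqrt[:, None] * inv_sqrt[None, :]
    return out


def _layer_preactivation(h, g, bases_l, coeffs_l, share_direction_params, norms):
    w = basis_compose(coeffs_l, bases_l)
    n_d = g.n_drugs
    pre = None
    for ri, rel in enumerate(RELATIONS):
        c = norms[rel]
        if share_direction_params:
            msg = nn.matmul(h, w[ri])
            term = nn.matmul(c, msg)
        else:
            # relation splits by message-source entity type: indices 2*ri
            # (from drugs) and 2*ri + 1 (from diseases)
            msg_d = nn.matmul(h[:n_d], w[2 * ri])
            msg_m = nn.matmul(h[n_d:], w[2 * ri + 1])
            term = nn.matmul(c[:, :n_d], msg_d) + nn.matmul(c[:, n_d:], msg_m)
        pre = term if pre is None else pre + term
    return pre


def topology_layer(
    h,
    g: BipartiteAssociationGraph,
    weights: RelationBasisWeights,
    layer: int,
    activation: str = "relu",
    norms: dict[str, np.ndarray] | None = None,
):
    """One message-passing step; ``h`` covers drugs then diseases row-wise."""
    n_rows = h.shape[0]
    if n_rows != g.n_nodes:
        raise ValueError(f"h has {n_rows} rows but graph has {g.n_nodes} nodes")
    act = _ACTIVATIONS[activation]
    if norms is None:
        norms = relation_norm_matrices(g)
    pre = _layer_preactivation(
        h, g, weights.bases[layer], weights.coeffs[layer],
        weights.share_direction_params, norms,
    )
    return act(pre)


def topology_encode(
    h0,
    g: BipartiteAssociationGraph,
    weights: RelationBasisWeights,
    n_layers: int | None = None,
    activation: str = "relu",
) -> TopologyEmbedding:
    """Apply L layers and average their outputs into z_topo.

    The input h0 itself is not part of the average; only the L post-layer
    representations h^(1)..h^(L) contribute (all share the hidden width).
    """
    L = weights.n_layers if n_layers is None else n_layers
    if not 1 <= L <= weights.n_layers:
        raise ValueError(f"n_layers must be in [1, {weights.n_layers}]")
    norms = relation_norm_matrices(g)
    per_layer = []
    h = h0
    for l in range(L):
        h = topology_layer(h, g, weights, l, activation=activation, norms=norms)
        per_layer.append(h)
    z = per_layer[0]
    for hl in per_layer[1:]:
        z = z + hl
    z = z * (1.0 / L)
    return TopologyEmbedding(per_layer, z)
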