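"""Two-layer GCNs over the similarity graphs and per-entity fusion.

For each entity type (drug, disease) two weighted similarity graphs exist:
one from predefined domain scores (chemical fingerprints / ontology
semantics) and one from cosine similarity of the initial embeddings. Each
graph is processed by its own two-layer GCN,

    H^(l+1) = sigma( A_hat H^(l) W^(l) + b^(l) ),

with A_hat the symmetrically normalized weighted adjacency with self-loops.
The two resulting views are concatenated and fused through an affine + ReLU
+ dropout layer into the unified similarity embedding z_sim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .graph_construction import SimilarityGraph, normalize_adjacency

__all__ = [
    "GcnLayerParams",
    "SimilarityEncoderParams",
    "gcn_layer",
    "similarity_encode",
    "fuse_similarity",
]

_ACTIVATIONS = {"relu": nn.relu, "tanh": nn.tanh, "identity": nn.identity}


@dataclass
class GcnLayerParams:
    """One graph-convolution layer: weight (d_in x d_out) and bias (d_out,)."""

    W: object
    b: object

    def __post_init__(self) -> None:
        w_shape = self.W.shape
        b_shape = self.b.shape
        if len(w_shape) != 2 or b_shape != (w_shape[1],):
            raise ValueError(f"inconsistent GCN layer shapes W{w_shape}, b{b_shape}")

    @classmethod
    def init(cls, d_in: int, d_out: int, rng: np.random.Generator) -> "GcnLayerParams":
        return cls(nn.parameter((d_in, d_out), rng=rng), nn.parameter(np.zeros(d_out)))

    def parameters(self) -> list:
        return [self.W, self.b]


@dataclass
class SimilarityEncoderParams:
    """Parameters of the two 2-layer GCNs plus the fusion layer for one entity type.

    ``share_graphs=True`` ties the predefined-graph and embedding-graph GCNs
    (the default parameter-sharing mode); untied GCNs implement the
    no-sharing ablation.
    """

    pred_layers: list[GcnLayerParams]
    feat_layers: list[GcnLayerParams]
    w_fuse: object   # (2 * d_out, d_out)
    b_fuse: object
    share_graphs: bool = True

    @classmethod
    def init(
        cls,
        d_in: int,
        hidden1: int,
        hidden2: int,
        rng: np.random.Generator,
        share_graphs: bool = True,
    ) -> "SimilarityEncoderParams":
        pred = [GcnLayerParams.init(d_in, hidden1, rng), GcnLayerParams.init(hidden1, hidden2, rng)]
        feat = pred if share_graphs else [
            GcnLayerParams.init(d_in, hidden1, rng),
            GcnLayerParams.init(hidden1, hidden2, rng),
        ]
        return cls(
            pred, feat,
            nn.parameter((2 * hidden2, hidden2), rng=rng),
            nn.parameter(np.zeros(hidden2)),
            share_graphs=share_graphs,
        )

    def parameters(self) -> list:
        params = []
        for layer in self.pred_layers:
            params.extend(layer.parameters())
        if not self.share_graphs:
            for layer in self.feat_layers:
                params.extend(layer.parameters())
        params.extend([self.w_fuse, self.b_fuse])
        return params


def gcn_layer(h, a_hat: np.ndarray, params: GcnLayerParams, activation: str = "relu"):
    """H' = sigma(A_hat H W + b)."""
    if h.shape[0] != a_hat.shape[0]:
        raise ValueError(
            f"feature rows ({h.shape[0]}) != adjacency size ({a_hat.shape[0]})"
        )
    if h.shape[1] != params.W.shape[0]:
        raise ValueError(
            f"feature width ({h.shape[1]}) != layer input width ({params.W.shape[0]})"
        )
    act = _ACTIVATIONS[activation]
    return act(nn.matmul(a_hat, nn.matmul(h, params.W)) + params.b)


def similarity_encode(
    features,
    g_pred: SimilarityGraph,
    g_feat: SimilarityGraph,
    params: SimilarityEncoderParams,
    activation: str = "relu",
):
    """Run the two independent 2-layer GCN passes; returns (h_pred, h_feat)."""
    n = features.shape[0]
    if g_pred.n != n or g_feat.n != n:
        raise ValueError(
            f"graphs cover {g_pred.n}/{g_feat.n} entities but features have {n} rows"
        )
    out = []
    for g, layers in ((g_pred, params.pred_layers), (g_feat, params.feat_layers)):
        a_hat = normalize_adjacency(g)
        h = features
        for li, layer in enumerate(layers):
            # final layer left linear so the fusion ReLU is the nonlinearity
            last = li == len(layers) - 1
            h = gcn_layer(h, a_hat, layer, activation="identity" if last else activation)
        out.append(h)
    return out[0], out[1]


def fuse_similarity(
    h_pred,
    h_feat,
    w_fuse,
    b_fuse,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    training: bool = False,
):
    """z_sim = Dropout(ReLU(W_fuse [h_pred ; h_feat] + b_fuse))."""
    if h_pred.shape[0] != h_feat.shape[0]:
        raise ValueError("h_pred and h_feat must have equal row counts")
    z = nn.relu(nn.matmul(nn.concat([h_pred, h_feat], axis=1), w_fuse) + b_fuse)
    return nn.dropout(z, dropout_rate, rng, training)
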