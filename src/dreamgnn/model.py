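"""The dual-route model: parameters, forward pass and pair scoring.

One :class:`DualRouteModel` owns all learnable weights — the topology
encoder's bases/coefficients and output projection, the four similarity-GCN
stacks with their per-entity fusion layers, the additive-attention gate and
the MLP decoder — and exposes a forward pass that produces fused node
embeddings plus logits for any set of drug-disease index pairs. Route
ablations (topology-only / similarity-only) bypass the attention gate and
feed the surviving view straight to the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import DreamConfig
from .fusion_decoder import AttentionParams, PairScorerParams, attention_weights, fuse_views, pair_logits
from .graph_construction import BipartiteAssociationGraph, SimilarityGraph
from .similarity_encoder import SimilarityEncoderParams, fuse_similarity, similarity_encode
from .topology_encoder import RelationBasisWeights, topology_encode

__all__ = ["DualRouteModel", "ModelInputs"]


@dataclass
class ModelInputs:
    """Everything one forward pass consumes (built per fold, realized per epoch)."""

    features_drugs: np.ndarray      # (n_d, d_in) harmonized drug features
    features_diseases: np.ndarray   # (n_m, d_in)
    bipartite: BipartiteAssociationGraph | None
    drug_pred: SimilarityGraph | None
    drug_feat: SimilarityGraph | None
    disease_pred: SimilarityGraph | None
    disease_feat: SimilarityGraph | None

    @property
    def n_drugs(self) -> int:
        return self.features_drugs.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.features_diseases.shape[0]


class DualRouteModel:
    """All learnable state plus the forward computation."""

    def __init__(self, d_in: int, config: DreamConfig, rng: np.random.Generator | int):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.config = config
        self.d_in = d_in
        d = config.topo_out
        self.topo_weights = None
        self.topo_proj = None
        self.sim_params = {}
        if config.route != "similarity_only":
            self.topo_weights = RelationBasisWeights.init(
                d_in, config.topo_hidden, config.topo_layers, config.topo_bases,
                rng, share_direction_params=config.share_direction_params,
            )
            self.topo_proj = nn.parameter((config.topo_hidden, d), rng=rng)
        if config.route != "topology_only":
            share = config.sim_share_granularity in ("graphs", "entity_types")
            drug_params = SimilarityEncoderParams.init(
                d_in, config.sim_hidden1, config.sim_hidden2, rng, share_graphs=share
            )
            if config.sim_share_granularity == "entity_types":
                disease_params = drug_params
            else:
                disease_params = SimilarityEncoderParams.init(
                    d_in, config.sim_hidden1, config.sim_hidden2, rng, share_graphs=share
                )
            self.sim_params = {"drug": drug_params, "disease": disease_params}
        self.attention = None
        if config.route == "dual":
            self.attention = AttentionParams.init(
                d, config.attn_hidden, rng, attn_dropout_rate=config.attn_dropout
            )
        self.decoder = PairScorerParams.init(d, tuple(config.dec_hidden), rng)

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[nn.Tensor]:
        params: list[nn.Tensor] = []
        if self.topo_weights is not None:
            params.extend(self.topo_weights.parameters())
            params.append(self.topo_proj)
        seen: set[int] = set()
        for sp in self.sim_params.values():
            for p in sp.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        if self.attention is not None:
            params.extend(self.attention.parameters())
        params.extend(self.decoder.parameters())
        return params

    # -- forward --------------------------------------------------------------
    def node_embeddings(
        self,
        inputs: ModelInputs,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Fused per-node embeddings; returns (z_drugs, z_diseases)."""
        cfg = self.config
        n_d = inputs.n_drugs
        z_topo = z_sim = None
        if self.topo_weights is not None:
            if inputs.bipartite is None:
                raise ValueError("topology route requires the bipartite graph")
            h0 = np.vstack([inputs.features_drugs, inputs.features_diseases])
            emb = topology_encode(
                nn.Tensor(h0), inputs.bipartite, self.topo_weights,
                activation=cfg.topo_activation,
            )
            z_topo = nn.matmul(emb.z_topo, self.topo_proj)
        if self.sim_params:
            parts = []
            for etype, feats, g_pred, g_feat in (
                ("drug", inputs.features_drugs, inputs.drug_pred, inputs.drug_feat),
                ("disease", inputs.features_diseases, inputs.disease_pred, inputs.disease_feat),
            ):
                if g_pred is None or g_feat is None:
                    raise ValueError(f"similarity route requires both {etype} graphs")
                sp = self.sim_params[etype]
                h_pred, h_feat = similarity_encode(nn.Tensor(feats), g_pred, g_feat, sp)
                parts.append(
                    fuse_similarity(
                        h_pred, h_feat, sp.w_fuse, sp.b_fuse,
                        dropout_rate=cfg.dropout, rng=rng, training=training,
                    )
                )
            z_sim = nn.concat(parts, axis=0)
        if cfg.route == "topology_only":
            z = z_topo
        elif cfg.route == "similarity_only":
            z = z_sim
        else:
            w = attention_weights(z_topo, z_sim, self.attention, rng=rng, training=training)
            z = fuse_views(z_topo, z_sim, w, dropout_rate=cfg.dropout, rng=rng, training=training)
        return z[:n_d], z[n_d:]

    def pair_scores(
        self,
        inputs: ModelInputs,
        pairs: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Logits for (drug, disease) index pairs (apply sigmoid for scores)."""
        z_d, z_m = self.node_embeddings(inputs, training=training, rng=rng)
        return pair_logits(z_d, z_m, pairs, self.decoder)

    def predict(self, inputs: ModelInputs, pairs: np.ndarray) -> np.ndarray:
        """Evaluation-mode probability scores (deterministic)."""
        logits = self.pair_scores(inputs, pairs, training=False)
        data = logits.data if isinstance(logits, nn.Tensor) else logits
        return nn.sigmoid(data)
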