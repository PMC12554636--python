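"""Model and training configuration.

Defaults are the grid-search optima reported for the benchmark setting
(selected on LRSSL and applied unchanged to the other datasets). The
``small()`` preset scales every width down for desk-scale synthetic data;
the architecture and all protocol rules are identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Any

import yaml

#: granularities accepted for the parameter-sharing ablation of the
#: similarity encoder (see DreamConfig.sim_share_granularity)
SHARE_GRANULARITIES = ("graphs", "entity_types", "none")

ROUTES = ("dual", "topology_only", "similarity_only")


@dataclass
class DreamConfig:
    # feature harmonization
    drug_dim: int = 768          # PCA components kept for the unified drug matrix
    # topology encoder
    topo_layers: int = 3
    topo_hidden: int = 1024      # aggregation units (shared layer width)
    topo_out: int = 128          # output units after the final projection
    topo_bases: int = 4          # basis-decomposition count B
    topo_activation: str = "relu"
    share_direction_params: bool = True
    # similarity encoder
    sim_hidden1: int = 768
    sim_hidden2: int = 128       # must equal topo_out for view stacking
    knn_k: int = 4
    knn_symmetrize: str = "union"    # "union" | "mutual"
    sparsify_predefined: bool = True
    sim_share_granularity: str = "graphs"  # weights shared across the two graphs
    # regularization / augmentation
    dropout: float = 0.3
    attn_dropout: float = 0.1
    feature_sigma: float = 0.05      # Gaussian feature-perturbation scale
    edge_dropout_p: float = 0.10
    augment: bool = True
    # fusion + decoder
    attn_hidden: int = 64
    dec_hidden: tuple[int, ...] = (256, 64)
    # optimization
    lr: float = 2e-3
    weight_decay: float = 1e-5
    epochs: int = 1000
    patience: int = 50
    val_fraction: float = 0.05
    # protocol
    n_folds: int = 10
    negative_ratio: float = 1.0      # sampled unknown edges per known edge
    unknown_edges_in_graph: bool = True   # whether R_unknown edges carry messages
    route: str = "dual"
    random_node_features: bool = False    # ablation: replace embeddings with noise
    pca_per_fold: bool = True
    coldstart_k: int = 4
    coldstart_temperature: float = 0.1

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.sim_share_granularity not in SHARE_GRANULARITIES:
            raise ValueError(
                f"sim_share_granularity must be one of {SHARE_GRANULARITIES}"
            )
        if self.sim_hidden2 != self.topo_out:
            raise ValueError(
                "sim_hidden2 must equal topo_out: the two views are stacked into a "
                f"2 x d tensor (got {self.sim_hidden2} vs {self.topo_out})"
            )
        if self.knn_symmetrize not in ("union", "mutual"):
            raise ValueError("knn_symmetrize must be 'union' or 'mutual'")

    @classmethod
    def small(cls, **overrides: Any) -> "DreamConfig":
        """Desk-scale preset for synthetic data (tens of entities)."""
        base = dict(
            drug_dim=32,
            topo_hidden=64,
            topo_out=32,
            sim_hidden1=64,
            sim_hidden2=32,
            attn_hidden=16,
            dec_hidden=(64, 16),
            epochs=600,
            patience=60,
        )
        base.update(overrides)
        return cls(**base)

    def with_ablation(self, name: str) -> "DreamConfig":
        """Return a copy configured as one of the named ablation variants."""
        variants = {
            "full": {},
            "wo_attention_dropout": {"attn_dropout": 0.0},
            "wo_parameter_sharing": {
                "share_direction_params": False,
                "sim_share_granularity": "none",
            },
            "wo_augmentation": {"augment": False},
            "wo_node_feature_embedding": {"random_node_features": True},
            "topology_only": {"route": "topology_only"},
            "similarity_only": {"route": "similarity_only"},
        }
        if name not in variants:
            raise ValueError(f"unknown ablation {name!r}; choose from {sorted(variants)}")
        return replace(self, **variants[name])

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "DreamConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {k: (tuple(v) if k == "dec_hidden" else v) for k, v in raw.items()}
        return cls(**raw)
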