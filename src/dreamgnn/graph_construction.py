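"""Typed bipartite interaction graph and weighted kNN similarity graphs.

The topology route runs on a bipartite drug-disease graph with two edge
types: ``known`` (training positives) and ``unknown`` (a seeded sample of
training non-edges used as negative evidence). The similarity route runs on
four weighted graphs — for each entity type one built from a predefined
similarity matrix and one from cosine similarity of the initial embeddings —
each keeping the top-k neighbors per node with the raw similarity value as
edge weight (no binarization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets_io import AssociationTable, EmbeddingMatrix, SimilarityTable

__all__ = [
    "BipartiteAssociationGraph",
    "SimilarityGraph",
    "build_bipartite_graph",
    "knn_similarity_graph",
    "normalize_adjacency",
    "edge_dropout",
    "gaussian_perturb",
]

RELATIONS = ("known", "unknown")


@dataclass
class BipartiteAssociationGraph:
    """Edge sets over drug and disease index spaces, typed by relation."""

    n_drugs: int
    n_diseases: int
    known: np.ndarray    # (K, 2) int array of (drug index, disease index)
    unknown: np.ndarray  # (U, 2)

    def __post_init__(self) -> None:
        self.known = np.asarray(self.known, dtype=np.int64).reshape(-1, 2)
        self.unknown = np.asarray(self.unknown, dtype=np.int64).reshape(-1, 2)
        for name, edges in (("known", self.known), ("unknown", self.unknown)):
            if len(edges):
                if edges[:, 0].min() < 0 or edges[:, 0].max() >= self.n_drugs:
                    raise ValueError(f"{name} edge drug index out of range")
                if edges[:, 1].min() < 0 or edges[:, 1].max() >= self.n_diseases:
                    raise ValueError(f"{name} edge disease index out of range")
        combined = {tuple(e) for e in self.known} | {tuple(e) for e in self.unknown}
        if len(combined) != len(self.known) + len(self.unknown):
            raise ValueError("duplicate (drug, disease) pair across relations")

    def edges(self, relation: str) -> np.ndarray:
        if relation not in RELATIONS:
            raise ValueError(f"relation must be in {RELATIONS}")
        return self.known if relation == "known" else self.unknown

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_diseases

    def adjacency(self, relation: str) -> np.ndarray:
        """Symmetric (n_nodes x n_nodes) 0/1 adjacency; diseases offset by n_drugs."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        e = self.edges(relation)
        if len(e):
            a[e[:, 0], e[:, 1] + self.n_drugs] = 1.0
            a[e[:, 1] + self.n_drugs, e[:, 0]] = 1.0
        return a


@dataclass
class SimilarityGraph:
    """Weighted undirected graph over one entity type; no stored self-edges."""

    entity_type: str          # "drug" | "disease"
    source: str               # "predefined" | "embedding_knn"
    weights: np.ndarray       # dense symmetric, non-negative, zero diagonal
    k: int | None = None

    def __post_init__(self) -> None:
        if self.entity_type not in ("drug", "disease"):
            raise ValueError("entity_type must be 'drug' or 'disease'")
        if self.source not in ("predefined", "embedding_knn"):
            raise ValueError("source must be 'predefined' or 'embedding_knn'")
        w = np.asarray(self.weights, dtype=np.float64)
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("similarity graph weights must be symmetric")
        if w.min() < 0:
            raise ValueError("similarity graph weights must be non-negative")
        np.fill_diagonal(w, 0.0)  # self-loops only enter via normalization
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def isolated_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.weights.sum(axis=1) == 0)


def build_bipartite_graph(
    assoc: AssociationTable,
    fold_train_mask: np.ndarray,
    unknown_sample_size: int,
    rng: np.random.Generator | int,
) -> BipartiteAssociationGraph:
    """Build the training interaction graph for one fold.

    ``fold_train_mask[i, j] = 1`` marks pairs whose label may be seen during
    training. Known edges are the training positives; unknown edges are a
    uniform seeded sample of training non-associations. Held-out pairs can
    never become edges of either relation.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mask = np.asarray(fold_train_mask, dtype=bool)
    if mask.shape != assoc.matrix.shape:
        raise ValueError("fold_train_mask shape must match association matrix")
    pos = np.argwhere((assoc.matrix == 1) & mask)
    unk = np.argwhere((assoc.matrix == 0) & mask)
    if unknown_sample_size > len(unk):
        raise ValueError(
            f"requested {unknown_sample_size} unknown edges but only {len(unk)} "
            "training non-associations exist"
        )
    if unknown_sample_size > 0:
        take = rng.choice(len(unk), size=unknown_sample_size, replace=False)
        sampled = unk[take]
    else:
        sampled = np.empty((0, 2), dtype=np.int64)
    return BipartiteAssociationGraph(assoc.n_drugs, assoc.n_diseases, pos, sampled)


def knn_similarity_graph(
    source: EmbeddingMatrix | SimilarityTable,
    k: int,
    metric: str = "cosine",
    *,
    entity_type: str = "drug",
    symmetrize: str = "union",
    sparsify: bool = True,
) -> SimilarityGraph:
    """Connect each node to its k most similar peers, weighted by similarity.

    Edge weights are the similarity values themselves. Symmetrization is by
    union by default (an edge survives if either endpoint selected it);
    ``mutual`` keeps only reciprocal selections. For ``precomputed`` sources
    ``sparsify=False`` passes the dense matrix through unchanged.
    """
    if metric not in ("cosine", "precomputed"):
        raise ValueError("metric must be 'cosine' or 'precomputed'")
    if symmetrize not in ("union", "mutual"):
        raise ValueError("symmetrize must be 'union' or 'mutual'")
    if metric == "cosine":
        if not isinstance(source, EmbeddingMatrix):
            raise TypeError("cosine metric requires an EmbeddingMatrix")
        norms = np.linalg.norm(source.matrix, axis=1)
        zero = np.flatnonzero(norms == 0)
        if len(zero):
            raise ValueError(
                f"zero-norm embedding row for entity {source.entity_ids[zero[0]]!r}"
            )
        unit = source.matrix / norms[:, None]
        sim = unit @ unit.T
        # cosine can dip below 0; graph weights must be non-negative
        sim = np.clip(sim, 0.0, None)
        graph_source = "embedding_knn"
    else:
        if not isinstance(source, SimilarityTable):
            raise TypeError("precomputed metric requires a SimilarityTable")
        sim = source.matrix.copy()
        graph_source = "predefined"
    n = sim.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")
    np.fill_diagonal(sim, -np.inf)
    if metric == "precomputed" and not sparsify:
        w = np.where(np.isfinite(sim), sim, 0.0)
        return SimilarityGraph(entity_type, graph_source, w, k=None)
    # selection matrix: row i selects its k largest similarities
    top = np.argpartition(-sim, kth=k - 1, axis=1)[:, :k]
    select = np.zeros((n, n), dtype=bool)
    select[np.arange(n)[:, None], top] = True
    keep = select | select.T if symmetrize == "union" else select & select.T
    w = np.where(keep, np.where(np.isfinite(sim), sim, 0.0), 0.0)
    w = np.maximum(w, w.T)  # symmetric weight = the (shared) similarity value
    return SimilarityGraph(entity_type, graph_source, w, k=k)


def normalize_adjacency(g: SimilarityGraph | np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}.

    D is the degree (row-sum) matrix of A + I, so every node has positive
    degree and the result is finite with spectral radius <= 1.
    """
    a = g.weights if isinstance(g, SimilarityGraph) else np.asarray(g, dtype=np.float64)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0:
        raise ValueError("adjacency must be non-negative")
    a_loop = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_loop.sum(axis=1))
    return a_loop * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def edge_dropout(
    g: BipartiteAssociationGraph | SimilarityGraph,
    p: float,
    rng: np.random.Generator | int,
):
    """Remove each edge independently with probability ``p`` (training only)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge dropout probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(g, BipartiteAssociationGraph):
        keep_known = rng.random(len(g.known)) >= p
        keep_unknown = rng.random(len(g.unknown)) >= p
        return BipartiteAssociationGraph(
            g.n_drugs, g.n_diseases, g.known[keep_known], g.unknown[keep_unknown]
        )
    if isinstance(g, SimilarityGraph):
        n = g.n
        iu = np.triu_indices(n, k=1)
        keep = rng.random(len(iu[0])) >= p
        w = np.zeros_like(g.weights)
        kept_i, kept_j = iu[0][keep], iu[1][keep]
        w[kept_i, kept_j] = g.weights[kept_i, kept_j]
        w = w + w.T
        return SimilarityGraph(g.entity_type, g.source, w, k=g.k)
    raise TypeError(f"unsupported graph type {type(g).__name__}")


def gaussian_perturb(
    features: EmbeddingMatrix | np.ndarray,
    sigma: float,
    rng: np.random.Generator | int,
):
    """Add i.i.d. N(0, sigma^2) noise to every feature entry (training only)."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(features, EmbeddingMatrix):
        if sigma == 0:
            return features
        noisy = features.matrix + rng.normal(0.0, sigma, size=features.matrix.shape)
        return EmbeddingMatrix(list(features.entity_ids), noisy, modality=features.modality)
    x = np.asarray(features, dtype=np.float64)
    if sigma == 0:
        return x.copy()
    return x + rng.normal(0.0, sigma, size=x.shape)
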