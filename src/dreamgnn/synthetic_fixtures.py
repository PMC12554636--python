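"""Self-contained synthetic datasets with planted block structure.

The generator emulates the three input kinds a real study supplies —
pretrained embeddings, predefined similarity matrices and a sparse binary
association matrix — from a single latent mechanism. Entities belong to
latent communities; each entity's latent factor is its community centroid
plus isotropic noise; embeddings expose that factor, "predefined"
similarities are noisy cosines of an independently re-noised copy of it
(so the two similarity sources are correlated but not identical), and
association probabilities increase with latent-factor cosine affinity,
calibrated to a target matrix density. With ``signal_strength = 0``
associations are independent of everything else (a null dataset); with
``noise_sigma = 0`` embeddings collapse onto their centroids and community
membership is perfectly recoverable.

A fraction of drugs is tagged as protein therapeutics with a wider raw
dimension, exercising the zero-padding path of the harmonizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .datasets_io import AssociationTable, EmbeddingMatrix, SimilarityTable
from .graph_construction import BipartiteAssociationGraph
from .training_evaluation import DatasetBundle

__all__ = ["SyntheticSpec", "generate", "toy_worked_example", "ToyExample"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the desk-scale conditions used throughout the test suite:
    60 drugs x 40 diseases in 3 communities, 32-dim raw embeddings, 5%
    association density.
    """

    n_drugs: int = 60
    n_diseases: int = 40
    n_blocks: int = 3
    embed_dim: int = 32
    assoc_density: float = 0.05
    noise_sigma: float = 0.15
    signal_strength: float = 25.0
    popularity_scale: float = 0.1
    protein_fraction: float = 0.2
    protein_extra_dims: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks > min(self.n_drugs, self.n_diseases):
            raise ValueError("n_blocks cannot exceed the smaller entity count")
        if not 0.0 < self.assoc_density < 1.0:
            raise ValueError("assoc_density must lie in (0, 1)")
        if self.noise_sigma < 0 or self.signal_strength < 0:
            raise ValueError("noise_sigma and signal_strength must be non-negative")
        if not 0.0 <= self.protein_fraction <= 1.0:
            raise ValueError("protein_fraction must lie in [0, 1]")


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def _calibrate_intercept(affinity: np.ndarray, strength: float, density: float) -> float:
    """Intercept a such that mean sigmoid(a + strength * affinity) == density."""

    def gap(a: float) -> float:
        return float(expit(a + strength * affinity).mean() - density)

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target density {density} infeasible for signal_strength {strength}"
        )
    return brentq(gap, lo, hi, xtol=1e-12)


def generate(spec: SyntheticSpec) -> DatasetBundle:
    """Draw one dataset; byte-identical regeneration for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    dim = spec.embed_dim
    # near-orthogonal unit centroids via QR of a random Gaussian matrix
    raw = rng.normal(size=(dim, spec.n_blocks))
    q, _ = np.linalg.qr(raw)
    centroids = q.T  # (n_blocks, dim), orthonormal rows

    def sample_entities(n: int) -> tuple[np.ndarray, np.ndarray]:
        blocks = rng.permutation(np.arange(n) % spec.n_blocks)
        latent = centroids[blocks] + rng.normal(0.0, spec.noise_sigma, size=(n, dim))
        return blocks, latent

    drug_blocks, drug_latent = sample_entities(spec.n_drugs)
    disease_blocks, disease_latent = sample_entities(spec.n_diseases)

    # associations: probability increases with latent cosine affinity plus a
    # per-entity popularity offset (degree heterogeneity, a hallmark of the
    # real benchmarks that only the interaction topology can reveal — the
    # popularity of an entity is not encoded in its embedding). Both terms
    # scale with signal_strength so a zero-signal dataset is exactly null.
    drug_pop = rng.normal(0.0, 1.0, size=(spec.n_drugs, 1))
    disease_pop = rng.normal(0.0, 1.0, size=(1, spec.n_diseases))
    affinity = (
        _unit_rows(drug_latent) @ _unit_rows(disease_latent).T
        + spec.popularity_scale * (drug_pop + disease_pop)
    )
    intercept = _calibrate_intercept(affinity, spec.signal_strength, spec.assoc_density)
    probs = expit(intercept + spec.signal_strength * affinity)
    matrix = (rng.random(probs.shape) < probs).astype(np.int8)
    if matrix.sum() == 0:  # guarantee the table validates
        i, j = np.unravel_index(np.argmax(probs), probs.shape)
        matrix[i, j] = 1

    drug_ids = [f"drug_{i:03d}" for i in range(spec.n_drugs)]
    disease_ids = [f"disease_{j:03d}" for j in range(spec.n_diseases)]
    assoc = AssociationTable(drug_ids, disease_ids, matrix)

    # embeddings expose the latent factor; protein drugs get extra raw dims
    n_protein = int(round(spec.protein_fraction * spec.n_drugs))
    protein_idx = rng.choice(spec.n_drugs, size=n_protein, replace=False)
    is_protein = np.zeros(spec.n_drugs, dtype=bool)
    is_protein[protein_idx] = True
    sm_rows = np.flatnonzero(~is_protein)
    pr_rows = np.flatnonzero(is_protein)
    small_mol = (
        EmbeddingMatrix([drug_ids[i] for i in sm_rows], drug_latent[sm_rows],
                        modality="synthetic")
        if len(sm_rows)
        else None
    )
    protein = None
    if len(pr_rows):
        extra = rng.normal(0.0, 0.5, size=(len(pr_rows), spec.protein_extra_dims))
        protein = EmbeddingMatrix(
            [drug_ids[i] for i in pr_rows],
            np.hstack([drug_latent[pr_rows], extra]),
            modality="synthetic",
        )
    diseases = EmbeddingMatrix(disease_ids, disease_latent, modality="synthetic")

    # predefined similarities: noisy cosine of a re-noised latent copy
    def predefined(blocks: np.ndarray, ids: list[str]) -> SimilarityTable:
        held_aside = centroids[blocks] + rng.normal(
            0.0, max(spec.noise_sigma, 0.05), size=(len(blocks), dim)
        )
        sim = np.clip(_unit_rows(held_aside) @ _unit_rows(held_aside).T, 0.0, 1.0)
        np.fill_diagonal(sim, 1.0)
        return SimilarityTable(ids, (sim + sim.T) / 2)

    return DatasetBundle(
        assoc,
        small_mol,
        protein,
        diseases,
        predefined(drug_blocks, drug_ids),
        predefined(disease_blocks, disease_ids),
    )


# ---------------------------------------------------------------------------
# fixed worked example (documentation walkthrough + oracle anchor)
# ---------------------------------------------------------------------------


@dataclass
class ToyExample:
    """A hand-checkable 4-drug x 3-disease instance.

    ``expected_layer_identity`` is the one-layer output of the relational
    message-passing rule with both relation weight matrices equal to the
    2x2 identity and the identity activation — each row is the degree-
    normalized sum of neighbor features under both relations, verifiable by
    hand from the edge lists. ``expected_normalized_drug_adjacency`` is
    D^{-1/2}(A + I)D^{-1/2} of the drug similarity weights.
    """

    assoc: AssociationTable
    graph: BipartiteAssociationGraph
    node_features: np.ndarray                 # 7 x 2, drugs then diseases
    drug_sim_weights: np.ndarray              # 4 x 4 symmetric, zero diagonal
    expected_layer_identity: np.ndarray       # 7 x 2
    expected_normalized_drug_adjacency: np.ndarray  # 4 x 4


def toy_worked_example() -> ToyExample:
    matrix = np.array(
        [
            [1, 0, 0],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
        ]
    )
    assoc = AssociationTable(
        ["d0", "d1", "d2", "d3"], ["m0", "m1", "m2"], matrix
    )
    known = np.argwhere(matrix == 1)
    unknown = np.array([[0, 2]])  # one sampled negative-evidence edge
    graph = BipartiteAssociationGraph(4, 3, known, unknown)
    features = np.array(
        [
            [1.0, 0.0],   # d0
            [0.0, 1.0],   # d1
            [1.0, 1.0],   # d2
            [2.0, 0.0],   # d3
            [1.0, 2.0],   # m0
            [0.0, 3.0],   # m1
            [1.0, 1.0],   # m2
        ]
    )
    # hand computation, identity weights / identity activation.
    # known degrees: d0=1, d1=2, d2=1, d3=1, m0=2, m1=2, m2=1
    # unknown degrees: d0=1, m2=1
    r2 = np.sqrt(2.0)
    expected = np.array(
        [
            [1.0 / r2 + 1.0, 2.0 / r2 + 1.0],          # d0: m0/sqrt(2) + m2 (unknown)
            [1.0 / 2.0 + 0.0, 2.0 / 2.0 + 3.0 / 2.0],  # d1: m0/2 + m1/2
            [0.0 / r2, 3.0 / r2],                      # d2: m1/sqrt(2)
            [1.0, 1.0],                                # d3: m2/1
            [1.0 / r2 + 0.0 / 2.0, 0.0 / r2 + 1.0 / 2.0],  # m0: d0/sqrt(2) + d1/2
            [0.0 / 2.0 + 1.0 / r2, 1.0 / 2.0 + 1.0 / r2],  # m1: d1/2 + d2/sqrt(2)
            [2.0 + 1.0, 0.0 + 0.0],                    # m2: d3/1 + d0 (unknown)
        ]
    )
    drug_sim = np.array(
        [
            [0.0, 0.8, 0.0, 0.0],
            [0.8, 0.0, 0.5, 0.0],
            [0.0, 0.5, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    a_loop = drug_sim + np.eye(4)
    d_inv = 1.0 / np.sqrt(a_loop.sum(axis=1))
    expected_norm = a_loop * d_inv[:, None] * d_inv[None, :]
    return ToyExample(assoc, graph, features, drug_sim, expected, expected_norm)
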