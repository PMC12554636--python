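"""Harmonizing heterogeneous initial embeddings into one feature space.

Small-molecule drugs arrive as 1024-dim vectors (SMILES language model),
protein therapeutics as 1280-dim vectors (protein language model), diseases
as 768-dim text vectors. Drug vectors are zero-padded to the widest drug
dimension, stacked into one drug-major matrix and compressed by PCA to the
shared width (768 by default) used by both graph encoders. The pooling
contract for upstream token states (masked mean over substantive tokens) is
also defined here so synthetic stand-ins obey the same convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .datasets_io import EmbeddingMatrix

__all__ = [
    "TokenStates",
    "PcaModel",
    "HarmonizedFeatures",
    "masked_mean_pool",
    "zero_pad",
    "stack_drug_features",
    "fit_pca_reduce",
    "apply_pca",
    "harmonize",
]

logger = logging.getLogger(__name__)


@dataclass
class TokenStates:
    """Per-token hidden states with a padding mask (1 = substantive token)."""

    states: np.ndarray  # T x D
    mask: np.ndarray    # length T, binary

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=np.float64))
        self.mask = np.asarray(self.mask).astype(np.int8).ravel()
        if self.mask.shape[0] != self.states.shape[0]:
            raise ValueError("mask length must equal number of token rows")
        if not np.isfinite(self.states).all():
            raise ValueError("token states contain non-finite values")


@dataclass
class PcaModel:
    """Frozen PCA transform: stored so held-out entities project identically."""

    mean: np.ndarray
    components: np.ndarray          # n_components x D, rows orthonormal
    explained_variance: np.ndarray  # non-increasing

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-6):
            raise ValueError("PCA components are not orthonormal")


@dataclass
class HarmonizedFeatures:
    drugs: EmbeddingMatrix
    diseases: EmbeddingMatrix
    pca_model: PcaModel

    def __post_init__(self) -> None:
        if self.drugs.dim != self.diseases.dim:
            raise ValueError(
                "harmonized drug and disease features must share one width "
                f"(got {self.drugs.dim} vs {self.diseases.dim})"
            )


def masked_mean_pool(tokens: TokenStates) -> np.ndarray:
    """Mean of token-state rows where the mask is 1; padding contributes nothing."""
    keep = tokens.mask == 1
    if not keep.any():
        raise ValueError("masked_mean_pool requires at least one unmasked token")
    return tokens.states[keep].mean(axis=0)


def zero_pad(emb: EmbeddingMatrix, target_dim: int) -> EmbeddingMatrix:
    """Append zero columns up to ``target_dim``; existing coordinates untouched."""
    if target_dim < emb.dim:
        raise ValueError(f"target_dim {target_dim} < embedding dim {emb.dim}")
    if target_dim == emb.dim:
        return emb
    padded = np.hstack([emb.matrix, np.zeros((emb.n, target_dim - emb.dim))])
    return EmbeddingMatrix(list(emb.entity_ids), padded, modality=emb.modality)


def stack_drug_features(
    small_mol: EmbeddingMatrix | None,
    protein: EmbeddingMatrix | None,
    drug_order: list[str],
) -> EmbeddingMatrix:
    """Assemble one drug-major matrix, zero-padding the narrower modality.

    Every drug in ``drug_order`` must come from exactly one source; small
    molecules and proteins end up in the same width (the max of the two).
    """
    sources = [e for e in (small_mol, protein) if e is not None and e.n > 0]
    if not sources:
        raise ValueError("at least one non-empty drug embedding source is required")
    seen: dict[str, tuple[int, int]] = {}
    for si, src in enumerate(sources):
        for ri, eid in enumerate(src.entity_ids):
            if eid in seen:
                raise ValueError(f"drug {eid!r} appears in more than one embedding source")
            seen[eid] = (si, ri)
    missing = [d for d in drug_order if d not in seen]
    if missing:
        raise ValueError(f"drugs missing from every embedding source: {missing[:5]}")
    target = max(src.dim for src in sources)
    padded = [zero_pad(src, target) for src in sources]
    rows = np.empty((len(drug_order), target))
    for out_i, eid in enumerate(drug_order):
        si, ri = seen[eid]
        rows[out_i] = padded[si].matrix[ri]
    return EmbeddingMatrix(list(drug_order), rows, modality="synthetic"
                           if any(s.modality == "synthetic" for s in sources)
                           else sources[0].modality)


def fit_pca_reduce(
    features: EmbeddingMatrix, n_components: int = 768
) -> tuple[EmbeddingMatrix, PcaModel]:
    """Center, fit PCA and project onto the top ``n_components`` axes.

    ``n_components`` larger than ``min(N, D)`` is clamped with a warning so
    small fixtures remain runnable; component signs are fixed by making each
    component's largest-magnitude loading positive, which removes the sign
    ambiguity of the underlying SVD.
    """
    if n_components < 1:
        raise ValueError("n_components must be positive")
    if features.n < 2:
        raise ValueError("PCA requires at least 2 rows")
    limit = min(features.n - 1, features.dim)
    if n_components > limit:
        logger.warning(
            "clamping n_components from %d to %d (matrix is %d x %d)",
            n_components, limit, features.n, features.dim,
        )
        n_components = limit
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(features.matrix)
    components = pca.components_.copy()
    # deterministic sign: largest-|loading| coordinate of each axis made positive
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1
    model = PcaModel(pca.mean_.copy(), components, pca.explained_variance_.copy())
    reduced = EmbeddingMatrix(
        list(features.entity_ids), apply_pca(model, features.matrix), modality=features.modality
    )
    return reduced, model


def apply_pca(model: PcaModel, x: np.ndarray) -> np.ndarray:
    """Project new rows with a frozen PCA model (same centering as the fit)."""
    return (np.atleast_2d(x) - model.mean) @ model.components.T


def harmonize(
    small_mol: EmbeddingMatrix | None,
    protein: EmbeddingMatrix | None,
    diseases: EmbeddingMatrix,
    drug_order: list[str],
    n_components: int = 768,
) -> HarmonizedFeatures:
    """Full drug-side pipeline: stack, pad, PCA-reduce; diseases pass through.

    When the PCA width is clamped below the disease width (tiny fixtures),
    the disease matrix is truncated to match, keeping the two entity types
    stackable downstream.
    """
    stacked = stack_drug_features(small_mol, protein, drug_order)
    reduced, model = fit_pca_reduce(stacked, n_components)
    dis = diseases
    if dis.dim != reduced.dim:
        if dis.dim < reduced.dim:
            dis = zero_pad(dis, reduced.dim)
        else:
            dis = EmbeddingMatrix(
                list(dis.entity_ids), dis.matrix[:, : reduced.dim], modality=dis.modality
            )
    return HarmonizedFeatures(reduced, dis, model)
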