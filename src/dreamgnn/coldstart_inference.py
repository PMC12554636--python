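"""Strict cold-start scoring for entities absent from the training graph.

An unseen drug or disease never touches training: its raw pretrained
embedding is compared (cosine, in the original embedding space) against the
raw embeddings of training entities, the top-k matches are retrieved, and a
pseudo-query is formed as a temperature-scaled-attention combination of the
neighbors' *trained* fused representations. The frozen decoder then scores
the pseudo-query against every candidate partner; no parameter is updated
and no graph is rebuilt at inference time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as sp_softmax

from .config import DreamConfig
from .datasets_io import AssociationTable, EmbeddingMatrix, SimilarityTable
from .fusion_decoder import PairScorerParams, pair_logits
from .graph_construction import BipartiteAssociationGraph
from .model import DualRouteModel
from .training_evaluation import (
    DatasetBundle,
    FoldInputs,
    MetricsReport,
    _model_inputs,
    auprc,
    auroc,
    rebuild_fold_inputs,
    train_model,
    FoldPlan,
)
from . import nn

__all__ = [
    "ColdStartQuery",
    "find_neighbors",
    "pseudo_query",
    "score_unseen",
    "coldstart_cv",
]


@dataclass
class ColdStartQuery:
    entity_type: str
    raw_embedding: np.ndarray
    neighbor_ids: np.ndarray       # indices into the training entity set
    neighbor_sims: np.ndarray      # non-increasing cosine similarities
    temperature: float
    pseudo_embedding: np.ndarray

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.neighbor_ids) < 1:
            raise ValueError("at least one neighbor is required")
        if np.any(np.diff(self.neighbor_sims) > 1e-12):
            raise ValueError("neighbor_sims must be sorted non-increasing")


def find_neighbors(
    query: np.ndarray, training_raw: EmbeddingMatrix | np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact top-k training entities by cosine similarity to ``query``.

    Ties broken deterministically toward the lower index.
    """
    matrix = training_raw.matrix if isinstance(training_raw, EmbeddingMatrix) else np.asarray(training_raw)
    query = np.asarray(query, dtype=np.float64).ravel()
    if not 1 <= k <= matrix.shape[0]:
        raise ValueError(f"k must be in [1, {matrix.shape[0]}], got {k}")
    qn = np.linalg.norm(query)
    if qn == 0:
        raise ValueError("cold-start query has zero norm")
    norms = np.linalg.norm(matrix, axis=1)
    if (norms == 0).any():
        raise ValueError("training embedding rows must have nonzero norm")
    sims = matrix @ query / (norms * qn)
    order = np.argsort(-sims, kind="stable")[:k]
    return order, sims[order]


def pseudo_query(
    neighbor_trained: np.ndarray, neighbor_sims: np.ndarray, temperature: float
) -> np.ndarray:
    """Attention-weighted combination of neighbors' trained embeddings.

    weights = Softmax(similarities / temperature); small temperatures sharpen
    toward the nearest neighbor, large ones approach the plain mean. The
    output always lies in the convex hull of the neighbor embeddings.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    neighbor_trained = np.atleast_2d(np.asarray(neighbor_trained, dtype=np.float64))
    sims = np.asarray(neighbor_sims, dtype=np.float64).ravel()
    if len(sims) != neighbor_trained.shape[0]:
        raise ValueError("one similarity per neighbor required")
    if len(sims) == 0:
        raise ValueError("at least one neighbor is required")
    weights = sp_softmax(sims / temperature)
    return weights @ neighbor_trained


def score_unseen(
    pseudo: np.ndarray,
    candidates: np.ndarray,
    decoder: PairScorerParams,
    entity_type: str = "drug",
) -> np.ndarray:
    """Score a pseudo-query against trained candidate embeddings.

    ``entity_type`` names the *unseen* side: an unseen drug is scored against
    disease candidates as ([pseudo ; candidate]), an unseen disease as
    ([candidate ; pseudo]) — the decoder's concatenation is ordered. The
    decoder is verified untouched (parameter hash before == after).
    """
    if entity_type not in ("drug", "disease"):
        raise ValueError("entity_type must be 'drug' or 'disease'")
    pseudo = np.asarray(pseudo, dtype=np.float64).ravel()
    candidates = np.atleast_2d(np.asarray(candidates, dtype=np.float64))
    before = decoder.state_hash()
    n = candidates.shape[0]
    pairs = np.column_stack([np.zeros(n, dtype=np.int64), np.arange(n)])
    if entity_type == "drug":
        logits = pair_logits(pseudo[None, :], candidates, pairs, decoder)
    else:
        pairs = pairs[:, ::-1]
        logits = pair_logits(candidates, pseudo[None, :], pairs, decoder)
    after = decoder.state_hash()
    assert before == after, "decoder parameters changed during cold-start scoring"
    data = logits.data if isinstance(logits, nn.Tensor) else logits
    return nn.sigmoid(data)


def _subset_dataset(dataset: DatasetBundle, keep: np.ndarray, mode: str) -> DatasetBundle:
    """Restrict a dataset to the training entities of one cold-start fold."""
    assoc = dataset.assoc
    if mode == "unseen_drug":
        ids = [assoc.drug_ids[i] for i in keep]
        new_assoc = AssociationTable(ids, list(assoc.disease_ids), assoc.matrix[keep])
        keep_ids = set(ids)
        sm = _subset_embedding(dataset.drug_small_mol, keep_ids)
        pr = _subset_embedding(dataset.drug_protein, keep_ids)
        dsim = _subset_similarity(dataset.drug_sim, ids)
        return DatasetBundle(new_assoc, sm, pr, dataset.disease_emb, dsim, dataset.disease_sim)
    ids = [assoc.disease_ids[j] for j in keep]
    new_assoc = AssociationTable(list(assoc.drug_ids), ids, assoc.matrix[:, keep])
    dis = EmbeddingMatrix(
        ids,
        dataset.disease_emb.matrix[[dataset.disease_emb.entity_ids.index(i) for i in ids]],
        modality=dataset.disease_emb.modality,
    )
    msim = _subset_similarity(dataset.disease_sim, ids)
    return DatasetBundle(new_assoc, dataset.drug_small_mol, dataset.drug_protein, dis,
                         dataset.drug_sim, msim)


def _subset_embedding(emb: EmbeddingMatrix | None, keep_ids: set) -> EmbeddingMatrix | None:
    if emb is None:
        return None
    rows = [i for i, eid in enumerate(emb.entity_ids) if eid in keep_ids]
    if not rows:
        return None
    return EmbeddingMatrix([emb.entity_ids[i] for i in rows], emb.matrix[rows], modality=emb.modality)


def _subset_similarity(sim: SimilarityTable | None, ids: list) -> SimilarityTable | None:
    if sim is None:
        return None
    idx = [sim.entity_ids.index(i) for i in ids]
    return SimilarityTable(list(ids), sim.matrix[np.ix_(idx, idx)])


def coldstart_cv(
    dataset: DatasetBundle,
    config: DreamConfig,
    mode: str = "unseen_drug",
    seed: int = 0,
    n_folds: int | None = None,
    return_scores: bool = False,
) -> MetricsReport:
    """Entity-wise cross-validation under the strict cold-start protocol.

    Entities (not pairs) are partitioned into folds; each fold's entities are
    removed from every training structure — association graph, similarity
    graphs, PCA fit. Inference uses the trained model as-is. Metrics pool all
    pairs between held-out entities and training entities of the other type;
    pairs between two held-out entities are excluded (neither endpoint has a
    trained representation).
    """
    if mode not in ("unseen_drug", "unseen_disease"):
        raise ValueError("mode must be 'unseen_drug' or 'unseen_disease'")
    n_folds = n_folds if n_folds is not None else config.n_folds
    assoc = dataset.assoc
    n_entities = assoc.n_drugs if mode == "unseen_drug" else assoc.n_diseases
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n_entities), n_folds)

    from .feature_space import stack_drug_features

    full_raw_drugs = stack_drug_features(
        dataset.drug_small_mol, dataset.drug_protein, assoc.drug_ids
    ).matrix
    full_raw_diseases = dataset.disease_emb.matrix

    aurocs, auprcs = [], []
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = []
    for fold_entities in folds:
        held = np.sort(fold_entities)
        keep = np.setdiff1d(np.arange(n_entities), held)
        sub = _subset_dataset(dataset, keep, mode)
        # train on the reduced dataset with every reduced pair visible
        plan = FoldPlan(
            1,
            [np.empty((0, 2), dtype=np.int64)],
            [np.empty((0, 2), dtype=np.int64)],
            seed,
        )
        fold_inputs = rebuild_fold_inputs(0, plan, sub, config, seed=seed)
        model, history = train_model(fold_inputs, config, seed=seed)
        eval_graph: BipartiteAssociationGraph = history["eval_graph"]
        # leakage audit: held-out entity indices cannot occur in the reduced
        # graph (its index space has size n_train < min(held indices' source))
        axis = 0 if mode == "unseen_drug" else 1
        limit = eval_graph.n_drugs if mode == "unseen_drug" else eval_graph.n_diseases
        assert limit == len(keep), "held-out entities leaked into the training graph"
        inputs = _model_inputs(fold_inputs, eval_graph)
        z_d, z_m = model.node_embeddings(inputs, training=False)
        z_d = z_d.data if isinstance(z_d, nn.Tensor) else z_d
        z_m = z_m.data if isinstance(z_m, nn.Tensor) else z_m
        if mode == "unseen_drug":
            train_raw = full_raw_drugs[keep]
            trained_z, cand_z = z_d, z_m
        else:
            train_raw = full_raw_diseases[keep]
            trained_z, cand_z = z_m, z_d
        k = min(config.coldstart_k, len(keep))
        scores_all, labels_all = [], []
        for h in held:
            query = full_raw_drugs[h] if mode == "unseen_drug" else full_raw_diseases[h]
            nbr_idx, nbr_sims = find_neighbors(query, train_raw, k)
            pq = pseudo_query(trained_z[nbr_idx], nbr_sims, config.coldstart_temperature)
            scores = score_unseen(
                pq, cand_z, model.decoder,
                entity_type="drug" if mode == "unseen_drug" else "disease",
            )
            labels = assoc.matrix[h, :] if mode == "unseen_drug" else assoc.matrix[:, h]
            scores_all.append(scores)
            labels_all.append(np.asarray(labels, dtype=np.int64))
        scores_all = np.concatenate(scores_all)
        labels_all = np.concatenate(labels_all)
        if len(np.unique(labels_all)) < 2:
            warnings.warn("cold-start fold has a single label class; skipping metrics")
            continue
        aurocs.append(auroc(scores_all, labels_all))
        auprcs.append(auprc(scores_all, labels_all))
        if return_scores:
            fold_scores.append((scores_all, labels_all))
    extras = {"mode": mode, "seed": seed}
    if return_scores:
        extras["fold_scores"] = fold_scores
    return MetricsReport(aurocs, auprcs, extras=extras)
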