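"""End-to-end training and the leakage-free cross-validation protocol.

Known associations (positives) and unknown pairs (negatives) are partitioned
independently into 10 mutually exclusive folds. For every fold the training
graph is rebuilt from training edges only and all similarity structures and
the PCA harmonization are recomputed without any test-pair information.
Evaluation scores every held-out pair — all held-out unknowns, no negative
subsampling — with AUROC and AUPRC; per-fold metric vectors feed a paired
t-test against competing score sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from . import nn
from .config import DreamConfig
from .datasets_io import AssociationTable, EmbeddingMatrix, SimilarityTable
from .feature_space import harmonize
from .graph_construction import (
    BipartiteAssociationGraph,
    build_bipartite_graph,
    edge_dropout,
    gaussian_perturb,
    knn_similarity_graph,
)
from .model import DualRouteModel, ModelInputs

__all__ = [
    "DatasetBundle",
    "FoldPlan",
    "FoldInputs",
    "MetricsReport",
    "make_folds",
    "rebuild_fold_inputs",
    "train_model",
    "auroc",
    "auprc",
    "f1_recall_at_threshold",
    "paired_t_test",
    "run_cv",
    "audit_no_leakage",
]


@dataclass
class DatasetBundle:
    """One dataset: associations, raw embeddings, optional predefined similarities."""

    assoc: AssociationTable
    drug_small_mol: EmbeddingMatrix | None
    drug_protein: EmbeddingMatrix | None
    disease_emb: EmbeddingMatrix
    drug_sim: SimilarityTable | None = None
    disease_sim: SimilarityTable | None = None


@dataclass
class FoldPlan:
    """Pair-wise CV bookkeeping: per-fold held-out positives and unknowns."""

    n_folds: int
    test_pos: list          # fold -> (k, 2) array of held-out positive pairs
    test_unk: list          # fold -> (u, 2) array of held-out unknown pairs
    seed: int

    def __post_init__(self) -> None:
        if len(self.test_pos) != self.n_folds or len(self.test_unk) != self.n_folds:
            raise ValueError("one test set per fold required")

    def train_mask(self, fold: int, shape: tuple[int, int]) -> np.ndarray:
        """Binary matrix: 1 where the pair's label is visible during training."""
        mask = np.ones(shape, dtype=bool)
        for pairs in (self.test_pos[fold], self.test_unk[fold]):
            mask[pairs[:, 0], pairs[:, 1]] = False
        return mask

    def test_pairs(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Held-out (pairs, labels) for one fold: positives then all unknowns."""
        pairs = np.vstack([self.test_pos[fold], self.test_unk[fold]])
        labels = np.concatenate(
            [np.ones(len(self.test_pos[fold])), np.zeros(len(self.test_unk[fold]))]
        )
        return pairs, labels


def make_folds(assoc: AssociationTable, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Split positives and unknowns independently into near-equal folds.

    Fold sizes differ by at most one in each class; the full unknown set is
    retained (no subsampling), so the union of test folds covers every pair
    of the matrix exactly once.
    """
    pos = np.argwhere(assoc.matrix == 1)
    unk = np.argwhere(assoc.matrix == 0)
    if len(pos) < n_folds:
        raise ValueError(f"{len(pos)} positives cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    pos = pos[rng.permutation(len(pos))]
    unk = unk[rng.permutation(len(unk))]
    return FoldPlan(
        n_folds,
        [np.array(part) for part in np.array_split(pos, n_folds)],
        [np.array(part) for part in np.array_split(unk, n_folds)],
        seed,
    )


@dataclass
class FoldInputs:
    """Everything training needs for one fold, built leakage-free."""

    features_drugs: np.ndarray        # harmonized, (n_d, d)
    features_diseases: np.ndarray     # harmonized, (n_m, d)
    raw_drugs: np.ndarray             # stacked pre-PCA drug matrix (kNN / cold-start space)
    raw_diseases: np.ndarray
    train_pos: np.ndarray             # (k, 2) training positive pairs
    train_unknowns: np.ndarray        # all training unknown pairs (sampling pool)
    train_mask: np.ndarray
    graphs: dict                      # drug_pred / drug_feat / disease_pred / disease_feat
    pca_model: object
    assoc: AssociationTable


def _build_similarity_graphs(
    raw_drugs: EmbeddingMatrix,
    raw_diseases: EmbeddingMatrix,
    drug_sim: SimilarityTable | None,
    disease_sim: SimilarityTable | None,
    config: DreamConfig,
) -> dict:
    graphs = {}
    for etype, emb, pre in (
        ("drug", raw_drugs, drug_sim),
        ("disease", raw_diseases, disease_sim),
    ):
        feat = knn_similarity_graph(
            emb, config.knn_k, metric="cosine",
            entity_type=etype, symmetrize=config.knn_symmetrize,
        )
        if pre is not None:
            pred = knn_similarity_graph(
                pre, config.knn_k, metric="precomputed",
                entity_type=etype, symmetrize=config.knn_symmetrize,
                sparsify=config.sparsify_predefined,
            )
        else:
            # no predefined matrix supplied: similarity route runs on the
            # embedding-derived graph alone
            pred = feat
        graphs[f"{etype}_pred"] = pred
        graphs[f"{etype}_feat"] = feat
    return graphs


def rebuild_fold_inputs(
    fold: int,
    plan: FoldPlan,
    dataset: DatasetBundle,
    config: DreamConfig,
    seed: int = 0,
) -> FoldInputs:
    """Rebuild all fold-specific structures from training information only.

    The bipartite graph is assembled later (per epoch, because unknown edges
    are resampled); this returns the training pair sets, the harmonized
    features and the four similarity graphs. Raw embeddings are label-free,
    so the kNN graphs are identical across pair-wise folds by construction —
    the leakage rule bites through the train mask handed to the graph
    builder and, in the cold-start protocol, through entity removal.
    """
    assoc = dataset.assoc
    mask = plan.train_mask(fold, assoc.matrix.shape)
    train_pos = np.argwhere((assoc.matrix == 1) & mask)
    train_unk = np.argwhere((assoc.matrix == 0) & mask)

    feats = harmonize(
        dataset.drug_small_mol,
        dataset.drug_protein,
        dataset.disease_emb,
        assoc.drug_ids,
        n_components=config.drug_dim,
    )
    features_drugs = feats.drugs.matrix
    features_diseases = feats.diseases.matrix
    from .feature_space import stack_drug_features

    raw_drugs = stack_drug_features(
        dataset.drug_small_mol, dataset.drug_protein, assoc.drug_ids
    )
    raw_diseases = dataset.disease_emb
    if config.random_node_features:
        noise_rng = np.random.default_rng(seed + 7919)
        features_drugs = noise_rng.normal(size=features_drugs.shape)
        features_diseases = noise_rng.normal(size=features_diseases.shape)
    graphs = _build_similarity_graphs(
        raw_drugs, raw_diseases, dataset.drug_sim, dataset.disease_sim, config
    )
    return FoldInputs(
        features_drugs,
        features_diseases,
        raw_drugs.matrix,
        raw_diseases.matrix,
        train_pos,
        train_unk,
        mask,
        graphs,
        feats.pca_model,
        assoc,
    )


def audit_no_leakage(fold_inputs: FoldInputs, graph: BipartiteAssociationGraph,
                     test_pairs: np.ndarray) -> None:
    """Assert no held-out pair appears as an edge of any relation."""
    test = {tuple(p) for p in np.asarray(test_pairs)}
    for rel in ("known", "unknown"):
        for e in graph.edges(rel):
            if tuple(e) in test:
                raise AssertionError(
                    f"leakage: held-out pair {tuple(e)} present as a {rel} edge"
                )


def _model_inputs(fold_inputs: FoldInputs, graph: BipartiteAssociationGraph | None,
                  features_drugs=None, features_diseases=None,
                  graphs: dict | None = None) -> ModelInputs:
    g = graphs if graphs is not None else fold_inputs.graphs
    return ModelInputs(
        features_drugs if features_drugs is not None else fold_inputs.features_drugs,
        features_diseases if features_diseases is not None else fold_inputs.features_diseases,
        graph,
        g["drug_pred"],
        g["drug_feat"],
        g["disease_pred"],
        g["disease_feat"],
    )


def train_model(
    fold_inputs: FoldInputs,
    config: DreamConfig,
    seed: int = 0,
) -> tuple[DualRouteModel, dict]:
    """Train one model on one fold's training data.

    Per epoch: the unknown-relation edges (which double as the loss
    negatives) are resampled 1:1 with the training positives, Gaussian
    feature perturbation and edge dropout are applied when augmentation is
    on, and one full-batch AdamW step is taken on the binary cross-entropy
    over training positives + sampled negatives. Early stopping watches the
    loss on a held-aside validation slice of the training positives (with
    matched sampled negatives); the best-validation parameters are restored.
    """
    rng = np.random.default_rng(seed)
    model = DualRouteModel(fold_inputs.features_drugs.shape[1], config, rng)
    opt = nn.AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    pos = fold_inputs.train_pos
    unk_pool = fold_inputs.train_unknowns
    n_val = max(1, int(round(config.val_fraction * len(pos)))) if len(pos) >= 4 else 0
    perm = rng.permutation(len(pos))
    val_pos, fit_pos = pos[perm[:n_val]], pos[perm[n_val:]]
    # a large fixed negative sample stabilizes the validation ranking signal;
    # these unknowns stay in the training pool (their labels are training
    # information either way)
    n_val_neg = min(len(unk_pool), max(200, 20 * n_val))
    val_neg = unk_pool[rng.choice(len(unk_pool), size=n_val_neg, replace=False)]
    fit_unk_pool = unk_pool
    val_pairs = np.vstack([val_pos, val_neg]) if n_val else None
    val_labels = (
        np.concatenate([np.ones(len(val_pos)), np.zeros(len(val_neg))]) if n_val else None
    )

    n_neg = min(len(fit_unk_pool), int(round(config.negative_ratio * len(fit_pos))))
    use_graph_negatives = config.unknown_edges_in_graph

    history: dict = {"train_loss": [], "val_loss": [], "val_auprc": [], "val_auroc": []}
    best_val = -np.inf
    best_state = [p.data.copy() for p in model.parameters()]
    patience_left = config.patience

    for epoch in range(config.epochs):
        neg_idx = rng.choice(len(fit_unk_pool), size=n_neg, replace=False)
        negatives = fit_unk_pool[neg_idx]
        graph = BipartiteAssociationGraph(
            fold_inputs.assoc.n_drugs,
            fold_inputs.assoc.n_diseases,
            fit_pos,
            negatives if use_graph_negatives else np.empty((0, 2), dtype=np.int64),
        )
        fd, fm = fold_inputs.features_drugs, fold_inputs.features_diseases
        if config.augment:
            graph = edge_dropout(graph, config.edge_dropout_p, rng)
            fd = gaussian_perturb(fd, config.feature_sigma, rng)
            fm = gaussian_perturb(fm, config.feature_sigma, rng)
        inputs = _model_inputs(fold_inputs, graph, fd, fm)
        pairs = np.vstack([fit_pos, negatives])
        labels = np.concatenate([np.ones(len(fit_pos)), np.zeros(len(negatives))])
        logits = model.pair_scores(inputs, pairs, training=True, rng=rng)
        loss = nn.bce_with_logits(logits, labels)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={float(loss.data)}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        history["train_loss"].append(float(loss.data))

        if val_pairs is not None:
            eval_graph = BipartiteAssociationGraph(
                fold_inputs.assoc.n_drugs, fold_inputs.assoc.n_diseases,
                fit_pos, negatives if use_graph_negatives else np.empty((0, 2), dtype=np.int64),
            )
            eval_inputs = _model_inputs(fold_inputs, eval_graph)
            val_logits = model.pair_scores(eval_inputs, val_pairs, training=False)
            data = val_logits.data if isinstance(val_logits, nn.Tensor) else val_logits
            # early stopping watches validation AUROC: with a handful of
            # validation positives it is far more stable than AUPRC, which can
            # spike on a lucky early epoch and pin the checkpoint there
            val_metric = roc_auc_score(val_labels, data)
            history["val_loss"].append(float(nn.bce_with_logits(data, val_labels)))
            history["val_auprc"].append(float(average_precision_score(val_labels, data)))
            history["val_auroc"].append(float(val_metric))
            if val_metric > best_val + 1e-6:
                best_val = float(val_metric)
                best_state = [p.data.copy() for p in model.parameters()]
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if val_pairs is not None:
        for p, s in zip(model.parameters(), best_state):
            p.data = s
    history["epochs_run"] = len(history["train_loss"])
    # the evaluation-time graph: all training positives + a final seeded
    # negative-edge sample (unknown edges are training scaffolding; scoring
    # itself never reads test labels)
    final_neg = (
        fit_unk_pool[rng.choice(len(fit_unk_pool), size=n_neg, replace=False)]
        if use_graph_negatives and n_neg
        else np.empty((0, 2), dtype=np.int64)
    )
    eval_graph = BipartiteAssociationGraph(
        fold_inputs.assoc.n_drugs, fold_inputs.assoc.n_diseases,
        np.vstack([fit_pos, val_pos]) if len(val_pos) else fit_pos,
        final_neg,
    )
    history["eval_graph"] = eval_graph
    return model, history


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("metric requires both classes present")
    return labels


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties count 1/2)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def f1_recall_at_threshold(scores, labels, threshold: float = 0.5) -> dict:
    """Secondary threshold metrics; 0.5 by default."""
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(scores) >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"f1": f1, "recall": recall, "precision": precision, "threshold": threshold}


def paired_t_test(values_a, values_b) -> dict:
    """Two-sided paired t-test on per-fold metric differences."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs two equal-length vectors of size >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences in paired t-test", RuntimeWarning)
        if np.allclose(diffs.mean(), 0.0):
            return {"t": 0.0, "p": 1.0}
        return {"t": float(np.sign(diffs.mean()) * np.inf), "p": 0.0}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p)}


@dataclass
class MetricsReport:
    """Per-fold metrics with mean +/- sd summaries."""

    auroc_per_fold: list[float]
    auprc_per_fold: list[float]
    f1_per_fold: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.auroc_per_fold))

    @property
    def auroc_sd(self) -> float:
        return float(np.std(self.auroc_per_fold, ddof=1)) if len(self.auroc_per_fold) > 1 else 0.0

    @property
    def auprc_mean(self) -> float:
        return float(np.mean(self.auprc_per_fold))

    @property
    def auprc_sd(self) -> float:
        return float(np.std(self.auprc_per_fold, ddof=1)) if len(self.auprc_per_fold) > 1 else 0.0

    def compare(self, other: "MetricsReport") -> dict:
        return {
            "auroc": paired_t_test(self.auroc_per_fold, other.auroc_per_fold),
            "auprc": paired_t_test(self.auprc_per_fold, other.auprc_per_fold),
        }

    def to_dict(self) -> dict:
        return {
            "auroc": {"per_fold": self.auroc_per_fold, "mean": self.auroc_mean, "sd": self.auroc_sd},
            "auprc": {"per_fold": self.auprc_per_fold, "mean": self.auprc_mean, "sd": self.auprc_sd},
            "f1_at_threshold": self.f1_per_fold,
            **self.extras,
        }


def run_cv(
    dataset: DatasetBundle,
    config: DreamConfig,
    seed: int = 0,
    n_folds: int | None = None,
) -> MetricsReport:
    """Full cross-validation: rebuild, train, score every held-out pair.

    Each fold's held-out set is its positives plus *all* of its unknowns.
    """
    n_folds = n_folds if n_folds is not None else config.n_folds
    plan = make_folds(dataset.assoc, n_folds=n_folds, seed=seed)
    aurocs, auprcs, f1s, logs = [], [], [], []
    for fold in range(n_folds):
        fold_inputs = rebuild_fold_inputs(fold, plan, dataset, config, seed=seed)
        model, history = train_model(fold_inputs, config, seed=seed + fold)
        test_pairs, test_labels = plan.test_pairs(fold)
        eval_graph = history["eval_graph"]
        audit_no_leakage(fold_inputs, eval_graph, test_pairs)
        inputs = _model_inputs(fold_inputs, eval_graph)
        scores = model.predict(inputs, test_pairs)
        aurocs.append(auroc(scores, test_labels))
        auprcs.append(auprc(scores, test_labels))
        f1s.append(f1_recall_at_threshold(scores, test_labels))
        logs.append({"epochs_run": history["epochs_run"],
                     "final_train_loss": history["train_loss"][-1]})
    return MetricsReport(aurocs, auprcs, f1s, extras={"fold_logs": logs, "seed": seed})
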