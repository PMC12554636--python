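"""Fold construction, leakage-free rebuilds, training loop and metrics."""

import numpy as np
import pytest

from dreamgnn.config import DreamConfig
from dreamgnn.datasets_io import AssociationTable
from dreamgnn.synthetic_fixtures import SyntheticSpec, generate
from dreamgnn.training_evaluation import (
    audit_no_leakage,
    auprc,
    auroc,
    f1_recall_at_threshold,
    make_folds,
    paired_t_test,
    rebuild_fold_inputs,
    run_cv,
    train_model,
    _model_inputs,
)


def _assoc(n_pos=23, shape=(10, 8), seed=0):
    rng = np.random.default_rng(seed)
    m = np.zeros(shape, dtype=int)
    flat = rng.choice(shape[0] * shape[1], size=n_pos, replace=False)
    m[np.unravel_index(flat, shape)] = 1
    return AssociationTable(
        [f"d{i}" for i in range(shape[0])], [f"m{j}" for j in range(shape[1])], m
    )


class TestMakeFolds:
    def test_equal_split_when_divisible(self):
        plan = make_folds(_assoc(n_pos=20), n_folds=10, seed=0)
        assert all(len(p) == 2 for p in plan.test_pos)

    def test_partition_is_exhaustive_and_disjoint(self):
        assoc = _assoc(n_pos=23)
        plan = make_folds(assoc, n_folds=10, seed=1)
        all_pos = np.vstack(plan.test_pos)
        all_unk = np.vstack(plan.test_unk)
        assert len(all_pos) == 23
        assert len(all_unk) == 80 - 23
        seen = {tuple(p) for p in np.vstack([all_pos, all_unk])}
        assert len(seen) == 80  # every pair exactly once

    def test_fold_sizes_differ_by_at_most_one(self):
        plan = make_folds(_assoc(n_pos=23), n_folds=10, seed=2)
        sizes = [len(p) for p in plan.test_pos]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 23

    def test_too_few_positives_errors(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds(_assoc(n_pos=5), n_folds=10)


class TestRebuildAndLeakage:
    def test_training_positives_exclude_test_fold(self, tiny_bundle, fast_config):
        plan = make_folds(tiny_bundle.assoc, n_folds=5, seed=0)
        fi = rebuild_fold_inputs(0, plan, tiny_bundle, fast_config, seed=0)
        test_set = {tuple(p) for p in plan.test_pos[0]}
        train_set = {tuple(p) for p in fi.train_pos}
        assert train_set.isdisjoint(test_set)
        assert train_set | test_set == {
            tuple(p) for p in np.argwhere(tiny_bundle.assoc.matrix == 1)
        }

    def test_embedding_knn_graphs_identical_across_folds(self, tiny_bundle, fast_config):
        plan = make_folds(tiny_bundle.assoc, n_folds=5, seed=0)
        a = rebuild_fold_inputs(0, plan, tiny_bundle, fast_config, seed=0)
        b = rebuild_fold_inputs(3, plan, tiny_bundle, fast_config, seed=0)
        for key in a.graphs:
            np.testing.assert_array_equal(a.graphs[key].weights, b.graphs[key].weights)

    def test_audit_catches_planted_leak(self, tiny_bundle, fast_config):
        from dreamgnn.graph_construction import BipartiteAssociationGraph

        plan = make_folds(tiny_bundle.assoc, n_folds=5, seed=0)
        fi = rebuild_fold_inputs(0, plan, tiny_bundle, fast_config, seed=0)
        leaked = plan.test_pos[0][:1]
        bad_graph = BipartiteAssociationGraph(
            tiny_bundle.assoc.n_drugs, tiny_bundle.assoc.n_diseases,
            np.vstack([fi.train_pos, leaked]), np.empty((0, 2), dtype=np.int64),
        )
        with pytest.raises(AssertionError, match="leakage"):
            audit_no_leakage(fi, bad_graph, plan.test_pairs(0)[0])


class TestTrainModel:
    def test_loss_decreases_on_toy_problem(self, tiny_bundle, fast_config):
        plan = make_folds(tiny_bundle.assoc, n_folds=5, seed=0)
        fi = rebuild_fold_inputs(0, plan, tiny_bundle, fast_config, seed=0)
        model, hist = train_model(fi, fast_config, seed=0)
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_fixed_seed_reproduces_loss_trace(self, tiny_bundle):
        config = DreamConfig.small(epochs=8, patience=8, augment=False)
        plan = make_folds(tiny_bundle.assoc, n_folds=5, seed=0)
        fi = rebuild_fold_inputs(0, plan, tiny_bundle, config, seed=0)
        _, h1 = train_model(fi, config, seed=11)
        _, h2 = train_model(fi, config, seed=11)
        np.testing.assert_array_equal(h1["train_loss"], h2["train_loss"])

    def test_train_auroc_at_least_test_auroc(self, tiny_bundle, fast_config):
        plan = make_folds(tiny_bundle.assoc, n_folds=5, seed=0)
        fi = rebuild_fold_inputs(0, plan, tiny_bundle, fast_config, seed=0)
        model, hist = train_model(fi, fast_config, seed=0)
        inputs = _model_inputs(fi, hist["eval_graph"])
        rng = np.random.default_rng(0)
        neg = fi.train_unknowns[rng.choice(len(fi.train_unknowns), 100)]
        tr_pairs = np.vstack([fi.train_pos, neg])
        tr_labels = np.r_[np.ones(len(fi.train_pos)), np.zeros(len(neg))]
        te_pairs, te_labels = plan.test_pairs(0)
        tr = auroc(model.predict(inputs, tr_pairs), tr_labels)
        te = auroc(model.predict(inputs, te_pairs), te_labels)
        assert tr >= te - 0.05  # overfit direction, small slack for sampling noise


class TestMetrics:
    def test_perfect_and_reversed_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auprc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auroc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0]) == 0.0

    def test_auroc_equals_pairwise_counting_oracle(self, rng):
        scores = rng.random(6)
        labels = np.array([1, 0, 1, 0, 0, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auroc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_f1_recall_at_half_threshold(self):
        out = f1_recall_at_threshold([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0])
        assert out["recall"] == pytest.approx(0.5)
        assert out["precision"] == pytest.approx(0.5)
        assert out["f1"] == pytest.approx(0.5)


class TestPairedTTest:
    def test_identical_vectors_warn_zero_variance(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = paired_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_shift_matches_closed_form(self):
        rng = np.random.default_rng(0)
        b = rng.random(10)
        a = b + 0.03 + rng.normal(0, 0.01, 10)
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert paired_t_test(a, b)["t"] == pytest.approx(t_expected)

    def test_swapping_negates_t_preserves_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(8), rng.random(8)
        r1, r2 = paired_t_test(a, b), paired_t_test(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])


class TestRunCv:
    def test_report_mean_is_arithmetic_mean_of_folds(self, tiny_bundle, fast_config):
        rep = run_cv(tiny_bundle, fast_config, seed=0, n_folds=3)
        assert rep.auroc_mean == pytest.approx(np.mean(rep.auroc_per_fold))
        assert all(0 <= v <= 1 for v in rep.auroc_per_fold + rep.auprc_per_fold)

    def test_route_ablations_run(self, tiny_bundle, fast_config):
        for route in ("topology_only", "similarity_only"):
            rep = run_cv(tiny_bundle, fast_config.with_ablation(route), seed=0, n_folds=2)
            assert len(rep.auroc_per_fold) == 2

    def test_remaining_ablation_variants_run(self, tiny_bundle):
        cfg = DreamConfig.small(epochs=5, patience=5)
        for name in ("wo_attention_dropout", "wo_parameter_sharing",
                     "wo_augmentation", "wo_node_feature_embedding"):
            rep = run_cv(tiny_bundle, cfg.with_ablation(name), seed=0, n_folds=2)
            assert len(rep.auprc_per_fold) == 2
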