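import dataclasses

import numpy as np
import pytest

from conftest import brute_force_pr
from gcnppi.data_io import Dataset, InteractionPair, SequenceRecord
from gcnppi.experiment import (ConfigurationError, TrainConfig, evaluate,
                               kfold_split, permute_labels,
                               pr_curve_sweep, protein_level_split,
                               score_pairs, train_fold, write_results)


def make_pairs(n_pos, n_neg):
    pairs = []
    k = 0
    for label, count in ((1, n_pos), (0, n_neg)):
        for _ in range(count):
            pairs.append(InteractionPair(f"A{k}", f"B{k}", label))
            k += 1
    return pairs


@pytest.fixture
def tiny_dataset():
    """20 proteins in two planted groups; strong topological signal."""
    rng = np.random.default_rng(5)
    records = [SequenceRecord(f"P{i}",
                              "".join(rng.choice(list("ACDEFGHIKL"), 30)))
               for i in range(20)]
    pairs = []
    for i in range(20):
        for j in range(i + 1, 20):
            same = (i < 10) == (j < 10)
            label = 1 if same and rng.random() < 0.8 else 0
            if same or rng.random() < 0.3:
                pairs.append(InteractionPair(f"P{i}", f"P{j}", label))
    return Dataset(records=records, pairs=pairs, name="tiny")


@pytest.fixture
def tiny_config():
    return TrainConfig(seed=0, epochs=5, batch_size=8, L=30, f=4,
                       branch_widths=(8, 4), joint_widths=(4, 2),
                       dropout_p=0.0)


class TestKfoldSplit:
    def test_stratified_balanced(self):
        pairs = make_pairs(5, 5)
        split = kfold_split(pairs, 5, seed=0)
        labels = np.array([p.label for p in pairs])
        for fold in range(5):
            idx = split.test_indices(fold)
            assert idx.size == 2
            assert labels[idx].sum() == 1

    def test_deterministic_given_seed(self):
        pairs = make_pairs(8, 8)
        s1 = kfold_split(pairs, 4, seed=3)
        s2 = kfold_split(pairs, 4, seed=3)
        assert np.array_equal(s1.assignments, s2.assignments)

    def test_partition_and_size_balance(self):
        pairs = make_pairs(11, 9)
        split = kfold_split(pairs, 4, seed=1)
        sizes = [split.test_indices(f).size for f in range(4)]
        assert sum(sizes) == 20
        assert max(sizes) - min(sizes) <= 1

    def test_k_out_of_range(self):
        with pytest.raises(ConfigurationError):
            kfold_split(make_pairs(2, 2), 10, seed=0)

    def test_protein_level_split_separates_proteins(self):
        pairs = [InteractionPair("X1", "X2", 1),
                 InteractionPair("X1", "X3", 0),
                 InteractionPair("X4", "X5", 1),
                 InteractionPair("X4", "X6", 0)]
        split = protein_level_split(pairs, 2, seed=0)
        # pairs anchored on the same protein always share a fold
        assert split.assignments[0] == split.assignments[1]
        assert split.assignments[2] == split.assignments[3]


class TestEvaluate:
    def test_hand_computed_confusion(self):
        # TP=3, FP=1, FN=0, TN=2
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        r = evaluate(scores, labels, threshold=0.5)
        assert (r.counts.tp, r.counts.fp, r.counts.fn, r.counts.tn) == \
            (3, 1, 0, 2)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(1.0)
        assert r.accuracy == pytest.approx(5 / 6)

    def test_perfect_separation_unit_area(self):
        r = evaluate(np.array([0.9, 0.8, 0.2, 0.1]),
                     np.array([1, 1, 0, 0]))
        assert r.auPR == pytest.approx(1.0)

    def test_precision_undefined_when_no_predicted_positives(self):
        r = evaluate(np.array([0.1, 0.2]), np.array([1, 0]), threshold=0.5)
        assert r.precision is None
        assert r.recall == 0.0

    def test_recall_undefined_without_positives(self):
        r = evaluate(np.array([0.9, 0.1]), np.array([0, 0]))
        assert r.recall is None
        assert r.auPR is None

    def test_threshold_tie_classifies_positive(self):
        r = evaluate(np.array([0.5]), np.array([1]), threshold=0.5)
        assert r.counts.tp == 1

    def test_counts_total_matches_pairs(self):
        rng = np.random.default_rng(0)
        scores = rng.random(37)
        labels = rng.integers(0, 2, 37)
        r = evaluate(scores, labels)
        assert r.counts.total == 37


class TestPRSweep:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        scores = np.round(rng.random(n), 2)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.sum() == 0:
            labels[0] = 1
        points, area = brute_force_pr(scores, labels)
        curve, got_area = pr_curve_sweep(scores, labels)
        assert got_area == pytest.approx(area, abs=1e-12)
        assert np.allclose(curve, np.array(points))

    def test_example_three_scores(self):
        # scores (0.9, 0.8, 0.3), labels (1, 0, 1): thresholds 0.9/0.8/0.3
        # give (R=0.5, P=1), (R=0.5, P=0.5), (R=1, P=2/3);
        # area = 0.5 * 1 + 0.5 * 2/3
        _, area = pr_curve_sweep(np.array([0.9, 0.8, 0.3]),
                                 np.array([1, 0, 1]))
        assert area == pytest.approx(0.5 + 0.5 * 2 / 3)


class TestTrainFold:
    def test_zero_epochs_returns_initialization(self, tiny_dataset,
                                                tiny_config):
        split = kfold_split(tiny_dataset.pairs, 3, seed=0)
        cfg0 = dataclasses.replace(tiny_config, epochs=0)
        t1 = train_fold(tiny_dataset, split, 0, cfg0)
        t2 = train_fold(tiny_dataset, split, 0, cfg0)
        for k, v in t1.model.parameters().items():
            assert np.array_equal(v, t2.model.parameters()[k])
        assert t1.epoch_losses == []

    def test_deterministic_given_seed(self, tiny_dataset, tiny_config):
        split = kfold_split(tiny_dataset.pairs, 3, seed=0)
        t1 = train_fold(tiny_dataset, split, 0, tiny_config)
        t2 = train_fold(tiny_dataset, split, 0, tiny_config)
        assert t1.epoch_losses == t2.epoch_losses
        for k, v in t1.model.parameters().items():
            assert np.array_equal(v, t2.model.parameters()[k])

    def test_loss_decreases_in_aggregate(self, tiny_dataset):
        cfg = TrainConfig(seed=1, epochs=200, batch_size=16, L=30, f=8,
                          branch_widths=(16, 8), joint_widths=(4, 2),
                          dropout_p=0.0)
        split = kfold_split(tiny_dataset.pairs, 3, seed=1)
        trained = train_fold(tiny_dataset, split, 0, cfg)
        losses = trained.epoch_losses
        assert np.mean(losses[-20:]) < np.mean(losses[:20])

    def test_graph_built_from_training_positives_only(self, tiny_dataset,
                                                      tiny_config):
        split = kfold_split(tiny_dataset.pairs, 3, seed=0)
        trained = train_fold(tiny_dataset, split, 0, tiny_config)
        test_keys = {tiny_dataset.pairs[i].key
                     for i in split.test_indices(0)}
        assert not (trained.graph.edges & test_keys)

    def test_leakage_safety_adjacency_bit_identical(self, tiny_dataset,
                                                    tiny_config):
        """Removing the test-fold pairs from the dataset entirely leaves
        the training adjacency bit-identical."""
        split = kfold_split(tiny_dataset.pairs, 3, seed=0)
        trained_full = train_fold(tiny_dataset, split, 0, tiny_config)
        keep = split.train_indices(0)
        reduced = Dataset(
            records=tiny_dataset.records,
            pairs=[tiny_dataset.pairs[i] for i in keep],
            name="reduced")
        reduced_split = dataclasses.replace(
            split, assignments=split.assignments[keep])
        trained_reduced = train_fold(reduced, reduced_split, 0, tiny_config)
        assert np.array_equal(trained_full.graph.A_tilde,
                              trained_reduced.graph.A_tilde)

    def test_score_pairs_shape_and_range(self, tiny_dataset, tiny_config):
        split = kfold_split(tiny_dataset.pairs, 3, seed=0)
        trained = train_fold(tiny_dataset, split, 0, tiny_config)
        test = [tiny_dataset.pairs[i] for i in split.test_indices(0)]
        scores = score_pairs(trained, tiny_dataset, test, tiny_config)
        assert scores.shape == (len(test),)
        assert np.all((scores >= 0) & (scores <= 1))


class TestConfigValidation:
    def test_invalid_mode(self):
        with pytest.raises(ConfigurationError, match="mode"):
            TrainConfig(mode="both")

    def test_invalid_learning_rate(self):
        with pytest.raises(ConfigurationError, match="learning_rate"):
            TrainConfig(learning_rate=0.0)

    def test_invalid_dtype(self):
        with pytest.raises(ConfigurationError, match="dtype"):
            TrainConfig(dtype="float16")


def test_permute_labels_preserves_label_multiset(tiny_dataset):
    permuted = permute_labels(tiny_dataset, seed=0)
    original = sorted(p.label for p in tiny_dataset.pairs)
    assert sorted(p.label for p in permuted.pairs) == original
    assert [(p.id_a, p.id_b) for p in permuted.pairs] == \
        [(p.id_a, p.id_b) for p in tiny_dataset.pairs]


def test_write_results_files(tmp_path):
    from gcnppi.experiment import CrossValResult
    r = evaluate(np.array([0.9, 0.1]), np.array([1, 0]))
    result = CrossValResult(
        fold_reports=[r],
        mean_metrics={"precision": 1.0, "recall": 1.0, "accuracy": 1.0,
                      "auPR": 1.0},
        pooled_metrics={"precision": 1.0, "recall": 1.0, "accuracy": 1.0,
                        "auPR": 1.0})
    write_results(result, tmp_path, prefix="combined")
    assert (tmp_path / "combined_folds.tsv").exists()
    summary = (tmp_path / "combined_summary.tsv").read_text()
    assert "fold_mean" in summary and "pooled" in summary
    assert (tmp_path / "combined_pr_fold0.tsv").exists()
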