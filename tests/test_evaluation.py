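"""Metric formulas against independent oracles; protocol contracts."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, matthews_corrcoef, recall_score

from bbbpep.architectures import build_architecture
from bbbpep.classifiers import TrainConfig, predict_labels, predict_proba, train
from bbbpep.evaluation import (
    ConfusionCounts,
    EvalReport,
    metrics,
    roc_auc,
    self_consistency,
    independent_test,
    five_fold_cv,
)
from bbbpep.features import FeatureConfig, featurize_dataset, fit_apply_scaling
from bbbpep.sequences import LabeledDataset, Peptide
from bbbpep.synthetic import SplitSpec, generate_synthetic_dataset

#: Small feature layout + quick training for protocol tests.
FAST_FEATURES = FeatureConfig(blocks=("FV", "AAPIV", "RAAPIV"))
FAST_CFG = TrainConfig(max_epochs=60, patience=60, seed=0)


def counts_to_arrays(c: ConfusionCounts):
    y_true = np.concatenate([np.ones(c.TP + c.FN, dtype=int), np.zeros(c.TN + c.FP, dtype=int)])
    y_pred = np.concatenate(
        [np.ones(c.TP, dtype=int), np.zeros(c.FN, dtype=int), np.zeros(c.TN, dtype=int), np.ones(c.FP, dtype=int)]
    )
    return y_true, y_pred


class TestMetrics:
    def test_symmetric_null(self):
        m = metrics(ConfusionCounts(25, 25, 25, 25))
        assert m["accuracy"] == 0.5 and m["mcc"] == 0.0

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0, "mcc": 1.0}

    def test_worked_example(self):
        m = metrics(ConfusionCounts(TP=50, TN=40, FP=10, FN=0))
        assert m["accuracy"] == pytest.approx(0.9)
        assert m["sensitivity"] == pytest.approx(1.0)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["mcc"] == pytest.approx(0.8164965809)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_zero_denominator_mcc_convention(self):
        assert metrics(ConfusionCounts(TP=10, TN=0, FP=0, FN=0))["mcc"] == 0.0

    def test_agrees_with_sklearn_oracle_on_random_tables(self, rng):
        for _ in range(300):
            c = ConfusionCounts(*rng.integers(0, 40, size=4))
            if c.total == 0:
                continue
            y_true, y_pred = counts_to_arrays(c)
            m = metrics(c)
            assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
            if c.TP + c.FN > 0:
                assert m["sensitivity"] == pytest.approx(recall_score(y_true, y_pred, pos_label=1, zero_division=0))
            if c.TN + c.FP > 0:
                assert m["specificity"] == pytest.approx(recall_score(y_true, y_pred, pos_label=0, zero_division=0))
            if len(np.unique(y_true)) == 2 and len(np.unique(y_pred)) == 2:
                assert m["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred))


class TestRocAuc:
    def test_perfect_ranking(self):
        _, area = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert area == 1.0

    def test_inverted_ranking(self):
        _, area = roc_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert area == 0.0

    def test_all_ties_give_half(self):
        _, area = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert area == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_equals_pairwise_comparison_probability(self, rng):
        for _ in range(30):
            n_pos, n_neg = rng.integers(3, 100, size=2)
            labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
            scores = np.round(rng.random(n_pos + n_neg), 2)  # ties likely
            _, area = roc_auc(labels, scores)
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert area == pytest.approx(wins / (n_pos * n_neg))


@pytest.fixture(scope="module")
def dataset():
    return generate_synthetic_dataset(40, 40, (8, 25), 0.8, seed=13)


class TestProtocols:

    def test_self_consistency_memorizes_separable_fixtures(self, dataset):
        spec = build_architecture("FCN", FAST_FEATURES.n_features)
        report = self_consistency(spec, dataset, FAST_CFG, FAST_FEATURES)
        assert report.protocol == "self_consistency"
        assert report.counts.total == len(dataset)
        assert report.accuracy >= 0.95

    def test_independent_counts_sum_to_test_partition(self, dataset):
        spec = build_architecture("FCN", FAST_FEATURES.n_features)
        report = independent_test(spec, dataset, SplitSpec(0.77, seed=3), FAST_CFG, FAST_FEATURES)
        assert report.protocol == "independent"
        # floor(0.77*40)=30 per class -> 10 per class held out
        assert report.counts.total == 20

    def test_independent_deterministic_under_fixed_seeds(self, dataset):
        spec = build_architecture("FCN", FAST_FEATURES.n_features)
        a = independent_test(spec, dataset, SplitSpec(0.77, seed=3), FAST_CFG, FAST_FEATURES)
        b = independent_test(spec, dataset, SplitSpec(0.77, seed=3), FAST_CFG, FAST_FEATURES)
        assert a.to_dict() == b.to_dict()

    def test_label_shuffled_data_scores_near_chance(self):
        rng = np.random.default_rng(4)
        ds = generate_synthetic_dataset(100, 100, (8, 25), 0.8, seed=21)
        shuffled_labels = rng.permutation([p.label for p in ds])
        shuffled = LabeledDataset(
            [Peptide(p.id, p.sequence, int(l)) for p, l in zip(ds, shuffled_labels)]
        )
        spec = build_architecture("FCN", FAST_FEATURES.n_features)
        report = independent_test(spec, shuffled, SplitSpec(0.5, seed=3), FAST_CFG, FAST_FEATURES)
        assert abs(report.accuracy - 0.5) <= 0.12

    def test_five_fold_partition_arithmetic(self, dataset):
        spec = build_architecture("FCN", FAST_FEATURES.n_features)
        report = five_fold_cv(spec, dataset, seed=5, cfg=FAST_CFG, feature_config=FAST_FEATURES)
        assert report.protocol == "five_fold_cv"
        assert [f["n_test"] for f in report.folds] == [16] * 5
        assert report.counts.total == len(dataset)
        assert all(0.0 <= f["accuracy"] <= 1.0 for f in report.folds)
        assert report.accuracy == pytest.approx(np.mean([f["accuracy"] for f in report.folds]))

    def test_five_fold_pooled_aggregation_mode(self, dataset):
        spec = build_architecture("FCN", FAST_FEATURES.n_features)
        report = five_fold_cv(
            spec, dataset, seed=5, cfg=FAST_CFG, feature_config=FAST_FEATURES, aggregate="pooled"
        )
        assert report.accuracy == pytest.approx(metrics(report.counts)["accuracy"])

    def test_five_fold_requires_enough_samples(self):
        tiny = generate_synthetic_dataset(3, 3, (8, 25), 0.5, seed=1)
        spec = build_architecture("FCN", FAST_FEATURES.n_features)
        with pytest.raises(ValueError):
            five_fold_cv(spec, tiny, cfg=FAST_CFG, feature_config=FAST_FEATURES)

    def test_report_serialization(self, dataset, tmp_path):
        spec = build_architecture("FCN", FAST_FEATURES.n_features)
        report = self_consistency(spec, dataset, FAST_CFG, FAST_FEATURES)
        report.to_json(tmp_path / "r.json")
        md = report.to_markdown()
        assert "| Accuracy |" in md.replace("Classifier | Accuracy", "Classifier | Accuracy") or "Accuracy" in md
        report.write_roc_tsv(tmp_path / "roc.tsv")
        lines = (tmp_path / "roc.tsv").read_text().splitlines()
        assert lines[0] == "fpr\ttpr\tthreshold" and len(lines) > 2


class TestModelRoundtrip:
    def test_checkpoint_save_load_preserves_predictions(self, tmp_path):
        ds = generate_synthetic_dataset(20, 20, (8, 25), 0.8, seed=2)
        table = featurize_dataset(ds, FAST_FEATURES)
        scaled, _ = fit_apply_scaling(table)
        spec = build_architecture("GRU", FAST_FEATURES.n_features)
        model = train(spec, scaled, TrainConfig(max_epochs=5, seed=1))
        before = predict_proba(model, scaled)
        path = str(tmp_path / "model.npz")
        model.save(path)
        from bbbpep.classifiers import TrainedModel

        loaded = TrainedModel.load(path)
        assert np.allclose(before, predict_proba(loaded, scaled))
        assert predict_labels(loaded, scaled).shape == (40,)
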