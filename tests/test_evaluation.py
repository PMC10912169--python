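import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afmspeech.evaluation import (
    CLASSIFIER_NAMES,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    ConfusionCounts,
    LabeledFeatureTable,
    UndefinedMetricError,
    accuracy,
    auc,
    f1,
    f1_from_precision_recall,
    kfold_evaluate,
    loso_evaluate,
    make_classifier,
    precision,
    recall,
    split_evaluate,
)


def brute_force_auc(scores, labels):
    """Average over all positive-negative pairs, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == POSITIVE_LABEL]
    neg = [s for s, l in zip(scores, labels) if l == NEGATIVE_LABEL]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0)
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def blob_table(n_per_class=100, sep=4.0, n_features=4, seed=0, n_subjects=5):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(n_per_class, n_features)),
            rng.normal(sep, 1.0, size=(n_per_class, n_features)),
        ]
    )
    labels = np.array([NEGATIVE_LABEL] * n_per_class + [POSITIVE_LABEL] * n_per_class)
    subjects = np.array(
        [f"hc{i % n_subjects}" for i in range(n_per_class)]
        + [f"dys{i % n_subjects}" for i in range(n_per_class)]
    )
    cols = [f"f{i}" for i in range(n_features)]
    return LabeledFeatureTable(pd.DataFrame(X, columns=cols), labels, subjects)


class TestConfusionMetrics:
    def test_perfect(self):
        assert accuracy(ConfusionCounts(5, 5, 0, 0)) == 1.0

    def test_direct_arithmetic(self):
        assert accuracy(ConfusionCounts(3, 2, 1, 2)) == 0.625

    def test_always_wrong(self):
        assert accuracy(ConfusionCounts(0, 0, 4, 4)) == 0.0

    def test_f1_harmonic_mean_fixed_point(self):
        assert f1_from_precision_recall(0.8, 0.8) == pytest.approx(0.8)

    def test_f1_matches_lda_split_cells(self):
        # printed precision/recall 0.8623 / 0.8025 must give the printed 0.8313
        assert f1_from_precision_recall(0.8623, 0.8025) == pytest.approx(0.8313, abs=1e-4)

    def test_f1_matches_boosted_tree_split_cells(self):
        # printed precision/recall 0.9840 / 0.9388 against the printed 0.9608
        assert f1_from_precision_recall(0.9840, 0.9388) == pytest.approx(0.9608, abs=1e-4)

    def test_undefined_metrics_raise(self):
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(0, 5, 0, 5))
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(0, 5, 5, 0))

    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_metric_identities(self, counts):
        tp, tn, fp, fn = counts
        c = ConfusionCounts(tp, tn, fp, fn)
        if c.total:
            assert accuracy(c) == (tp + tn) / (tp + tn + fp + fn)
        if tp + fp:
            assert precision(c) == tp / (tp + fp)
        if tp + fn:
            assert recall(c) == tp / (tp + fn)
        if tp + fp and tp + fn and tp:
            pre, rec = precision(c), recall(c)
            expected = 2 * pre * rec / (pre + rec)
            assert f1(c) == pytest.approx(expected)
            assert min(pre, rec) - 1e-12 <= f1(c) <= max(pre, rec) + 1e-12


class TestAUC:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.9, 0.8]
        labels = [NEGATIVE_LABEL, NEGATIVE_LABEL, POSITIVE_LABEL, POSITIVE_LABEL]
        assert auc(scores, labels) == 1.0

    def test_all_ties(self):
        labels = [POSITIVE_LABEL, NEGATIVE_LABEL] * 3
        assert auc(np.ones(6), labels) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.2], [POSITIVE_LABEL, POSITIVE_LABEL])

    @given(
        st.lists(st.integers(0, 5), min_size=6, max_size=12),
        st.lists(st.booleans(), min_size=6, max_size=12),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_pair_oracle(self, raw_scores, raw_labels):
        m = min(len(raw_scores), len(raw_labels))
        scores = [float(s) for s in raw_scores[:m]]
        labels = [POSITIVE_LABEL if b else NEGATIVE_LABEL for b in raw_labels[:m]]
        if len(set(labels)) < 2:
            return
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=20)
        labels = [POSITIVE_LABEL if i % 3 else NEGATIVE_LABEL for i in range(20)]
        base = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(base)
        assert auc(3 * scores - 7, labels) == pytest.approx(base)


class TestMakeClassifier:
    def test_unknown_name_lists_options(self):
        with pytest.raises(ValueError, match="LDA"):
            make_classifier("RandomForest")

    def test_lda_separates_blobs(self):
        table = blob_table(sep=4.0)
        report = split_evaluate(table, "LDA", train_fraction=0.8, seed=0)
        assert report.test_accuracy > 0.95

    def test_knn1_memorizes_training_set(self):
        table = blob_table(n_per_class=20, sep=1.0)
        model = make_classifier("KNN", n_neighbors=1)
        model.fit(table.X, table.labels)
        assert np.mean(model.predict(table.X) == table.labels) == 1.0

    def test_boosted_tree_seeded_determinism(self):
        table = blob_table(sep=1.0)
        preds = []
        for _ in range(2):
            model = make_classifier("BoostedTree", seed=3)
            model.fit(table.X, table.labels)
            preds.append(model.predict(table.X))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestSplitEvaluate:
    def test_stratification_within_one_row(self):
        table = blob_table(n_per_class=51)
        report = split_evaluate(table, "LDA", train_fraction=0.8, seed=0)
        test_total = report.counts.total
        test_pos = report.counts.tp + report.counts.fn
        assert abs(test_pos - test_total / 2) <= 1

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_evaluate(blob_table(), "LDA", train_fraction=1.5)


class TestKFoldEvaluate:
    def test_pooled_counts_cover_table(self):
        table = blob_table(n_per_class=50)
        report = kfold_evaluate(table, "NB", k=5, seed=0)
        assert report.counts.total == len(table)
        assert len(report.folds) == 5

    def test_fold_sizes_balanced(self):
        table = blob_table(n_per_class=50)  # 100 rows
        report = kfold_evaluate(table, "LDA", k=5, seed=1)
        for fold in report.folds:
            assert abs(fold.counts.total - 20) <= 1


class TestLosoEvaluate:
    def test_fold_per_subject(self):
        table = blob_table(n_subjects=7)
        report = loso_evaluate(table, "LDA")
        assert len(report.folds) == 14  # 7 per class, distinct prefixes

    def test_no_subject_leaks_across_fold(self):
        table = blob_table(n_subjects=3)
        subjects = sorted(set(table.subject_ids))
        for subject in subjects:
            test_mask = table.subject_ids == subject
            train_subjects = set(table.subject_ids[~test_mask])
            assert subject not in train_subjects

    def test_single_subject_rejected(self):
        table = blob_table(n_per_class=10, n_subjects=1)
        single = LabeledFeatureTable(
            table.features, table.labels, np.array(["s1"] * len(table), dtype=object)
        )
        with pytest.raises(ValueError, match="2 distinct subjects"):
            loso_evaluate(single, "LDA")

    def test_single_class_fold_auc_is_none_but_counted(self):
        table = blob_table(n_per_class=20, n_subjects=2, sep=3.0)
        report = loso_evaluate(table, "LDA")
        # every test fold is one subject = one class: per-fold AUC undefined
        assert all(f.auc is None for f in report.folds)
        assert report.counts.total == len(table)

    def test_report_dict_round_trips_metrics(self):
        table = blob_table(n_per_class=30, n_subjects=3)
        report = loso_evaluate(table, "NB")
        d = report.to_dict()
        pooled = ConfusionCounts(**d["counts"])
        assert d["test_pct"] == pytest.approx(100.0 * accuracy(pooled))


class TestLabeledFeatureTable:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LabeledFeatureTable(
                pd.DataFrame({"a": [1.0, 2.0]}),
                np.array([POSITIVE_LABEL]),
                np.array(["s1", "s2"], dtype=object),
            )

    def test_empty_subjects_rejected_by_loso(self):
        table = blob_table(n_per_class=10, n_subjects=2)
        blanked = LabeledFeatureTable(
            table.features, table.labels, np.array([""] * len(table), dtype=object)
        )
        with pytest.raises(ValueError, match="subject_id"):
            loso_evaluate(blanked, "LDA")

    def test_csv_round_trip(self, tmp_path):
        table = blob_table(n_per_class=5)
        path = tmp_path / "features.csv"
        table.to_csv(str(path))
        again = LabeledFeatureTable.from_csv(str(path))
        np.testing.assert_allclose(again.X, table.X)
        assert list(again.labels) == list(table.labels)
        assert list(again.subject_ids) == list(table.subject_ids)
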