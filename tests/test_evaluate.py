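import numpy as np
import pytest

from hemidiff.evaluate import (AblationSpec, compute_metrics, group_split,
                               run_ablation, subject_split)
from hemidiff.preprocess import MI_CLASSES

from oracles import auc_trapezoid, metrics_from_counts


def probs_for_predictions(preds, classes=MI_CLASSES, confidence=0.9):
    """Deterministic simplex rows whose argmax is the given prediction."""
    out = np.full((len(preds), len(classes)),
                  (1.0 - confidence) / (len(classes) - 1))
    for i, p in enumerate(preds):
        out[i, classes.index(p)] = confidence
    return out


class TestSubjectSplit:
    def test_stratified_90_10_of_84_trials(self):
        labels = np.repeat(MI_CLASSES, 21)
        plan = subject_split(labels, fraction=0.9, seed=0)
        assert len(plan.train_indices) == 76
        assert len(plan.test_indices) == 8
        for cls in MI_CLASSES:
            test_count = np.sum(labels[plan.test_indices] == cls)
            assert test_count == 2  # round(0.1 * 21)

    def test_partition_is_exact(self):
        labels = np.repeat(MI_CLASSES, 21)
        plan = subject_split(labels, seed=3)
        union = np.sort(np.concatenate([plan.train_indices,
                                        plan.test_indices]))
        np.testing.assert_array_equal(union, np.arange(84))

    def test_deterministic_under_seed(self):
        labels = np.repeat(MI_CLASSES, 21)
        a = subject_split(labels, seed=9)
        b = subject_split(labels, seed=9)
        np.testing.assert_array_equal(a.test_indices, b.test_indices)

    def test_degenerate_fractions_rejected(self):
        labels = np.repeat(MI_CLASSES, 21)
        with pytest.raises(ValueError, match="strictly between"):
            subject_split(labels, fraction=1.0)

    def test_tiny_class_rejected(self):
        labels = np.array(["T1"] * 12 + ["T2"])
        with pytest.raises(ValueError, match="fewer than 2"):
            subject_split(labels)


class TestGroupSplit:
    def test_near_equal_parts_of_84(self):
        subjects = np.repeat(np.arange(2), 84)
        plan = group_split(subjects, folds=10, seed=0)
        for sizes in plan.detail["part_sizes"].values():
            assert sum(sizes) == 84
            assert max(sizes) - min(sizes) <= 1

    def test_partition_and_per_subject_test_share(self):
        subjects = np.repeat(np.arange(3), 84)
        plan = group_split(subjects, folds=10, seed=1)
        union = np.sort(np.concatenate([plan.train_indices,
                                        plan.test_indices]))
        np.testing.assert_array_equal(union, np.arange(3 * 84))
        for s in range(3):
            n_test = np.sum(subjects[plan.test_indices] == s)
            assert n_test in (8, 9)  # one near-equal part per subject

    def test_deterministic_under_seed(self):
        subjects = np.repeat(np.arange(2), 30)
        a = group_split(subjects, folds=10, seed=4)
        b = group_split(subjects, folds=10, seed=4)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    def test_too_few_folds_or_trials_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            group_split(np.zeros(20), folds=1)
        with pytest.raises(ValueError, match="fewer than"):
            group_split(np.zeros(5), folds=10)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array(list(MI_CLASSES) * 5)
        report = compute_metrics(probs_for_predictions(y), y)
        assert report.accuracy == 1.0
        assert report.kappa == 1.0
        assert report.f1 == 1.0
        assert report.auc == 1.0
        assert np.trace(report.confusion) == 20

    def test_metrics_match_first_principles_oracle(self, rng):
        y_true = rng.choice(MI_CLASSES, size=500)
        y_pred = np.where(rng.random(500) < 0.6, y_true,
                          rng.choice(MI_CLASSES, size=500))
        report = compute_metrics(probs_for_predictions(y_pred), y_true)
        expected = metrics_from_counts(report.confusion)
        assert report.accuracy == pytest.approx(expected["accuracy"], abs=1e-12)
        assert report.kappa == pytest.approx(expected["kappa"], abs=1e-12)
        assert report.precision == pytest.approx(expected["precision"], abs=1e-12)
        assert report.recall == pytest.approx(expected["recall"], abs=1e-12)
        assert report.f1 == pytest.approx(expected["f1"], abs=1e-12)

    def test_auc_matches_trapezoid_oracle(self, rng):
        y_true = rng.choice(MI_CLASSES, size=200)
        raw = rng.random((200, 4))
        probs = raw / raw.sum(axis=1, keepdims=True)
        report = compute_metrics(probs, y_true)
        expected = np.mean([
            auc_trapezoid((y_true == cls).astype(int), probs[:, k])
            for k, cls in enumerate(MI_CLASSES)
        ])
        assert report.auc == pytest.approx(expected, abs=1e-12)

    def test_random_predictions_have_zero_kappa(self, rng):
        n = 10_000
        y_true = rng.choice(MI_CLASSES, size=n)
        y_pred = rng.choice(MI_CLASSES, size=n)  # independent of truth
        report = compute_metrics(probs_for_predictions(y_pred), y_true)
        assert abs(report.kappa) < 0.05

    def test_two_class_block_confusion(self):
        y = np.array(["T1"] * 5 + ["T2"] * 5)
        report = compute_metrics(probs_for_predictions(y), y)
        assert report.accuracy == 1.0
        assert report.confusion[0, 0] == 5 and report.confusion[1, 1] == 5

    def test_mass_conservation(self, rng):
        y_true = rng.choice(MI_CLASSES, size=123)
        y_pred = rng.choice(MI_CLASSES, size=123)
        report = compute_metrics(probs_for_predictions(y_pred), y_true)
        assert report.confusion.sum() == 123

    def test_kappa_one_iff_diagonal(self):
        y = np.array(list(MI_CLASSES) * 3)
        perfect = compute_metrics(probs_for_predictions(y), y)
        assert perfect.kappa == 1.0
        wrong = np.roll(y, 1)
        imperfect = compute_metrics(probs_for_predictions(wrong), y)
        assert imperfect.kappa < 1.0

    def test_invalid_inputs_rejected(self):
        y = np.array(["T1", "T5"])
        with pytest.raises(ValueError, match="labels outside"):
            compute_metrics(np.full((2, 4), 0.25), y)
        with pytest.raises(ValueError, match="simplex"):
            compute_metrics(np.full((2, 4), 0.3), np.array(["T1", "T2"]))


class TestAblation:
    def test_four_variants_on_easy_data(self, rng):
        """All four dropout/BN variants must beat chance on separable data."""
        from hemidiff.evaluate import subject_split
        t = np.arange(640) / 160.0
        X, y = [], []
        for k, cls in enumerate(MI_CLASSES):
            tone = np.sin(2 * np.pi * (8.0 + 5.0 * k) * t)[:, None]
            for _ in range(12):
                trial = 0.2 * rng.standard_normal((1280, 9))
                trial[:640] += 1.5 * tone
                trial[640:] += (1.5 if k % 2 else -1.5) * tone
                X.append(trial)
                y.append(cls)
        X, y = np.asarray(X, dtype=np.float32), np.asarray(y)
        split = subject_split(y, fraction=0.75, seed=0)
        reports = run_ablation(
            X, y, split,
            base_params={"n_iter": 80, "batch_size": 16, "random_state": 0})
        assert set(reports) == {"full", "no_dropout", "no_batchnorm", "neither"}
        for name, report in reports.items():
            assert report.accuracy > 0.5, name

    def test_requires_all_classes(self, rng):
        X = rng.normal(size=(10, 1280, 9))
        y = np.array(["T1", "T2"] * 5)
        split = subject_split(np.repeat(MI_CLASSES, 3), seed=0)
        with pytest.raises(ValueError, match="all four"):
            run_ablation(X, y, split)

    def test_spec_lists_four_variants(self):
        spec = AblationSpec()
        assert len(spec.variants) == 4
        flags = {(d, b) for _, d, b in spec.variants}
        assert flags == {(True, True), (False, True), (True, False),
                         (False, False)}
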