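import numpy as np
import pytest

from hemidiff.dualcnn import (ArchitectureConfig, DualCNNClassifier,
                              TrainingConfig, build_model, forward,
                              shape_propagate, train)

TABLE_SHAPES = [
    ("Input", ((640, 9), (640, 9))),
    ("Conv1", (630, 1, 25)),
    ("Pool1", (210, 1, 25)),
    ("Conv2", (200, 1, 50)),
    ("Pool2", (66, 1, 50)),
    ("Conv3", (56, 1, 100)),
    ("Pool3", (18, 1, 100)),
    ("Conv4", (8, 1, 200)),
    ("Pool4", (4, 1, 200)),
    ("Flatten", (800,)),
    ("Difference", (800,)),
    ("FC", (128,)),
    ("Softmax", (4,)),
]


def separable_trials(rng, n_per_class=20, classes=("T1", "T2")):
    """Strongly separable synthetic inputs: distinct tones per class."""
    t = np.arange(640) / 160.0
    X, y = [], []
    for k, cls in enumerate(classes):
        tone = np.sin(2 * np.pi * (10.0 + 6.0 * k) * t)
        for _ in range(n_per_class):
            trial = 0.3 * rng.standard_normal((1280, 9))
            half = slice(0, 640) if k % 2 == 0 else slice(640, 1280)
            trial[half, :] += 2.0 * tone[:, None]
            X.append(trial)
            y.append(cls)
    order = rng.permutation(len(X))
    return np.asarray(X, dtype=np.float32)[order], np.asarray(y)[order]


class TestShapePropagate:
    def test_default_architecture_shape_table(self):
        assert shape_propagate(ArchitectureConfig()) == TABLE_SHAPES

    def test_kernel_spanning_input_collapses_to_one(self):
        cfg = ArchitectureConfig(input_shape=(20, 4), conv_maps=(3,),
                                 conv_kernels=((10, 4),), pool_sizes=((1, 1),))
        shapes = dict(shape_propagate(cfg))
        assert shapes["Conv1"] == (1, 1, 3)

    def test_collapsed_dimension_names_layer(self):
        cfg = ArchitectureConfig(input_shape=(40, 9), conv_maps=(3, 3),
                                 conv_kernels=((11, 9), (11, 1)),
                                 pool_sizes=((1, 1), (1, 1)))
        with pytest.raises(ValueError, match="Conv2"):
            shape_propagate(cfg)


class TestBuildModel:
    def test_shared_mode_aliases_parameters(self):
        cfg = ArchitectureConfig(weight_sharing="shared")
        model = build_model(cfg, seed=0)
        conv_l = model.branch_left[0]
        conv_r = model.branch_right[0]
        assert conv_l.w is conv_r.w  # one and the same array
        conv_l.w[0, 0, 0, 0] = 123.0
        assert conv_r.w[0, 0, 0, 0] == 123.0

    def test_independent_mode_same_init_different_objects(self):
        model = build_model(ArchitectureConfig(), seed=0)
        conv_l, conv_r = model.branch_left[0], model.branch_right[0]
        assert conv_l.w is not conv_r.w
        np.testing.assert_array_equal(conv_l.w, conv_r.w)
        conv_l.w += 1.0
        assert not np.array_equal(conv_l.w, conv_r.w)

    def test_fc_weight_count(self):
        model = build_model(ArchitectureConfig(), seed=0)
        assert model.fc.w.shape == (800, 128)
        assert model.fc.w.size == 800 * 128

    def test_deterministic_initialization(self):
        a = build_model(ArchitectureConfig(), seed=5)
        b = build_model(ArchitectureConfig(), seed=5)
        for (_, pa, _), (_, pb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError, match="dropout_rate"):
            ArchitectureConfig(dropout_rate=1.0)


class TestForward:
    def test_output_on_probability_simplex(self, rng):
        model = build_model(ArchitectureConfig(), seed=0)
        x = rng.standard_normal((3, 1280, 9)).astype(np.float32)
        probs = forward(model, x)
        assert probs.shape == (3, 4)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_head_gives_uniform_probabilities(self, rng):
        model = build_model(ArchitectureConfig(), seed=0)
        model.out.w[...] = 0.0
        model.out.b[...] = 0.0
        probs = forward(model, rng.standard_normal((2, 1280, 9)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-7)

    def test_identical_branch_inputs_zero_difference(self, rng):
        model = build_model(ArchitectureConfig(weight_sharing="shared"),
                            seed=0)
        half = rng.standard_normal((640, 9)).astype(np.float32)
        x = np.concatenate([half, half], axis=0)
        diff = model.difference_features(x, train=False)
        np.testing.assert_array_equal(diff, 0.0)

    def test_branch_swap_negates_difference(self, rng):
        model = build_model(ArchitectureConfig(weight_sharing="shared"),
                            seed=1)
        a = rng.standard_normal((640, 9)).astype(np.float32)
        b = rng.standard_normal((640, 9)).astype(np.float32)
        d_ab = model.difference_features(np.concatenate([a, b]), train=False)
        d_ba = model.difference_features(np.concatenate([b, a]), train=False)
        assert np.max(np.abs(d_ab + d_ba)) < 1e-5

    def test_wrong_shape_rejected(self, rng):
        model = build_model(ArchitectureConfig(), seed=0)
        with pytest.raises(ValueError, match="expected input shape"):
            model.forward(rng.standard_normal((2, 640, 9)))


class TestTrain:
    def test_initial_loss_near_chance_level(self, rng):
        """Near-zero-mean init: first-batch loss ~ ln 4 for 4 classes."""
        X = rng.standard_normal((16, 1280, 9)).astype(np.float32)
        y = np.array(["T1", "T2", "T3", "T4"] * 4)
        model = build_model(ArchitectureConfig(), seed=0)
        trained = train(model, (X, y), None,
                        TrainingConfig(iterations=1, seed=0))
        assert trained.history["train_loss"][0] == pytest.approx(
            np.log(4.0), abs=0.15)

    def test_separable_data_reaches_perfect_training_accuracy(self, rng):
        X, y = separable_trials(rng)
        model = build_model(ArchitectureConfig(), seed=0)
        trained = train(model, (X, y), None,
                        TrainingConfig(iterations=200, seed=0))
        assert max(trained.history["train_acc"]) == 1.0

    def test_history_length_equals_iterations(self, rng):
        X, y = separable_trials(rng, n_per_class=8)
        model = build_model(ArchitectureConfig(), seed=0)
        trained = train(model, (X, y), (X[:4], y[:4]),
                        TrainingConfig(iterations=7, seed=0))
        for key in ("train_loss", "train_acc", "test_loss", "test_acc"):
            assert len(trained.history[key]) == 7

    def test_training_is_deterministic(self, rng):
        X, y = separable_trials(rng, n_per_class=6)
        runs = []
        for _ in range(2):
            model = build_model(ArchitectureConfig(), seed=3)
            trained = train(model, (X, y), None,
                            TrainingConfig(iterations=5, seed=3))
            runs.append(trained.history["train_loss"])
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_empty_or_single_class_rejected(self, rng):
        model = build_model(ArchitectureConfig(), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, (np.empty((0, 1280, 9)), np.array([])), None)
        X = rng.standard_normal((4, 1280, 9))
        with pytest.raises(ValueError, match="2 classes"):
            train(model, (X, np.array(["T1"] * 4)), None)


class TestClassifierEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        clf = DualCNNClassifier(n_iter=3)
        params = clf.get_params()
        assert params["n_iter"] == 3
        clone(clf)  # must be clonable from constructor params

    def test_fit_predict_on_separable_data(self, rng):
        X, y = separable_trials(rng, n_per_class=12)
        clf = DualCNNClassifier(n_iter=60, batch_size=16, random_state=0)
        clf.fit(X[:20], y[:20])
        assert set(clf.classes_) == set(y)
        acc = clf.score(X[20:], y[20:])
        assert acc >= 0.75
        probs = clf.predict_proba(X[20:])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_flat_input_accepted(self, rng):
        X, y = separable_trials(rng, n_per_class=4)
        clf = DualCNNClassifier(n_iter=2, random_state=0)
        clf.fit(X.reshape(len(X), -1), y)
        assert clf.predict(X[:2].reshape(2, -1)).shape == (2,)
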