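"""Dual-branch CNN with a hemispheric feature-difference layer.

The assembled 1280 x 9 trial is reshaped into two 640 x 9 arrays holding the
nine left- and nine right-hemisphere scout series.  Each branch runs four
valid (unpadded, stride-1) convolutions, each followed by max pooling with
floor division, giving per-branch feature maps

    640x9 -conv 11x9,25-> 630x1x25 -pool 3x1-> 210x1x25
          -conv 11x1,50-> 200x1x50 -pool 3x1->  66x1x50
          -conv 11x1,100-> 56x1x100 -pool 3x1-> 18x1x100
          -conv 11x1,200->  8x1x200 -pool 2x1->  4x1x200 -flatten-> 800.

The two 800-vectors are subtracted elementwise (the hemispheric difference),
passed through a 128-unit fully connected layer and a 4-way softmax.  Batch
normalisation sits after each convolution (before the ReLU) and spatial
dropout after each pooling stage; both are ablatable.  Branches default to
independent parameters; a shared mode binds both branches to one parameter
set, which makes the difference features exactly antisymmetric under branch
swap in evaluation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .scouts import split_branches

__all__ = [
    "LayerSpec",
    "ArchitectureConfig",
    "TrainingConfig",
    "TrainedModel",
    "shape_propagate",
    "build_model",
    "forward",
    "train",
    "DualCNN",
    "DualCNNClassifier",
]


@dataclass(frozen=True)
class LayerSpec:
    """One architectural layer: kind plus the extents that define it."""

    kind: str  # input | conv | pool | flatten | difference | fc | softmax
    maps: int = 1
    kernel: tuple[int, int] | None = None
    pool: tuple[int, int] | None = None
    activation: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "conv" and (self.kernel is None
                                    or min(self.kernel) < 1):
            raise ValueError("conv layer needs a positive kernel extent")
        if self.kind == "pool" and (self.pool is None or min(self.pool) < 1):
            raise ValueError("pool layer needs a positive pool extent")


@dataclass(frozen=True)
class ArchitectureConfig:
    """The dual-branch architecture; defaults reproduce the reference shapes."""

    input_shape: tuple[int, int] = (1280, 9)
    conv_maps: tuple[int, ...] = (25, 50, 100, 200)
    conv_kernels: tuple[tuple[int, int], ...] = ((11, 9), (11, 1), (11, 1), (11, 1))
    pool_sizes: tuple[tuple[int, int], ...] = ((3, 1), (3, 1), (3, 1), (2, 1))
    fc_units: int = 128
    n_classes: int = 4
    weight_sharing: str = "independent"  # or "shared"
    dropout_rate: float = 0.3
    use_spatial_dropout: bool = True
    use_batchnorm: bool = True

    def __post_init__(self) -> None:
        if not (len(self.conv_maps) == len(self.conv_kernels)
                == len(self.pool_sizes)):
            raise ValueError("conv_maps, conv_kernels and pool_sizes must "
                             "have equal lengths")
        if self.weight_sharing not in ("independent", "shared"):
            raise ValueError(f"unknown weight_sharing {self.weight_sharing!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_shape[0] % 2 != 0:
            raise ValueError("input row count must be even (two branches)")

    def branch_layer_specs(self) -> list[LayerSpec]:
        specs = []
        for maps, kernel, pool in zip(self.conv_maps, self.conv_kernels,
                                      self.pool_sizes):
            specs.append(LayerSpec(kind="conv", maps=maps, kernel=kernel,
                                   activation="relu"))
            specs.append(LayerSpec(kind="pool", maps=maps, pool=pool))
        specs.append(LayerSpec(kind="flatten"))
        return specs


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; iterations count mini-batch updates."""

    loss: str = "categorical_crossentropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    iterations: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def shape_propagate(config: ArchitectureConfig) -> list[tuple[str, tuple]]:
    """Pure shape arithmetic through the architecture.

    Valid convolution: ``out = in - kernel + 1`` per spatial axis; max
    pooling: ``out = floor(in / pool)``.  Raises with the layer name if any
    intermediate extent collapses.
    """
    rows, cols = config.input_shape
    branch_in = (rows // 2, cols)
    shapes: list[tuple[str, tuple]] = [("Input", (branch_in, branch_in))]
    t, c, m = branch_in[0], branch_in[1], 1
    for i, (maps, kernel, pool) in enumerate(
            zip(config.conv_maps, config.conv_kernels, config.pool_sizes),
            start=1):
        t = t - kernel[0] + 1
        c = c - kernel[1] + 1
        m = maps
        if t <= 0 or c <= 0:
            raise ValueError(f"Conv{i}: non-positive output extent ({t}, {c})")
        shapes.append((f"Conv{i}", (t, c, m)))
        t //= pool[0]
        c //= pool[1]
        if t <= 0 or c <= 0:
            raise ValueError(f"Pool{i}: non-positive output extent ({t}, {c})")
        shapes.append((f"Pool{i}", (t, c, m)))
    flat = t * c * m
    shapes.append(("Flatten", (flat,)))
    shapes.append(("Difference", (flat,)))
    shapes.append(("FC", (config.fc_units,)))
    shapes.append(("Softmax", (config.n_classes,)))
    return shapes


class DualCNN:
    """The trainable model: two branch stacks, difference, FC head."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        shapes = shape_propagate(config)  # validates the arithmetic
        self.flat_dim = shapes[-3][1][0]
        init_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.branch_left = self._build_branch(init_rng)
        if config.weight_sharing == "shared":
            self.branch_right = [layer.sharing_copy()
                                 for layer in self.branch_left]
        else:
            # identical initialisation, independent parameters
            twin_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
            self.branch_right = self._build_branch(twin_rng)
        head_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        self.fc = nn.Dense(self.flat_dim, config.fc_units, head_rng)
        self.fc_act = nn.ReLU()
        self.out = nn.Dense(config.fc_units, config.n_classes, head_rng)
        # near-zero softmax head: the untrained model starts at chance level
        self.out.w *= 0.01

    def _build_branch(self, rng: np.random.Generator) -> list[nn.Layer]:
        cfg = self.config
        layers: list[nn.Layer] = []
        in_maps = 1
        for maps, kernel, pool in zip(cfg.conv_maps, cfg.conv_kernels,
                                      cfg.pool_sizes):
            layers.append(nn.Conv2D(kernel, in_maps, maps, rng))
            if cfg.use_batchnorm:
                layers.append(nn.BatchNorm(maps))
            layers.append(nn.ReLU())
            layers.append(nn.MaxPool(pool))
            if cfg.use_spatial_dropout and cfg.dropout_rate > 0:
                layers.append(nn.SpatialDropout(cfg.dropout_rate, self.rng))
            in_maps = maps
        layers.append(nn.Flatten())
        return layers

    # -- plumbing ---------------------------------------------------------

    def parameters(self):
        """Unique (name, value, grad) triples; shared arrays appear once."""
        seen: set[int] = set()
        out = []
        for layer in (*self.branch_left, *self.branch_right, self.fc,
                      self.fc_act, self.out):
            for name, p, g in layer.params():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append((name, p, g))
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities for a batch of assembled inputs."""
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"expected input shape {self.config.input_shape}, "
                f"got {x.shape[1:]}")
        left, right = split_branches(x)
        hl = left[..., None]   # (n, 640, 9, 1)
        hr = right[..., None]
        for layer in self.branch_left:
            hl = layer.forward(hl, train)
        for layer in self.branch_right:
            hr = layer.forward(hr, train)
        diff = hl - hr
        z = self.fc.forward(diff, train)
        z = self.fc_act.forward(z, train)
        logits = self.out.forward(z, train)
        probs = nn.softmax(logits)
        self._train_mode = train
        return probs[0] if squeeze else probs

    def difference_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """The post-subtraction 800-vector(s), for inspection and tests."""
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        left, right = split_branches(x)
        hl, hr = left[..., None], right[..., None]
        for layer in self.branch_left:
            hl = layer.forward(hl, train)
        for layer in self.branch_right:
            hr = layer.forward(hr, train)
        diff = hl - hr
        return diff[0] if squeeze else diff

    def backward(self, probs: np.ndarray, onehot: np.ndarray) -> None:
        """Accumulate gradients of the mean cross-entropy."""
        g = (probs - onehot).astype(np.float32) / probs.shape[0]
        g = self.out.backward(g)
        g = self.fc_act.backward(g)
        g = self.fc.backward(g)
        gl, gr = g, -g
        for layer in reversed(self.branch_left):
            gl = layer.backward(gl)
        for layer in reversed(self.branch_right):
            gr = layer.backward(gr)


@dataclass
class TrainedModel:
    """A fitted model plus its per-iteration learning curves."""

    model: DualCNN
    classes: tuple[str, ...]
    history: dict[str, list[float]] = field(default_factory=dict)

    def history_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.history)
        frame.insert(0, "iteration", np.arange(1, len(frame) + 1))
        return frame


def build_model(config: ArchitectureConfig, seed: int = 0) -> DualCNN:
    """Initialise a dual-branch model; deterministic under fixed seed."""
    return DualCNN(config, seed=seed)


def forward(model: DualCNN, x: np.ndarray) -> np.ndarray:
    """Evaluation-mode class probabilities for one trial or a batch."""
    return model.forward(x, train=False)


def _encode(labels, classes: tuple[str, ...], width: int | None = None) -> np.ndarray:
    """One-hot rows; ``width`` pads extra columns for unused model outputs."""
    index = {c: i for i, c in enumerate(classes)}
    try:
        y = np.array([index[l] for l in labels])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in classes {classes}") from exc
    onehot = np.zeros((len(y), width or len(classes)), dtype=np.float32)
    onehot[np.arange(len(y)), y] = 1.0
    return onehot


def train(
    model: DualCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    test_set: tuple[np.ndarray, np.ndarray] | None,
    tcfg: TrainingConfig | None = None,
) -> TrainedModel:
    """Mini-batch cross-entropy training with Adam.

    ``train_set``/``test_set`` are ``(inputs, labels)`` pairs of assembled
    trials and string labels.  The history records, per iteration, the loss
    and accuracy of the training mini-batch (before the update) and of the
    full test set in evaluation mode.
    """
    if tcfg is None:
        tcfg = TrainingConfig()
    X, y = train_set
    X = np.asarray(X, dtype=np.float32)
    if len(X) == 0:
        raise ValueError("training set is empty")
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    width = model.config.n_classes
    if len(classes) > width:
        raise ValueError(
            f"{len(classes)} classes but the model has {width} outputs")
    onehot = _encode(y, classes, width)
    has_test = test_set is not None and len(test_set[0]) > 0
    if has_test:
        Xt = np.asarray(test_set[0], dtype=np.float32)
        onehot_t = _encode(test_set[1], classes, width)
    rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 3]))
    optimizer = nn.Adam(model.parameters(), lr=tcfg.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "test_loss": [], "test_acc": []}
    batch = min(tcfg.batch_size, len(X))
    for _ in range(tcfg.iterations):
        idx = rng.choice(len(X), size=batch, replace=False)
        probs = model.forward(X[idx], train=True)
        history["train_loss"].append(nn.cross_entropy(probs, onehot[idx]))
        history["train_acc"].append(float(np.mean(
            probs.argmax(axis=1) == onehot[idx].argmax(axis=1))))
        optimizer.zero_grad()
        model.backward(probs, onehot[idx])
        optimizer.step()
        if has_test:
            probs_t = model.forward(Xt, train=False)
            history["test_loss"].append(nn.cross_entropy(probs_t, onehot_t))
            history["test_acc"].append(float(np.mean(
                probs_t.argmax(axis=1) == onehot_t.argmax(axis=1))))
        else:
            history["test_loss"].append(np.nan)
            history["test_acc"].append(np.nan)
    return TrainedModel(model=model, classes=classes, history=history)


class DualCNNClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper: fit/predict on assembled 1280 x 9 trials.

    Accepts inputs as (n, 1280, 9) arrays or flattened (n, 11520) rows.
    Columns are standardised with training-set statistics before entering
    the network.
    """

    def __init__(self, weight_sharing: str = "independent",
                 dropout_rate: float = 0.3, use_spatial_dropout: bool = True,
                 use_batchnorm: bool = True, learning_rate: float = 1e-3,
                 batch_size: int = 32, n_iter: int = 600,
                 standardize: bool = True, random_state: int = 0):
        self.weight_sharing = weight_sharing
        self.dropout_rate = dropout_rate
        self.use_spatial_dropout = use_spatial_dropout
        self.use_batchnorm = use_batchnorm
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_iter = n_iter
        self.standardize = standardize
        self.random_state = random_state

    def _coerce(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X.reshape(len(X), 1280, 9)
        if X.ndim != 3:
            raise ValueError("X must be (n, 1280, 9) or (n, 11520)")
        return X

    def fit(self, X, y, eval_set: tuple | None = None):
        X = self._coerce(X)
        y = np.asarray(y).astype(str)
        self.classes_ = np.unique(y)
        if self.standardize:
            self.mean_ = X.mean(axis=(0, 1), keepdims=True)
            self.scale_ = X.std(axis=(0, 1), keepdims=True) + 1e-12
        else:
            self.mean_, self.scale_ = 0.0, 1.0
        Xs = (X - self.mean_) / self.scale_
        config = ArchitectureConfig(
            input_shape=tuple(X.shape[1:]),
            n_classes=len(self.classes_),
            weight_sharing=self.weight_sharing,
            dropout_rate=self.dropout_rate,
            use_spatial_dropout=self.use_spatial_dropout,
            use_batchnorm=self.use_batchnorm,
        )
        self.architecture_ = config
        model = build_model(config, seed=self.random_state)
        tcfg = TrainingConfig(learning_rate=self.learning_rate,
                              batch_size=self.batch_size,
                              iterations=self.n_iter,
                              seed=self.random_state)
        if eval_set is not None:
            Xe = (self._coerce(eval_set[0]) - self.mean_) / self.scale_
            eval_pair = (Xe, np.asarray(eval_set[1]).astype(str))
        else:
            eval_pair = None
        trained = train(model, (Xs, y), eval_pair, tcfg)
        self.model_ = trained.model
        self.history_ = trained.history
        self.train_classes_ = trained.classes
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        Xs = (self._coerce(X) - self.mean_) / self.scale_
        probs = self.model_.forward(Xs, train=False)
        # align training-class order with self.classes_
        order = [self.train_classes_.index(c) for c in self.classes_]
        return probs[:, order]

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
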