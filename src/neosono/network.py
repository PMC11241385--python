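"""The composite-image CNN classifier and the data-splitting protocol.

The architecture is a compact feature extractor of three conv blocks
(Conv 3x3 same-padded -> BatchNorm -> ReLU -> MaxPool 2x2 stride 2) with
16/32/64 channels, a fourth conv block without pooling at 128 channels,
and a 3-way dense softmax head. On a 100 x 100 x 3 input the feature maps
shrink 100 -> 50 -> 25 -> 12 (floor division at each pool); roughly 150k
trainable weights, comfortably CPU-scale.

Training is minibatch RMSProp on categorical cross-entropy with seeded
He initialisation, fully deterministic for a fixed ``random_state``.
The data protocol is a stratified 70/15/15 train/validation/test split
plus stratified 5-fold cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .evaluation import EvaluationReport, evaluate_predictions, cv_aggregate

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "build_network",
    "layer_shapes",
    "split_dataset",
    "CompositeCNNClassifier",
    "crossvalidate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters (defaults give the reference model)."""

    input_height: int = 100
    input_width: int = 100
    input_channels: int = 3
    block_channels: tuple[int, ...] = (16, 32, 64)
    head_channels: int = 128
    kernel_size: int = 3
    pool_size: int = 2
    pool_stride: int = 2
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same padding)")
        if self.pool_size != self.pool_stride:
            raise ValueError("pooling uses non-overlapping windows")
        if any(c < 1 for c in self.block_channels) or self.head_channels < 1:
            raise ValueError("channel counts must be positive")

    def spatial_sizes(self) -> list[tuple[int, int]]:
        """Feature-map sides after the input and each pooling stage."""
        h, w = self.input_height, self.input_width
        sizes = [(h, w)]
        for _ in self.block_channels:
            h, w = h // self.pool_stride, w // self.pool_stride
            sizes.append((h, w))
        return sizes


@dataclass
class TrainingConfig:
    """Optimisation settings: RMSProp on categorical cross-entropy."""

    learning_rate: float = 1e-3
    decay: float = 0.9
    epsilon: float = 1e-8
    max_epochs: int = 200
    batch_size: int = 16
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def layer_shapes(cfg: NetworkConfig = NetworkConfig()) -> list[tuple[str, tuple]]:
    """Named per-layer output shapes, (height, width, channels)."""
    shapes: list[tuple[str, tuple]] = [
        ("Input", (cfg.input_height, cfg.input_width, cfg.input_channels))
    ]
    h, w = cfg.input_height, cfg.input_width
    for i, ch in enumerate(cfg.block_channels, start=1):
        shapes.append((f"Conv{i}", (h, w, ch)))
        shapes.append((f"BatchNorm{i}", (h, w, ch)))
        shapes.append((f"ReLU{i}", (h, w, ch)))
        h, w = h // cfg.pool_stride, w // cfg.pool_stride
        shapes.append((f"MaxPool{i}", (h, w, ch)))
    i = len(cfg.block_channels) + 1
    shapes.append((f"Conv{i}", (h, w, cfg.head_channels)))
    shapes.append((f"BatchNorm{i}", (h, w, cfg.head_channels)))
    shapes.append((f"ReLU{i}", (h, w, cfg.head_channels)))
    shapes.append(("FullyConnected", (1, 1, cfg.n_classes)))
    shapes.append(("Softmax", (1, 1, cfg.n_classes)))
    return shapes


def build_network(cfg: NetworkConfig = NetworkConfig(),
                  rng: np.random.Generator | None = None) -> _nn.Network:
    """Assemble the untrained layer stack with seeded He initialisation."""
    rng = rng if rng is not None else np.random.default_rng(0)
    layers: list[_nn.Layer] = []
    c_in = cfg.input_channels
    for ch in cfg.block_channels:
        layers.append(_nn.Conv2D(cfg.kernel_size, c_in, ch, rng))
        layers.append(_nn.BatchNorm2D(ch))
        layers.append(_nn.ReLU())
        layers.append(_nn.MaxPool2D(cfg.pool_size, cfg.pool_stride))
        c_in = ch
    layers.append(_nn.Conv2D(cfg.kernel_size, c_in, cfg.head_channels, rng))
    layers.append(_nn.BatchNorm2D(cfg.head_channels))
    layers.append(_nn.ReLU())
    layers.append(_nn.Flatten())
    h, w = cfg.spatial_sizes()[-1]
    layers.append(_nn.Dense(h * w * cfg.head_channels, cfg.n_classes, rng))
    return _nn.Network(layers)


def split_dataset(
    labels: Sequence,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test index split.

    Partitions are disjoint and exhaustive and reproducible for a fixed
    seed. Raises when a class is too small to appear in every nonempty
    partition.
    """
    y = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    f_train, f_val, f_test = fractions
    classes, counts = np.unique(y, return_counts=True)
    n_parts = sum(1 for f in fractions if f > 0)
    if np.any(counts < n_parts):
        small = classes[counts < n_parts]
        raise ValueError(
            f"classes {list(small)} have fewer samples than partitions"
        )
    idx = np.arange(len(y))
    if f_val + f_test == 0:
        return idx, np.array([], dtype=int), np.array([], dtype=int)
    train_idx, rest_idx = train_test_split(
        idx, test_size=f_val + f_test, stratify=y, random_state=seed
    )
    if f_test == 0:
        return np.sort(train_idx), np.sort(rest_idx), np.array([], dtype=int)
    if f_val == 0:
        return np.sort(train_idx), np.array([], dtype=int), np.sort(rest_idx)
    val_idx, test_idx = train_test_split(
        rest_idx,
        test_size=f_test / (f_val + f_test),
        stratify=y[rest_idx],
        random_state=seed + 1,
    )
    return np.sort(train_idx), np.sort(val_idx), np.sort(test_idx)


def _as_input(X: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    x = np.asarray(X)
    expected = (cfg.input_height, cfg.input_width, cfg.input_channels)
    if x.ndim != 4 or x.shape[1:] != expected:
        raise ValueError(f"expected input of shape (n, {expected}), got {x.shape}")
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return x.astype(np.float32)


class CompositeCNNClassifier(ClassifierMixin, BaseEstimator):
    """CNN over standardised two-ROI composites, scikit-learn style.

    ``X`` is ``(n, 100, 100, 3)`` uint8 (scaled to [0, 1] internally) or
    float already in [0, 1]; ``y`` holds class labels. Training runs
    minibatch RMSProp on categorical cross-entropy for at most
    ``max_epochs`` epochs and records per-epoch accuracy and loss in
    ``history_`` (validation columns appear when validation data is given).

    Parameters
    ----------
    learning_rate, decay, epsilon : float
        RMSProp settings; the step divides by the root of a decaying mean
        square gradient.
    max_epochs : int, default=200
        Upper bound on training epochs.
    batch_size : int, default=16
    config : NetworkConfig or None
        Architecture; None means the 100 x 100 x 3 reference model.
    random_state : int, default=0
        Seeds weight initialisation and minibatch shuffling; runs are
        bit-reproducible for a fixed value.
    """

    def __init__(
        self,
        learning_rate: float = 1e-3,
        decay: float = 0.9,
        epsilon: float = 1e-8,
        max_epochs: int = 200,
        batch_size: int = 16,
        config: NetworkConfig | None = None,
        random_state: int = 0,
    ):
        self.learning_rate = learning_rate
        self.decay = decay
        self.epsilon = epsilon
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.config = config
        self.random_state = random_state

    def fit(self, X, y, validation=None):
        """Train; ``validation=(X_val, y_val)`` adds per-epoch val metrics."""
        cfg = self.config if self.config is not None else NetworkConfig()
        x = _as_input(X, cfg)
        y = np.asarray(y)
        if len(x) == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        if len(self.classes_) > cfg.n_classes:
            raise ValueError(
                f"{len(self.classes_)} classes exceed the {cfg.n_classes}-way head"
            )
        class_index = {c: i for i, c in enumerate(self.classes_)}
        onehot = np.zeros((len(y), cfg.n_classes), dtype=np.float32)
        for i, lbl in enumerate(y):
            onehot[i, class_index[lbl]] = 1.0

        rng = np.random.default_rng(self.random_state)
        net = build_network(cfg, rng)
        opt = _nn.RMSProp(
            net.params_grads(), lr=self.learning_rate,
            decay=self.decay, eps=self.epsilon,
        )

        x_val = y_val_idx = None
        if validation is not None:
            xv, yv = validation
            x_val = _as_input(xv, cfg)
            y_val_idx = np.asarray([class_index[lbl] for lbl in np.asarray(yv)])

        hist: dict[str, list] = {"epoch": [], "train_loss": [], "train_acc": []}
        if x_val is not None:
            hist["val_loss"] = []
            hist["val_acc"] = []

        n = len(x)
        bs = min(self.batch_size, n)
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, bs):
                sel = order[start : start + bs]
                logits = net.forward(x[sel], train=True)
                loss, dlogits = _nn.softmax_cross_entropy(logits, onehot[sel])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                net.backward(dlogits)
                opt.step()
                losses.append(loss * len(sel))
                correct += int(
                    (logits.argmax(axis=1) == onehot[sel].argmax(axis=1)).sum()
                )
            hist["epoch"].append(epoch)
            hist["train_loss"].append(sum(losses) / n)
            hist["train_acc"].append(correct / n)
            if x_val is not None:
                v_logits = self._batched_forward(net, x_val)
                v_loss, _ = _nn.softmax_cross_entropy(
                    v_logits,
                    np.eye(cfg.n_classes, dtype=np.float32)[y_val_idx],
                )
                hist["val_loss"].append(v_loss)
                hist["val_acc"].append(
                    float((v_logits.argmax(axis=1) == y_val_idx).mean())
                )

        self.network_ = net
        self.config_ = cfg
        self.history_ = hist
        return self

    @staticmethod
    def _batched_forward(net, x, batch: int = 32) -> np.ndarray:
        outs = [
            net.forward(x[i : i + batch], train=False)
            for i in range(0, len(x), batch)
        ]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        x = _as_input(X, self.config_)
        logits = self._batched_forward(self.network_, x)
        proba = _nn.softmax(logits)[:, : len(self.classes_)]
        # renormalise in case fewer classes than head outputs were fitted
        return proba / proba.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]


def crossvalidate(
    estimator,
    X,
    y,
    k: int = 5,
    seed: int = 0,
    probabilities: bool = True,
) -> tuple[list[EvaluationReport], "pd.DataFrame"]:
    """Stratified k-fold evaluation: per-fold reports plus mean ± sd table.

    Each sample is tested exactly once. The estimator is cloned per fold;
    if it exposes ``random_state`` the fold index is folded into the seed
    so folds are independent yet reproducible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < k):
        raise ValueError(
            f"classes {list(classes[counts < k])} have fewer than {k} samples"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    class_names = tuple(classes)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        est = clone(estimator)
        if "random_state" in est.get_params():
            est.set_params(random_state=seed + 1000 + fold)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        proba = (
            est.predict_proba(X[te])
            if probabilities and hasattr(est, "predict_proba")
            else None
        )
        reports.append(
            evaluate_predictions(y[te], pred, class_names, probabilities=proba)
        )
    return reports, cv_aggregate(reports)


def save_checkpoint(clf: CompositeCNNClassifier, path: str | Path) -> None:
    """Serialise weights (npz) with a JSON sidecar of config and classes."""
    check_is_fitted(clf, "network_")
    path = Path(path)
    weights = clf.network_.get_weights()
    running = [
        (l.running_mean, l.running_var)
        for l in clf.network_.layers
        if isinstance(l, _nn.BatchNorm2D)
    ]
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    for i, (m, v) in enumerate(running):
        arrays[f"bn_mean{i}"] = m
        arrays[f"bn_var{i}"] = v
    np.savez(path, **arrays)
    sidecar = {
        "config": asdict(clf.config_),
        "classes": [str(c) for c in clf.classes_],
        "params": {
            k: v for k, v in clf.get_params().items() if k != "config"
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> CompositeCNNClassifier:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg_d = sidecar["config"]
    cfg_d["block_channels"] = tuple(cfg_d["block_channels"])
    cfg = NetworkConfig(**cfg_d)
    clf = CompositeCNNClassifier(config=cfg, **sidecar["params"])
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    net = build_network(cfg, np.random.default_rng(0))
    n_w = len(net.get_weights())
    net.set_weights([data[f"w{i}"] for i in range(n_w)])
    bn_layers = [l for l in net.layers if isinstance(l, _nn.BatchNorm2D)]
    for i, l in enumerate(bn_layers):
        l.running_mean = data[f"bn_mean{i}"]
        l.running_var = data[f"bn_var{i}"]
    clf.network_ = net
    clf.config_ = cfg
    clf.classes_ = np.asarray(sidecar["classes"], dtype=object)
    clf.history_ = {}
    return clf
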