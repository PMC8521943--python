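"""Slim CNN acoustic-scene classifier and its evaluation protocol.

Architecture: four convolutional blocks (3x3 kernels, filter counts 32, 64,
128, 256; each block is convolution -> batch normalisation -> ReLU -> 2x2 max
pooling) followed by a 280-unit fully connected layer with ReLU, 50 % dropout,
and a linear output layer with one unit per scene class (14 by default).

Training: Adam on categorical cross-entropy, mini-batches of 24, at most 250
epochs with patience-10 early stopping on the monitored loss.  Evaluation:
stratified random 70/30 train/test splits, repeated with fresh initialisation
(10 repetitions by default), reported as class-wise accuracies plus the mean
and standard deviation of the row-normalised confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "CnnArchitecture",
    "TrainingConfig",
    "EvaluationReport",
    "SceneCNN",
    "build_model",
    "split_dataset",
    "train",
    "evaluate",
    "repeated_experiment",
]


@dataclass(frozen=True)
class CnnArchitecture:
    """Hyperparameters of the slim scene-classification CNN."""

    conv_filters: tuple = (32, 64, 128, 256)
    fc1_width: int = 280
    dropout_rate: float = 0.5
    n_classes: int = 14

    def __post_init__(self):
        if len(self.conv_filters) < 1:
            raise ValueError("need at least one convolutional block")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation and evaluation protocol parameters."""

    learning_rate: float = 1e-3
    batch_size: int = 24
    max_epochs: int = 250
    patience: int = 10
    train_fraction: float = 0.70
    n_repetitions: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


@dataclass
class EvaluationReport:
    """Aggregate of repeated train/test runs."""

    per_class_accuracy: dict
    overall_accuracy: float
    confusion_mean: np.ndarray
    confusion_std: np.ndarray
    n_repetitions: int
    class_labels: list = field(default_factory=list)
    #: row-normalised confusion matrix of every repetition, shape (R, C, C)
    confusion_runs: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "per_class_accuracy": self.per_class_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "confusion_mean": self.confusion_mean.tolist(),
            "confusion_std": self.confusion_std.tolist(),
            "n_repetitions": self.n_repetitions,
            "class_labels": list(self.class_labels),
        }


class SceneCNN:
    """The classifier model: architecture + weights + input contract."""

    def __init__(self, arch: CnnArchitecture, input_shape: tuple, seed: int = 0, dtype=np.float32):
        H, W = input_shape
        min_side = 2 ** len(arch.conv_filters)
        if H < min_side or W < min_side:
            raise ValueError(
                f"input {input_shape} too small to survive {len(arch.conv_filters)} 2x2 poolings"
            )
        self.arch = arch
        self.input_shape = (int(H), int(W))
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        layers = []
        ch = 1
        h, w = H, W
        for f in arch.conv_filters:
            layers += [
                nn.Conv2D(ch, f, rng, dtype=dtype),
                nn.BatchNorm2D(f, dtype=dtype),
                nn.ReLU(),
                nn.MaxPool2x2(),
            ]
            ch = f
            h, w = h // 2, w // 2
        layers += [
            nn.Flatten(),
            nn.Dense(ch * h * w, arch.fc1_width, rng, dtype=dtype),
            nn.ReLU(),
            nn.Dropout(arch.dropout_rate, self._dropout_rng),
            nn.Dense(arch.fc1_width, arch.n_classes, rng, dtype=dtype),
        ]
        self.net = nn.Sequential(layers)

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2:] != self.input_shape:
            raise ValueError(f"expected input {self.input_shape}, got {x.shape[2:]}")
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Batch of (H, W) features -> batch of class score vectors."""
        return self.net.forward(self._prep(x), train=train)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x)
        out = [
            self.forward(x[i : i + batch_size], train=False).argmax(axis=1)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out) if out else np.array([], dtype=int)

    def parameter_count(self) -> int:
        return self.net.parameter_count()

    def save(self, path) -> None:
        """Opaque weights file + JSON sidecar with the architecture contract."""
        path = Path(path)
        params = self.net.params()
        np.savez(path.with_suffix(".npz"), *params)
        stats = [
            (l.running_mean, l.running_var)
            for l in self.net.layers
            if isinstance(l, nn.BatchNorm2D)
        ]
        np.savez(
            path.with_suffix(".bn.npz"), *[a for pair in stats for a in pair]
        )
        sidecar = {
            "conv_filters": list(self.arch.conv_filters),
            "fc1_width": self.arch.fc1_width,
            "dropout_rate": self.arch.dropout_rate,
            "n_classes": self.arch.n_classes,
            "input_shape": list(self.input_shape),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "SceneCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            CnnArchitecture(
                conv_filters=tuple(meta["conv_filters"]),
                fc1_width=meta["fc1_width"],
                dropout_rate=meta["dropout_rate"],
                n_classes=meta["n_classes"],
            ),
            tuple(meta["input_shape"]),
        )
        with np.load(path.with_suffix(".npz")) as data:
            for p, key in zip(model.net.params(), data.files):
                p[...] = data[key]
        with np.load(path.with_suffix(".bn.npz")) as data:
            bns = [l for l in model.net.layers if isinstance(l, nn.BatchNorm2D)]
            for i, l in enumerate(bns):
                l.running_mean[...] = data[data.files[2 * i]]
                l.running_var[...] = data[data.files[2 * i + 1]]
        return model


def build_model(
    arch: CnnArchitecture | None = None, input_shape: tuple = (64, 400), seed: int = 0
) -> SceneCNN:
    """Instantiate the default scene CNN for features of ``input_shape``."""
    return SceneCNN(arch or CnnArchitecture(), input_shape, seed=seed)


def split_dataset(labels, train_fraction: float = 0.70, seed: int = 0):
    """Stratified random train/test index split.

    The training partition holds ``round(train_fraction * n)`` records
    overall, allocated per class by largest-remainder rounding so the split is
    stratified; every class must contribute at least 2 records.  Deterministic
    given ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 records: {list(bad)}")
    n_train_total = int(round(train_fraction * n))
    quotas = train_fraction * counts
    base = np.floor(quotas).astype(int)
    base = np.clip(base, 1, counts - 1)  # both partitions see every class
    remainder = n_train_total - base.sum()
    order = np.argsort(-(quotas - np.floor(quotas)), kind="stable")
    for ci in order:
        if remainder <= 0:
            break
        if base[ci] < counts[ci] - 1:
            base[ci] += 1
            remainder -= 1
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls, k in zip(classes, base):
        idx = np.nonzero(labels == cls)[0]
        perm = rng.permutation(idx)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def train(
    model: SceneCNN,
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
    shuffle_seed: int | None = None,
) -> list:
    """Fit the model; returns the per-epoch monitored (training) loss history.

    Early stopping: training ends after ``patience`` consecutive epochs
    without improvement of the monitored loss over its running best, or at
    ``max_epochs``.
    """
    x = np.asarray(features)
    y = np.asarray(labels, dtype=int)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed if shuffle_seed is None else shuffle_seed)
    opt = nn.Adam(model.net.params(), lr=config.learning_rate)
    history: list[float] = []
    best = np.inf
    since_improve = 0
    for _epoch in range(config.max_epochs):
        perm = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), config.batch_size):
            bidx = perm[i : i + config.batch_size]
            logits = model.forward(x[bidx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[bidx])
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            model.net.backward(dlogits)
            opt.step(model.net.grads())
            losses.append(loss * len(bidx))
        epoch_loss = float(np.sum(losses) / len(x))
        history.append(epoch_loss)
        if epoch_loss < best:
            best = epoch_loss
            since_improve = 0
        else:
            since_improve += 1
        if since_improve >= config.patience:
            break
    return history


def evaluate(model: SceneCNN, features: np.ndarray, labels: np.ndarray):
    """Confusion counts and per-class accuracies on a held-out set."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty test set")
    C = model.arch.n_classes
    if y.min() < 0 or y.max() >= C:
        raise ValueError("test labels outside the model's class range")
    pred = model.predict(np.asarray(features))
    return confusion_and_accuracies(y, pred, C)


def confusion_and_accuracies(y_true, y_pred, n_classes: int):
    """Tally a confusion matrix (row = true class) and derive accuracies."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    row = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, np.diag(conf) / np.maximum(row, 1), np.nan)
    overall = float(np.trace(conf) / conf.sum())
    return conf, per_class, overall


def repeated_experiment(
    features: np.ndarray,
    labels: np.ndarray,
    arch: CnnArchitecture | None = None,
    config: TrainingConfig | None = None,
    class_labels: list | None = None,
) -> EvaluationReport:
    """The full protocol: repeat (fresh split, fresh init, train, test).

    Reports the element-wise mean and standard deviation of the
    row-normalised confusion matrices and the mean overall accuracy across
    repetitions.
    """
    config = config or TrainingConfig()
    arch = arch or CnnArchitecture()
    if config.n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    x = np.asarray(features)
    y = np.asarray(labels, dtype=int)
    C = arch.n_classes
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = [int(s % (2**31)) for s in ss.generate_state(3 * config.n_repetitions)]
    confusions, overalls, per_classes = [], [], []
    for rep in range(config.n_repetitions):
        split_seed, init_seed, shuffle_seed = rep_seeds[3 * rep : 3 * rep + 3]
        tr, te = split_dataset(y, config.train_fraction, seed=split_seed)
        model = SceneCNN(arch, x.shape[-2:], seed=init_seed)
        mu = x[tr].mean()
        sd = x[tr].std() + 1e-8
        train(model, (x[tr] - mu) / sd, y[tr], config, shuffle_seed=shuffle_seed)
        conf, per_class, overall = evaluate(model, (x[te] - mu) / sd, y[te])
        row = conf.sum(axis=1, keepdims=True)
        confusions.append(conf / np.maximum(row, 1))
        per_classes.append(per_class)
        overalls.append(overall)
    confusions = np.stack(confusions)
    per_class_mean = np.nanmean(np.stack(per_classes), axis=0)
    names = list(class_labels) if class_labels is not None else [str(i) for i in range(C)]
    return EvaluationReport(
        per_class_accuracy={names[i]: float(per_class_mean[i]) for i in range(C)},
        overall_accuracy=float(np.mean(overalls)),
        confusion_mean=confusions.mean(axis=0),
        confusion_std=confusions.std(axis=0),
        n_repetitions=config.n_repetitions,
        class_labels=names,
        confusion_runs=confusions,
    )
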