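"""The twelve classifier architectures, their training, and ensembling.

Every model consumes the 1396-length pair encoding reshaped either to a
37x37 single-channel matrix (image-style architectures) or to 37 timesteps
of 37 features (sequence architectures: RNN, BiRNN, Seq2Seq), and emits
two-class probabilities (DOWN, UP) via a softmax head.  Training is Adam
on two-class cross-entropy (learning rate 1e-3, batch size 100) with early
stopping on the validation AUC.  Ensembles average member upregulation
probabilities; the "top" ensemble greedily selects members by validation
AUC.  Layer plans follow the stated counts (filter numbers, layer counts,
hidden units); unstated details are fixed conventions documented in
docs/methods.md.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluation import roc_auc
from .features import MATRIX_CELLS, MATRIX_SIDE
from .nn import (
    AddChannel,
    BatchNorm,
    Bidirectional,
    ChannelAttention,
    Conv2D,
    ConvLSTM1D,
    Dense,
    DepthwiseConv2D,
    Flatten,
    GELU,
    GlobalAvgPool,
    LastStep,
    LSTM,
    MaxPool2D,
    ReLU,
    Residual,
    Sequential,
    SpatialAttention,
    TimeMajorPool,
)


class InputMode(enum.Enum):
    MATRIX = "matrix"
    SEQUENCE = "sequence"


def to_model_input(features: np.ndarray, mode: InputMode) -> np.ndarray:
    """Reshape (n, 1396) pair encodings for a model's input mode."""
    features = np.asarray(features, dtype=nn.DTYPE)
    if features.ndim != 2 or features.shape[1] < MATRIX_CELLS:
        raise ValueError(
            f"expected (n, >= {MATRIX_CELLS}) feature array, got {features.shape}"
        )
    grid = features[:, :MATRIX_CELLS].reshape(-1, MATRIX_SIDE, MATRIX_SIDE)
    if mode is InputMode.MATRIX:
        return grid[..., None]
    return grid


# ---------------------------------------------------------------------------
# architecture builders


def _conv_bn_relu(c_in, c_out, k, rng, stride=1):
    return [Conv2D(c_in, c_out, k, rng, stride=stride), BatchNorm(c_out), ReLU()]


def _basic_block(c_in, c_out, rng, stride=1):
    body = Sequential(
        _conv_bn_relu(c_in, c_out, 3, rng, stride)
        + [Conv2D(c_out, c_out, 3, rng), BatchNorm(c_out)]
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential([Conv2D(c_in, c_out, 1, rng, stride=stride), BatchNorm(c_out)])
    return Residual(body, shortcut, post_relu=True)


def _bottleneck(c_in, width, rng, stride=1):
    c_out = 4 * width
    body = Sequential(
        _conv_bn_relu(c_in, width, 1, rng)
        + _conv_bn_relu(width, width, 3, rng, stride)
        + [Conv2D(width, c_out, 1, rng), BatchNorm(c_out)]
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential([Conv2D(c_in, c_out, 1, rng, stride=stride), BatchNorm(c_out)])
    return Residual(body, shortcut, post_relu=True)


def _inverted_residual(c_in, c_out, rng, stride=1, expand=2):
    mid = c_in * expand
    body = Sequential(
        _conv_bn_relu(c_in, mid, 1, rng)
        + [DepthwiseConv2D(mid, 3, rng, stride=stride), BatchNorm(mid), ReLU()]
        + [Conv2D(mid, c_out, 1, rng), BatchNorm(c_out)]
    )
    if stride == 1 and c_in == c_out:
        return Residual(body, None, post_relu=False)
    return body


def _build_cnn(rng):
    layers = []
    c = 1
    for _ in range(3):
        layers += [Conv2D(c, 32, 3, rng), BatchNorm(32), ReLU(), MaxPool2D(2)]
        c = 32
    layers += [Flatten(), Dense(4 * 4 * 32, 128, rng), ReLU(), Dense(128, 2, rng)]
    return Sequential(layers)


def _build_alexnet(rng):
    return Sequential(
        _conv_bn_relu(1, 96, 11, rng, stride=2) + [MaxPool2D(2)]        # 37->19->9
        + _conv_bn_relu(96, 256, 5, rng) + [MaxPool2D(2)]               # 9->4
        + _conv_bn_relu(256, 384, 3, rng)
        + _conv_bn_relu(384, 384, 3, rng)
        + _conv_bn_relu(384, 256, 3, rng) + [MaxPool2D(2)]              # 4->2
        + [
            Flatten(),
            Dense(2 * 2 * 256, 256, rng), ReLU(),
            Dense(256, 128, rng), ReLU(),
            Dense(128, 2, rng),
        ]
    )


def _build_convmixer64(rng):
    layers = [Conv2D(1, 64, 4, rng, stride=4), GELU(), BatchNorm(64)]  # patch embed, 37->10
    for _ in range(2):
        layers += [
            Residual(
                Sequential([DepthwiseConv2D(64, 3, rng), GELU(), BatchNorm(64)]),
                None,
                post_relu=False,
            ),
            Conv2D(64, 64, 1, rng), GELU(), BatchNorm(64),
        ]
    layers += [GlobalAvgPool(), Dense(64, 2, rng)]
    return Sequential(layers)


def _build_dsconv(rng):
    return Sequential(
        [
            DepthwiseConv2D(1, 3, rng, depth_multiplier=32), BatchNorm(32), ReLU(),
            MaxPool2D(2),                                                           # 37->18
            DepthwiseConv2D(32, 3, rng), Conv2D(32, 32, 1, rng), BatchNorm(32), ReLU(),
            DepthwiseConv2D(32, 3, rng), BatchNorm(32), ReLU(), MaxPool2D(2),       # 18->9
            DepthwiseConv2D(32, 3, rng), Conv2D(32, 32, 1, rng), BatchNorm(32), ReLU(),
            Flatten(),
            Dense(9 * 9 * 32, 128, rng), ReLU(),
            Dense(128, 2, rng),
        ]
    )


def _build_lstmcnn(rng):
    return Sequential(
        [
            ConvLSTM1D(1, 32, rng), TimeMajorPool(2),   # (37,37) -> (18,18)
            ConvLSTM1D(32, 32, rng), TimeMajorPool(2),  # -> (9,9)
            ConvLSTM1D(32, 32, rng), TimeMajorPool(2),  # -> (4,4)
            Flatten(),
            Dense(4 * 4 * 32, 2, rng),
        ]
    )


def _build_mobilenetv2(rng):
    layers = _conv_bn_relu(1, 8, 3, rng)
    plan = [  # (c_in, c_out, stride)
        (8, 16, 2), (16, 16, 1),
        (16, 24, 2), (24, 24, 1),
        (24, 32, 2), (32, 32, 1),
    ]
    for c_in, c_out, stride in plan:
        layers.append(_inverted_residual(c_in, c_out, rng, stride=stride, expand=2))
    layers += _conv_bn_relu(32, 64, 1, rng)
    layers += [GlobalAvgPool(), Dense(64, 2, rng)]
    return Sequential(layers)


_RESNET18_STAGES = [(16, 1), (32, 2), (48, 2), (64, 2)]


def _build_resnet18(rng, with_attention: bool = False):
    layers = _conv_bn_relu(1, 16, 3, rng, stride=2)  # 37 -> 19
    c_in = 16
    for c_out, stride in _RESNET18_STAGES:
        layers.append(_basic_block(c_in, c_out, rng, stride=stride))
        layers.append(_basic_block(c_out, c_out, rng))
        if with_attention:
            layers += [ChannelAttention(c_out, rng), SpatialAttention(rng)]
        c_in = c_out
    layers += [GlobalAvgPool(), Dense(c_in, 2, rng)]
    return Sequential(layers)


def _build_resnet50(rng):
    layers = _conv_bn_relu(1, 16, 3, rng, stride=2)  # 37 -> 19
    c_in = 16
    for width, n_blocks, stride in [(8, 3, 1), (12, 4, 2), (16, 6, 2), (24, 3, 2)]:
        layers.append(_bottleneck(c_in, width, rng, stride=stride))
        for _ in range(n_blocks - 1):
            layers.append(_bottleneck(4 * width, width, rng))
        c_in = 4 * width
    layers += [GlobalAvgPool(), Dense(c_in, 2, rng)]
    return Sequential(layers)


def _build_rnn(rng):
    return Sequential(
        [
            LSTM(37, 256, rng, return_sequences=True),
            LSTM(256, 256, rng, return_sequences=False),
            Dense(256, 256, rng), ReLU(),
            Dense(256, 2, rng),
        ]
    )


def _build_birnn(rng):
    return Sequential(
        [
            LSTM(37, 256, rng, return_sequences=True),
            LSTM(256, 256, rng, return_sequences=True),
            Bidirectional(256, 256, rng, return_sequences=False),
            Dense(512, 2, rng),
        ]
    )


def _build_seq2seq(rng):
    return Sequential(
        [
            # encoder: two LSTM layers then a bidirectional layer
            LSTM(37, 256, rng, return_sequences=True),
            LSTM(256, 256, rng, return_sequences=True),
            Bidirectional(256, 256, rng, return_sequences=True),
            # decoder: the same three layers in reverse order
            Bidirectional(512, 256, rng, return_sequences=True),
            LSTM(512, 256, rng, return_sequences=True),
            LSTM(256, 256, rng, return_sequences=False),
            Dense(256, 256, rng), ReLU(),
            Dense(256, 2, rng),
        ]
    )


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    input_mode: InputMode
    builder: object


ARCHITECTURES: dict[str, ArchitectureSpec] = {
    spec.name: spec
    for spec in [
        ArchitectureSpec("AlexNet", InputMode.MATRIX, _build_alexnet),
        ArchitectureSpec("BiRNN", InputMode.SEQUENCE, _build_birnn),
        ArchitectureSpec("CNN", InputMode.MATRIX, _build_cnn),
        ArchitectureSpec("ConvMixer64", InputMode.MATRIX, _build_convmixer64),
        ArchitectureSpec("DSConv", InputMode.MATRIX, _build_dsconv),
        ArchitectureSpec("LSTMCNN", InputMode.MATRIX, _build_lstmcnn),
        ArchitectureSpec("MobileNetV2", InputMode.MATRIX, _build_mobilenetv2),
        ArchitectureSpec("ResNet18", InputMode.MATRIX, _build_resnet18),
        ArchitectureSpec(
            "ResNet50", InputMode.MATRIX, _build_resnet50
        ),
        ArchitectureSpec("RNN", InputMode.SEQUENCE, _build_rnn),
        ArchitectureSpec("Seq2Seq", InputMode.SEQUENCE, _build_seq2seq),
        ArchitectureSpec(
            "SCAResNet18",
            InputMode.MATRIX,
            lambda rng: _build_resnet18(rng, with_attention=True),
        ),
    ]
}


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 100
    max_epochs: int = 400
    patience: int = 10
    folds: int = 5
    seed: int = 0
    #: optional compute caps: end training early once the epoch-mean
    #: training loss falls to this fraction of the first epoch's loss
    #: and/or the best validation AUC reaches stop_auc (when both are set,
    #: both must hold); the best-epoch parameters are still returned
    stop_loss_fraction: float | None = None
    stop_auc: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.patience < 1:
            raise ValueError("batch_size and patience must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_auc: float


@dataclass
class ModelHandle:
    """A (possibly trained) architecture instance.

    ``feat_mean``/``feat_std`` hold the per-feature standardization fitted
    on the training set; prediction re-applies it so raw pair encodings
    (binary bits, compositions, unbounded descriptors) enter the network
    on a common scale.
    """

    spec: ArchitectureSpec
    net: Sequential
    seed: int
    trained: bool = False
    history: list[EpochRecord] = field(default_factory=list)
    best_epoch: int | None = None
    best_val_auc: float | None = None
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None

    def standardize(self, features: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return np.asarray(features, dtype=nn.DTYPE)
        return ((features - self.feat_mean) / self.feat_std).astype(nn.DTYPE)

    @property
    def name(self) -> str:
        return self.spec.name

    def predict_p_up(self, features: np.ndarray) -> np.ndarray:
        return predict(self, features)


def build_model(name: str, seed: int = 0) -> ModelHandle:
    """Instantiate an untrained architecture with seeded initialization."""
    if name not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {name!r}; valid names: {sorted(ARCHITECTURES)}"
        )
    spec = ARCHITECTURES[name]
    rng = np.random.default_rng(seed)
    return ModelHandle(spec=spec, net=spec.builder(rng), seed=seed)


def _forward_batched(net: Sequential, x: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [net.forward(x[i : i + batch], train=False) for i in range(0, x.shape[0], batch)]
    return np.concatenate(outs, axis=0)


def _batchnorms(net: Sequential) -> list[BatchNorm]:
    return [m for m in nn.iter_modules(net) if isinstance(m, BatchNorm)]


def _snapshot(net: Sequential) -> tuple[list[np.ndarray], list[tuple[np.ndarray, np.ndarray]]]:
    params = [p.value.copy() for p in net.params()]
    stats = [(bn.run_mean.copy(), bn.run_var.copy()) for bn in _batchnorms(net)]
    return params, stats


def _restore(net: Sequential, snap) -> None:
    params, stats = snap
    for p, v in zip(net.params(), params):
        p.value = v.copy()
    for bn, (mean, var) in zip(_batchnorms(net), stats):
        bn.run_mean = mean.copy()
        bn.run_var = var.copy()


def train_model(
    handle: ModelHandle,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    config: TrainConfig | None = None,
) -> ModelHandle:
    """Train in place with Adam and early stopping on validation AUC.

    Labels are 1 for UP, 0 for DOWN.  The returned handle carries the
    parameters of the epoch with the best validation AUC; training stops
    after ``patience`` epochs without improvement.
    """
    config = config or TrainConfig()
    if config.max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    y_train = np.asarray(train_labels, dtype=int)
    y_val = np.asarray(val_labels, dtype=int)
    if y_val.size == 0:
        raise ValueError("validation set is empty")
    if len(np.unique(y_train)) < 2 or len(np.unique(y_val)) < 2:
        raise ValueError("training and validation sets must contain both classes")

    train_features = np.asarray(train_features, dtype=np.float64)
    handle.feat_mean = train_features.mean(axis=0)
    std = train_features.std(axis=0)
    std[std < 1e-8] = 1.0  # constant features pass through unscaled
    handle.feat_std = std
    x_train = to_model_input(handle.standardize(train_features), handle.spec.input_mode)
    x_val = to_model_input(handle.standardize(val_features), handle.spec.input_mode)
    opt = nn.Adam(handle.net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    best_auc = -np.inf
    best_snap = None
    best_epoch = -1
    since_best = 0
    first_loss = None
    min_loss = np.inf
    handle.history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(x_train.shape[0])
        losses = []
        for start in range(0, x_train.shape[0], config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = handle.net.forward(x_train[idx], train=True)
            loss, grad = nn.cross_entropy(logits, y_train[idx])
            handle.net.backward(grad)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))
        val_scores = nn.softmax(_forward_batched(handle.net, x_val))[:, 1]
        val_auc = roc_auc(val_scores, y_val)
        handle.history.append(EpochRecord(epoch=epoch, train_loss=train_loss, val_auc=val_auc))
        if val_auc > best_auc:
            best_auc, best_epoch, since_best = val_auc, epoch, 0
            best_snap = _snapshot(handle.net)
        else:
            since_best += 1
            if since_best >= config.patience:
                break
        if first_loss is None:
            first_loss = train_loss
        min_loss = min(min_loss, train_loss)
        caps = []
        if config.stop_loss_fraction is not None:
            caps.append(min_loss <= config.stop_loss_fraction * first_loss)
        if config.stop_auc is not None:
            caps.append(best_auc >= config.stop_auc)
        if caps and all(caps):
            break

    if best_snap is not None:
        _restore(handle.net, best_snap)
    handle.trained = True
    handle.best_epoch = best_epoch
    handle.best_val_auc = float(best_auc)
    return handle


def predict(handle: ModelHandle, features: np.ndarray) -> np.ndarray:
    """Upregulation probabilities (one per pair, order preserved)."""
    if not handle.trained:
        raise ValueError(f"model {handle.name} is not trained")
    x = to_model_input(handle.standardize(features), handle.spec.input_mode)
    return nn.softmax(_forward_batched(handle.net, x))[:, 1]


def predict_proba(handle: ModelHandle, features: np.ndarray) -> np.ndarray:
    """Two-class probabilities (DOWN, UP); rows sum to 1."""
    if not handle.trained:
        raise ValueError(f"model {handle.name} is not trained")
    x = to_model_input(handle.standardize(features), handle.spec.input_mode)
    return nn.softmax(_forward_batched(handle.net, x))


def ensemble_average(members: list, features: np.ndarray) -> np.ndarray:
    """Mean of member upregulation probabilities."""
    if not members:
        raise ValueError("ensemble needs at least one member")
    return np.mean([m.predict_p_up(features) for m in members], axis=0)


@dataclass
class EnsembleSpec:
    """Members chosen for the averaged ensemble, with the selection trace."""

    members: list
    mode: str  # "all" or "top"
    #: (member name, validation AUC after adding it) in selection order
    selection_record: list[tuple[str, float]] = field(default_factory=list)

    def predict_p_up(self, features: np.ndarray) -> np.ndarray:
        return ensemble_average(self.members, features)


def select_top_ensemble(
    members: list,
    val_features: np.ndarray,
    val_labels: np.ndarray,
) -> EnsembleSpec:
    """Greedy forward selection of ensemble members by validation AUC.

    Starts from the best single member, then repeatedly adds the member
    whose inclusion most increases the averaged-ensemble validation AUC,
    stopping when no addition improves it.
    """
    if len(members) < 2:
        raise ValueError("top-ensemble selection needs at least 2 members")
    y_val = np.asarray(val_labels, dtype=int)
    if y_val.size == 0 or len(np.unique(y_val)) < 2:
        raise ValueError("validation set must be non-empty with both classes")

    scores = {m.name: m.predict_p_up(val_features) for m in members}
    by_name = {m.name: m for m in members}
    aucs = {name: roc_auc(s, y_val) for name, s in scores.items()}
    first = max(sorted(aucs), key=lambda n: aucs[n])
    chosen = [first]
    best_auc = aucs[first]
    record = [(first, best_auc)]
    remaining = sorted(set(scores) - {first})
    while remaining:
        trial = [
            (roc_auc(np.mean([scores[n] for n in chosen + [cand]], axis=0), y_val), cand)
            for cand in remaining
        ]
        gain_auc, cand = max(trial, key=lambda t: (t[0], t[1]))
        if gain_auc <= best_auc:
            break
        chosen.append(cand)
        best_auc = gain_auc
        record.append((cand, gain_auc))
        remaining.remove(cand)
    return EnsembleSpec(
        members=[by_name[n] for n in chosen], mode="top", selection_record=record
    )


def crossval_auc(
    name: str,
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    folds: int = 5,
) -> list[float]:
    """Fold-wise validation AUCs for one architecture (assessment mode)."""
    config = config or TrainConfig()
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(y.shape[0])
    fold_ids = np.array_split(order, folds)
    aucs = []
    for k in range(folds):
        val_idx = fold_ids[k]
        train_idx = np.concatenate([fold_ids[j] for j in range(folds) if j != k])
        handle = build_model(name, seed=config.seed + k)
        train_model(
            handle, features[train_idx], y[train_idx], features[val_idx], y[val_idx], config
        )
        aucs.append(roc_auc(predict(handle, features[val_idx]), y[val_idx]))
    return aucs
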