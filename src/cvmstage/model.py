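"""The compact six-block staging CNN and its training procedures.

The network is a "six-layer" structure: five blocks of
convolution -> batch normalization -> ReLU -> max pooling -> dropout
(with increasing dropout rates), followed by one dense block
(dense -> batch normalization -> ReLU -> dropout) and a final dense
layer to 6 classes with softmax. It is trained with categorical
cross-entropy under SGD-with-momentum or Adam.

Also implemented here: the exponential learning-rate range test (increase
the LR geometrically batch-by-batch, record the per-batch loss, pick the LR
at the steepest smoothed loss decrease) and the confidence-thresholded
self-training step that moves pool samples classified correctly with very
high probability into the training set.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from cvmstage import nn
from cvmstage.stages import N_STAGES


class ContractError(ValueError):
    """An argument violates an interface contract (shape/value)."""


class TrainingDiverged(RuntimeError):
    """Loss became non-finite during training."""


# ---------------------------------------------------------------------------
# Loss

def one_hot(labels: np.ndarray, n_classes: int = N_STAGES) -> np.ndarray:
    """Stage labels 1..n -> one-hot rows."""
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > n_classes:
        raise ContractError(f"labels must be in 1..{n_classes}")
    return np.eye(n_classes, dtype=np.float32)[labels - 1]


def categorical_cross_entropy(
    true_labels: np.ndarray,
    predicted_probs: np.ndarray,
    reduction: str = "mean",
    eps: float = 1e-12,
) -> float:
    """Categorical cross-entropy  -sum_i sum_j y_ij ln(p_ij).

    ``true_labels`` is a one-hot matrix, ``predicted_probs`` a row-stochastic
    matrix of the same shape. Probabilities are clamped to ``[eps, 1]``
    before the log; with ``reduction="mean"`` the sum is divided by the
    number of samples.
    """
    y = np.asarray(true_labels, dtype=np.float64)
    p = np.asarray(predicted_probs, dtype=np.float64)
    if y.shape != p.shape or y.ndim != 2:
        raise ContractError(f"shape mismatch: {y.shape} vs {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ContractError("predicted_probs rows must sum to 1 within 1e-6")
    row_ok = np.all((y == 0) | (y == 1)) and np.all(y.sum(axis=1) == 1)
    if not row_ok:
        raise ContractError("true_labels must be valid one-hot rows")
    loss = -(y * np.log(np.clip(p, eps, 1.0))).sum()
    if reduction == "mean":
        loss /= y.shape[0]
    elif reduction != "sum":
        raise ContractError(f"unknown reduction {reduction!r}")
    return float(loss)


# ---------------------------------------------------------------------------
# Architecture

@dataclasses.dataclass(frozen=True)
class ConvBlockSpec:
    """One convolution block: conv -> batchnorm -> ReLU -> maxpool -> dropout."""

    filter_count: int
    kernel_side: int = 3
    pool_side: int = 2
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


def default_conv_blocks() -> tuple[ConvBlockSpec, ...]:
    """The five-block ladder: 32-64-64-128-128 filters, 2x2 pools,
    increasing dropout rates 0.1, 0.1, 0.15, 0.2, 0.25.

    The rates stay modest because at 64-px input the late blocks operate on
    2x2 and 1x1 feature maps, where heavy dropout combined with the
    dropout/batch-norm variance shift stalls optimization on small datasets.
    """
    filters = (32, 64, 64, 128, 128)
    dropouts = (0.1, 0.1, 0.15, 0.2, 0.25)
    return tuple(ConvBlockSpec(f, 3, 2, d) for f, d in zip(filters, dropouts))


def small_conv_blocks() -> tuple[ConvBlockSpec, ...]:
    """A narrower ladder for quick runs on small images."""
    filters = (16, 32, 32, 64, 64)
    dropouts = (0.1, 0.1, 0.15, 0.2, 0.25)
    return tuple(ConvBlockSpec(f, 3, 2, d) for f, d in zip(filters, dropouts))


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_side`` must survive the pooling cascade (divisible by the product
    of the pool sides with at least one pixel left). ``dense_width`` is the
    width of the dense block (1024 = "32 x 32" by default).
    """

    input_side: int = 64
    conv_blocks: tuple[ConvBlockSpec, ...] = dataclasses.field(
        default_factory=default_conv_blocks)
    dense_width: int = 1024
    dense_dropout: float = 0.4
    n_classes: int = N_STAGES

    def __post_init__(self) -> None:
        side = self.input_side
        for i, b in enumerate(self.conv_blocks):
            if side % b.pool_side:
                raise ValueError(
                    f"block {i}: spatial size {side} not divisible by "
                    f"pool {b.pool_side}")
            side //= b.pool_side
            if side < 1:
                raise ValueError("pooling cascade exhausts the spatial size")

    @property
    def final_side(self) -> int:
        side = self.input_side
        for b in self.conv_blocks:
            side //= b.pool_side
        return side


class CompactCNN:
    """Handle over the layer stack: forward evaluation, parameter count,
    state snapshot/restore."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        c_in = 1
        for b in config.conv_blocks:
            layers += [
                nn.Conv2D(c_in, b.filter_count, b.kernel_side, rng),
                nn.BatchNorm(b.filter_count),
                nn.ReLU(),
                nn.MaxPool2D(b.pool_side),
                nn.Dropout(b.dropout_rate),
            ]
            c_in = b.filter_count
        layers[0].compute_input_grad = False
        flat = config.final_side ** 2 * c_in
        layers += [
            nn.Flatten(),
            nn.Dense(flat, config.dense_width, rng),
            nn.BatchNorm(config.dense_width),
            nn.ReLU(),
            nn.Dropout(config.dense_dropout),
            nn.Dense(config.dense_width, config.n_classes, rng),
        ]
        self.layers = layers

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def logits(self, x: np.ndarray, training: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def state(self) -> list[dict]:
        return [l.state() for l in self.layers]

    def load_state(self, state: list[dict]) -> None:
        for l, s in zip(self.layers, state):
            l.load_state(s)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> CompactCNN:
    """Instantiate the network with seeded He initialization."""
    return CompactCNN(config or ModelConfig(), seed)


def _as_nhwc(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[3] != 1:
        raise ContractError(f"expected (N, H, W[, 1]) images, got {x.shape}")
    return x


def predict_proba(model: CompactCNN, images: np.ndarray,
                  batch_size: int = 128) -> np.ndarray:
    """Class-probability matrix, one row per image (rows sum to 1).

    The predicted stage is ``argmax + 1`` with the lowest index winning ties.
    """
    x = _as_nhwc(images)
    if x.shape[1] != model.config.input_side or x.shape[2] != model.config.input_side:
        raise ContractError(
            f"images are {x.shape[1:3]}, model expects "
            f"{(model.config.input_side,) * 2}")
    out = []
    for i in range(0, x.shape[0], batch_size):
        out.append(nn.softmax(model.logits(x[i:i + batch_size], training=False)))
    return np.concatenate(out, axis=0)


def predict_stages(model: CompactCNN, images: np.ndarray,
                   batch_size: int = 128) -> np.ndarray:
    """Predicted stage indices 1..6."""
    return predict_proba(model, images, batch_size).argmax(axis=1) + 1


# ---------------------------------------------------------------------------
# Training

@dataclasses.dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"            # "sgd" | "adam"
    learning_rate: float = 3e-3
    momentum: float = 0.9              # SGD momentum / Adam beta1
    beta2: float = 0.999               # Adam only
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    loss_reduction: str = "mean"
    restore_best: bool = True          # restore best-validation-accuracy state
    refresh_bn: bool = True            # re-estimate BN stats before evaluating

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclasses.dataclass
class TrainingHistory:
    """Per-epoch series; accuracies in [0, 1]."""

    train_loss: list[float] = dataclasses.field(default_factory=list)
    train_accuracy: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    val_accuracy: list[float] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(dataclasses.asdict(self))


def refresh_batchnorm(model: CompactCNN, images: np.ndarray,
                      batch_size: int = 64, max_samples: int = 512) -> None:
    """Re-estimate batch-normalization statistics with dropout disabled.

    Dropout scales activation variance during training, so running statistics
    accumulated then overestimate the variance the network sees at inference
    (the dropout/batch-norm "variance shift"). With several stacked
    dropout + batch-norm blocks the mismatch compounds and evaluation-mode
    outputs degrade badly. This pass re-runs (a subsample of) the training
    images with dropout off, replacing each layer's running mean/variance by
    the cumulative average of the dropout-free batch statistics.
    """
    x = _as_nhwc(images)[:max_samples]
    bns = [l for l in model.layers if isinstance(l, nn.BatchNorm)]
    for b in bns:
        b.running_mean[:] = 0.0
        b.running_var[:] = 0.0
    saved = [b.momentum for b in bns]
    n_batches = 0
    for start in range(0, x.shape[0], batch_size):
        n_batches += 1
        for b in bns:
            b.momentum = (n_batches - 1) / n_batches  # cumulative average
        out = x[start:start + batch_size]
        for layer in model.layers:
            if isinstance(layer, nn.BatchNorm):
                out = layer.forward(out, True, None)
            else:
                out = layer.forward(out, False, None)
    for b, m in zip(bns, saved):
        b.momentum = m


def _make_optimizer(model: CompactCNN, tc: TrainConfig) -> nn.Optimizer:
    if tc.optimizer == "sgd":
        return nn.SGD(model.layers, tc.learning_rate, tc.momentum)
    return nn.Adam(model.layers, tc.learning_rate, tc.momentum, tc.beta2)


def evaluate(model: CompactCNN, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 128) -> tuple[float, float]:
    """(cross-entropy loss, accuracy) in evaluation mode."""
    probs = predict_proba(model, images, batch_size)
    y = one_hot(labels, model.config.n_classes)
    loss = categorical_cross_entropy(y, probs)
    acc = float((probs.argmax(axis=1) + 1 == np.asarray(labels)).mean())
    return loss, acc


def train(
    model: CompactCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    tc: TrainConfig,
) -> tuple[CompactCNN, TrainingHistory]:
    """Mini-batch training; returns the model and its per-epoch history.

    Epoch train metrics are averaged over the training batches (training
    mode, as the batches were seen); validation metrics use evaluation mode.
    With ``restore_best`` the parameters revert to the epoch with the best
    validation accuracy (earliest on ties) before returning. Identical seeds
    and single-threaded execution reproduce identical histories.
    """
    x = _as_nhwc(train_set[0])
    y = np.asarray(train_set[1])
    if x.shape[0] == 0:
        raise ContractError("empty training set")
    onehot = one_hot(y, model.config.n_classes)
    rng = np.random.default_rng(tc.seed)
    opt = _make_optimizer(model, tc)
    history = TrainingHistory()
    best = (-1.0, None)

    n = x.shape[0]
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for bi, start in enumerate(range(0, n, tc.batch_size)):
            idx = order[start:start + tc.batch_size]
            xb, yb = x[idx], onehot[idx]
            logits = model.logits(xb, training=True, rng=rng)
            loss, dlogits, probs = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {bi}")
            if tc.loss_reduction == "sum":
                loss_rec = loss * xb.shape[0]
            else:
                loss_rec = loss
            losses.append(loss_rec)
            hits += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
            seen += xb.shape[0]
            model.backward(dlogits)
            opt.step()
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(hits / seen)
        if tc.refresh_bn:
            refresh_batchnorm(model, x)
        if val_set is not None and len(val_set[1]) > 0:
            vl, va = evaluate(model, *val_set)
            history.val_loss.append(vl)
            history.val_accuracy.append(va)
            if tc.restore_best and va > best[0]:
                best = (va, model.state())
        else:
            history.val_loss.append(float("nan"))
            history.val_accuracy.append(float("nan"))
    if tc.restore_best and best[1] is not None:
        model.load_state(best[1])
    return model, history


# ---------------------------------------------------------------------------
# Learning-rate range test

@dataclasses.dataclass(frozen=True)
class LRRangeResult:
    """Per-batch (learning rate, loss) records; rates strictly increasing
    along a geometric progression."""

    learning_rates: tuple[float, ...]
    losses: tuple[float, ...]


def lr_range_test(
    model: CompactCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    lr_bounds: tuple[float, float] = (1e-1, 1e1),
    n_steps: int = 100,
    tc: TrainConfig | None = None,
) -> LRRangeResult:
    """Exponential LR sweep: step k uses lr = low * (high/low)^(k/(n-1)).

    The training batch loss is recorded at each step; the model (and a fresh
    optimizer) is updated after each batch so the curve reflects training
    dynamics. The model's parameters are restored to their pre-test values
    before returning.
    """
    low, high = lr_bounds
    if not (0 < low < high):
        raise ContractError("lr_bounds must satisfy 0 < low < high")
    if n_steps < 2:
        raise ContractError("n_steps must be >= 2")
    tc = tc or TrainConfig()
    x = _as_nhwc(train_set[0])
    onehot = one_hot(np.asarray(train_set[1]), model.config.n_classes)
    saved = model.state()
    rng = np.random.default_rng(tc.seed)
    opt = _make_optimizer(model, tc)
    n = x.shape[0]
    order = rng.permutation(n)
    lrs, losses = [], []
    ratio = high / low
    pos = 0
    for k in range(n_steps):
        lr = low * ratio ** (k / (n_steps - 1))
        opt.lr = lr
        idx = order[pos:pos + tc.batch_size]
        pos += tc.batch_size
        if pos >= n:
            pos = 0
            order = rng.permutation(n)
        if len(idx) == 0:
            idx = order[: tc.batch_size]
        logits = model.logits(x[idx], training=True, rng=rng)
        loss, dlogits, _ = nn.softmax_cross_entropy(logits, onehot[idx])
        lrs.append(lr)
        losses.append(loss)
        if np.isfinite(loss):
            model.backward(dlogits)
            opt.step()
    model.load_state(saved)
    return LRRangeResult(tuple(lrs), tuple(losses))


def select_lr(result: LRRangeResult, smooth_window: int = 5) -> float:
    """LR at the steepest smoothed loss decrease.

    The loss series is smoothed with a centered moving average, finite
    differences are taken, and the LR reached by the steepest negative
    difference is returned. If the loss never decreases a warning is issued
    and the lower bound is returned.
    """
    if len(result.learning_rates) == 0:
        raise ContractError("empty LR range result")
    lrs = np.asarray(result.learning_rates)
    losses = np.asarray(result.losses, dtype=float)
    losses = np.where(np.isfinite(losses), losses, np.nanmax(
        np.where(np.isfinite(losses), losses, np.nan)))
    w = max(1, min(smooth_window, len(losses)))
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(losses, pad, mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")[: len(losses)]
    if len(smooth) < 2:
        return float(lrs[0])
    d = np.diff(smooth)
    i = int(np.argmin(d))
    if d[i] >= 0:
        warnings.warn("loss never decreases over the LR range; "
                      "returning the lower bound")
        return float(lrs[0])
    return float(lrs[i + 1])


# ---------------------------------------------------------------------------
# Checkpoints

def _flatten_state(state: list[dict], prefix: str = "") -> dict[str, np.ndarray]:
    flat: dict[str, np.ndarray] = {}
    for i, layer_state in enumerate(state):
        for key, val in layer_state.items():
            if isinstance(val, dict):
                for k2, v2 in val.items():
                    flat[f"{i}.{key}.{k2}"] = v2
            else:
                flat[f"{i}.{key}"] = val
    return flat


def model_config_to_dict(config: ModelConfig) -> dict:
    return dataclasses.asdict(config)


def model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["conv_blocks"] = tuple(
        ConvBlockSpec(**b) if isinstance(b, dict) else ConvBlockSpec(*b)
        for b in d["conv_blocks"])
    return ModelConfig(**d)


def save_checkpoint(model: CompactCNN, path, sidecar: dict | None = None) -> None:
    """Write parameters as ``.npz`` plus a ``.json`` sidecar holding the
    architecture (and any extra metadata, e.g. TrainConfig and seed)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **_flatten_state(model.state()))
    meta = {"model_config": model_config_to_dict(model.config)}
    meta.update(sidecar or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> tuple[CompactCNN, dict]:
    """Rebuild a model from ``save_checkpoint`` output."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    model = build_model(model_config_from_dict(meta["model_config"]))
    data = np.load(path)
    state = model.state()
    for full_key in data.files:
        parts = full_key.split(".")
        i = int(parts[0])
        if len(parts) == 3:
            state[i][parts[1]][parts[2]] = data[full_key]
        else:
            state[i][parts[1]] = data[full_key]
    model.load_state(state)
    return model, meta


# ---------------------------------------------------------------------------
# Self-training

def self_training_update(
    model: CompactCNN,
    train_set: tuple[np.ndarray, np.ndarray],
    pool_set: tuple[np.ndarray, np.ndarray],
    prob_threshold: float = 0.99,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray], list[dict]]:
    """Move pool samples the model classifies correctly with probability >=
    ``prob_threshold`` into the training set.

    Returns (augmented train set, reduced pool set, move log). The move log
    records the pool index, true label and predicted probability of every
    moved sample; the two sets stay disjoint.
    """
    if not 0.0 < prob_threshold <= 1.0:
        raise ContractError("prob_threshold must be in (0, 1]")
    xp, yp = np.asarray(pool_set[0]), np.asarray(pool_set[1])
    if xp.shape[0] == 0:
        return train_set, pool_set, [{"notice": "empty pool; nothing moved"}]
    probs = predict_proba(model, xp)
    pred = probs.argmax(axis=1) + 1
    conf = probs.max(axis=1)
    move = (pred == yp) & (conf >= prob_threshold)
    log = [
        {"pool_index": int(i), "label": int(yp[i]), "probability": float(conf[i])}
        for i in np.flatnonzero(move)
    ]
    xt, yt = np.asarray(train_set[0]), np.asarray(train_set[1])
    new_train = (np.concatenate([xt, xp[move]]), np.concatenate([yt, yp[move]]))
    new_pool = (xp[~move], yp[~move])
    return new_train, new_pool, log
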