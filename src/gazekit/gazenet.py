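"""Shallow feed-forward gaze regressor and its training protocol.

The network maps the 14 normalized landmark coordinates (x, y of seven
facial landmarks) to the two screen coordinates of the point of gaze:
a single fully connected hidden layer of 200 sigmoid units followed by a
linear 2-unit output layer. Training is plain mini-batch stochastic
gradient descent with classical (heavy-ball) momentum 0.6, initial
learning rate 0.03 halved every 2,000 epochs, batch size 4, and
best-validation-checkpoint selection evaluated every 10 epochs. The loss
is the mean over samples of the squared Euclidean offset
``mean(dx^2 + dy^2)``.

Screen targets are divided by ``target_scale`` before training and
predictions are scaled back. The default (600) applies the same
homogeneous normalization constant to the outputs that the feature
assembly applies to the inputs; it also sets the loss — and hence the
effective gradient step at the fixed 0.03 learning rate — at a scale where
the protocol converges well. Trace losses are in normalized units; error
reports downstream are in pixels/dva.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "TrainingTrace",
    "init_params",
    "forward",
    "l2_loss",
    "loss_gradients",
    "scheduled_lr",
    "train",
    "predict",
    "save_params",
    "load_params",
]

N_INPUT, N_HIDDEN, N_OUTPUT = 14, 200, 2


@dataclass(frozen=True)
class NetworkParams:
    """Weights and biases of the 14 -> 200 -> 2 regressor."""

    hidden_weights: np.ndarray  # (200, 14)
    hidden_bias: np.ndarray  # (200,)
    output_weights: np.ndarray  # (2, 200)
    output_bias: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        shapes = {
            "hidden_weights": (N_HIDDEN, N_INPUT),
            "hidden_bias": (N_HIDDEN,),
            "output_weights": (N_OUTPUT, N_HIDDEN),
            "output_bias": (N_OUTPUT,),
        }
        for name, expected in shapes.items():
            arr = getattr(self, name)
            if arr.shape != expected:
                raise ValueError(f"{name} must have shape {expected}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.hidden_weights.copy(),
            self.hidden_bias.copy(),
            self.output_weights.copy(),
            self.output_bias.copy(),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (defaults are the reference protocol)."""

    learning_rate0: float = 0.03
    momentum: float = 0.6
    halve_every_epochs: int = 2000
    batch_size: int = 4
    max_epochs: int = 15000
    validate_every_epochs: int = 10
    seed: int = 0
    target_scale: float = 600.0

    def __post_init__(self) -> None:
        for name in (
            "learning_rate0",
            "halve_every_epochs",
            "batch_size",
            "max_epochs",
            "validate_every_epochs",
            "target_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"TrainConfig.{name} must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass(frozen=True)
class TrainingTrace:
    """Per-evaluation loss records and the selected checkpoint epoch."""

    records: pd.DataFrame  # columns: epoch, train_loss, val_loss, lr
    best_epoch: int

    @property
    def best_val_loss(self) -> float:
        return float(self.records["val_loss"].min())


def init_params(seed: int) -> NetworkParams:
    """Seeded uniform initialization in +-1/sqrt(fan_in) per layer."""
    rng = np.random.default_rng(seed)
    return _init_with_rng(rng)


def _init_with_rng(rng: np.random.Generator) -> NetworkParams:
    b1 = 1.0 / np.sqrt(N_INPUT)
    b2 = 1.0 / np.sqrt(N_HIDDEN)
    return NetworkParams(
        hidden_weights=rng.uniform(-b1, b1, size=(N_HIDDEN, N_INPUT)),
        hidden_bias=rng.uniform(-b1, b1, size=N_HIDDEN),
        output_weights=rng.uniform(-b2, b2, size=(N_OUTPUT, N_HIDDEN)),
        output_bias=rng.uniform(-b2, b2, size=N_OUTPUT),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def forward(params: NetworkParams, features: np.ndarray) -> np.ndarray:
    """Evaluate the network: ``W2 @ sigmoid(W1 @ x + b1) + b2``.

    Accepts a single 14-vector or an (N, 14) batch.
    """
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != N_INPUT:
        raise ValueError(f"features must have {N_INPUT} columns, got {x.shape[1]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    hidden = _sigmoid(x @ params.hidden_weights.T + params.hidden_bias)
    out = hidden @ params.output_weights.T + params.output_bias
    return out[0] if single else out


def l2_loss(predictions: np.ndarray, truths: np.ndarray) -> float:
    """Mean over samples of the squared 2D offset ``dx^2 + dy^2``."""
    pred = np.atleast_2d(np.asarray(predictions, dtype=float))
    true = np.atleast_2d(np.asarray(truths, dtype=float))
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    if pred.shape[0] == 0:
        raise ValueError("loss of an empty batch is undefined")
    delta = pred - true
    return float(np.mean(np.sum(delta * delta, axis=1)))


def loss_gradients(
    params: NetworkParams, features: np.ndarray, targets: np.ndarray
) -> dict[str, np.ndarray]:
    """Analytic gradient of :func:`l2_loss` over a batch, by backpropagation."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    n = x.shape[0]
    hidden = _sigmoid(x @ params.hidden_weights.T + params.hidden_bias)
    out = hidden @ params.output_weights.T + params.output_bias
    d_out = 2.0 * (out - t) / n
    d_hidden = (d_out @ params.output_weights) * hidden * (1.0 - hidden)
    return {
        "hidden_weights": d_hidden.T @ x,
        "hidden_bias": d_hidden.sum(axis=0),
        "output_weights": d_out.T @ hidden,
        "output_bias": d_out.sum(axis=0),
    }


def scheduled_lr(epoch: int, cfg: TrainConfig) -> float:
    """Step-halving schedule: ``lr0 * 0.5 ** floor(epoch / halve_every)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.learning_rate0 * 0.5 ** (epoch // cfg.halve_every_epochs)


def train(
    train_features: np.ndarray,
    train_targets_px: np.ndarray,
    val_features: np.ndarray,
    val_targets_px: np.ndarray,
    cfg: TrainConfig,
) -> tuple[NetworkParams, TrainingTrace]:
    """Mini-batch SGD with momentum; returns the best-validation checkpoint.

    Targets are supplied in screen pixels and normalized internally by
    ``cfg.target_scale``. Epoch ``e`` (0-based) runs at learning rate
    ``scheduled_lr(e, cfg)`` over a freshly shuffled training set, keeping
    the last incomplete mini-batch. Every ``validate_every_epochs``
    completed epochs (and once before training, epoch 0) the train and
    validation losses are recorded; the parameters achieving the minimal
    recorded validation loss are returned. The classical momentum update is
    ``v <- mu*v - lr*grad; theta <- theta + v``.

    Raises ``FloatingPointError`` on divergence (non-finite loss), with the
    trace collected so far attached as ``exc.trace``.
    """
    x_tr = np.ascontiguousarray(np.atleast_2d(train_features), dtype=float)
    x_va = np.ascontiguousarray(np.atleast_2d(val_features), dtype=float)
    t_tr = np.asarray(train_targets_px, dtype=float) / cfg.target_scale
    t_va = np.asarray(val_targets_px, dtype=float) / cfg.target_scale
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be nonempty")

    rng = np.random.default_rng(cfg.seed)
    params = _init_with_rng(rng)
    w1 = params.hidden_weights.copy()
    b1 = params.hidden_bias.copy()
    w2 = params.output_weights.copy()
    b2 = params.output_bias.copy()
    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = np.zeros_like(b2)

    n = len(x_tr)
    bs = cfg.batch_size
    mu = cfg.momentum

    records: list[tuple[int, float, float, float]] = []
    best_val = np.inf
    best_epoch = -1
    best = None

    def evaluate(epoch: int) -> None:
        nonlocal best_val, best_epoch, best
        p = NetworkParams(w1, b1, w2, b2)
        tr_loss = l2_loss(forward(p, x_tr), t_tr)
        va_loss = l2_loss(forward(p, x_va), t_va)
        records.append((epoch, tr_loss, va_loss, scheduled_lr(epoch, cfg)))
        if not (np.isfinite(tr_loss) and np.isfinite(va_loss)):
            trace = _trace(records, best_epoch)
            exc = FloatingPointError(
                f"training diverged at epoch {epoch} (train={tr_loss}, val={va_loss})"
            )
            exc.trace = trace
            raise exc
        if va_loss < best_val:
            best_val = va_loss
            best_epoch = epoch
            best = p.copy()

    evaluate(0)
    for epoch in range(cfg.max_epochs):
        lr = scheduled_lr(epoch, cfg)
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb = x_tr[idx]
            tb = t_tr[idx]
            hidden = 1.0 / (1.0 + np.exp(-(xb @ w1.T + b1)))
            out = hidden @ w2.T + b2
            d_out = (2.0 / len(idx)) * (out - tb)
            d_hidden = (d_out @ w2) * hidden * (1.0 - hidden)
            v_w2 *= mu
            v_w2 -= lr * (d_out.T @ hidden)
            v_b2 *= mu
            v_b2 -= lr * d_out.sum(axis=0)
            v_w1 *= mu
            v_w1 -= lr * (d_hidden.T @ xb)
            v_b1 *= mu
            v_b1 -= lr * d_hidden.sum(axis=0)
            w2 += v_w2
            b2 += v_b2
            w1 += v_w1
            b1 += v_b1
        completed = epoch + 1
        if completed % cfg.validate_every_epochs == 0 or completed == cfg.max_epochs:
            evaluate(completed)

    assert best is not None
    return best, _trace(records, best_epoch)


def _trace(records: list[tuple[int, float, float, float]], best_epoch: int) -> TrainingTrace:
    df = pd.DataFrame(records, columns=["epoch", "train_loss", "val_loss", "lr"])
    return TrainingTrace(records=df.astype({"epoch": int}), best_epoch=int(best_epoch))


def predict(params: NetworkParams, features: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """Network output de-normalized to screen pixels."""
    return np.asarray(forward(params, features)) * cfg.target_scale


def save_params(params: NetworkParams, cfg: TrainConfig, path: str | Path) -> None:
    """Serialize weights plus the training configuration to an .npz artifact."""
    np.savez(
        path,
        hidden_weights=params.hidden_weights,
        hidden_bias=params.hidden_bias,
        output_weights=params.output_weights,
        output_bias=params.output_bias,
        config=np.array(
            [
                cfg.learning_rate0,
                cfg.momentum,
                cfg.halve_every_epochs,
                cfg.batch_size,
                cfg.max_epochs,
                cfg.validate_every_epochs,
                cfg.seed,
                cfg.target_scale,
            ]
        ),
    )


def load_params(path: str | Path) -> tuple[NetworkParams, TrainConfig]:
    with np.load(path) as data:
        params = NetworkParams(
            hidden_weights=data["hidden_weights"],
            hidden_bias=data["hidden_bias"],
            output_weights=data["output_weights"],
            output_bias=data["output_bias"],
        )
        c = data["config"]
    cfg = TrainConfig(
        learning_rate0=float(c[0]),
        momentum=float(c[1]),
        halve_every_epochs=int(c[2]),
        batch_size=int(c[3]),
        max_epochs=int(c[4]),
        validate_every_epochs=int(c[5]),
        seed=int(c[6]),
        target_scale=float(c[7]),
    )
    return params, cfg
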