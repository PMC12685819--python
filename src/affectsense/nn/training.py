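"""Seeded mini-batch training with early stopping and plateau scheduling.

The loop mirrors the usual Keras-style contract: validation loss is monitored
every epoch; ReduceLROnPlateau halves the learning rate after ``patience``
epochs without improvement (floored at ``min_lr``); early stopping ends
training after its own patience and restores the weights of the best
validation epoch.  All shuffling and dropout draw from generators derived
from one seed, so a rerun with the same seed reproduces the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .optim import Adam

__all__ = ["TrainConfig", "TrainHistory", "PlateauScheduler", "EarlyStopping",
           "train_model"]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 50
    early_stop_patience: int = 8
    plateau_patience: int = 4
    plateau_factor: float = 0.5
    min_lr: float = 1e-6
    loss: str = "sparse_ce"  # "sparse_ce" | "focal" | "smooth_l1"
    focal_gamma: float = 2.0
    class_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau factor must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_metric": self.val_metric,
            "lr": self.lr,
        })


class PlateauScheduler:
    """Halve (by ``factor``) the learning rate after ``patience`` epochs without
    validation-loss improvement; never below ``min_lr``."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 4,
                 min_lr: float = 1e-6, min_delta: float = 1e-8):
        self.lr = lr
        self.factor, self.patience = factor, patience
        self.min_lr, self.min_delta = min_lr, min_delta
        self.best = np.inf
        self._bad = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self._bad = 0
        else:
            self._bad += 1
            if self._bad >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self._bad = 0
        return self.lr


class EarlyStopping:
    """Track the best validation loss; signal a stop after ``patience`` epochs
    without improvement."""

    def __init__(self, patience: int = 8, min_delta: float = 1e-8):
        self.patience, self.min_delta = patience, min_delta
        self.best = np.inf
        self.best_epoch = -1
        self._bad = 0

    def step(self, val_loss: float, epoch: int) -> bool:
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.best_epoch = epoch
            self._bad = 0
            return False
        self._bad += 1
        return self._bad >= self.patience


def _batched_eval(model, x: np.ndarray, loss_grad: Callable, y: np.ndarray,
                  batch_size: int) -> float:
    total, n = 0.0, x.shape[0]
    for i in range(0, n, batch_size):
        out = model.network.forward(x[i:i + batch_size], training=False)
        loss, _ = loss_grad(out, y[i:i + batch_size])
        total += loss * (min(i + batch_size, n) - i)
    return total / n


def train_model(
    model,
    loss_grad: Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]],
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    metric_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> TrainHistory:
    """Run the full training loop on a model exposing ``.network`` (a
    :class:`~affectsense.nn.layers.Sequential`).  Modifies the model in place
    and returns the epoch history; the model ends with the weights of the
    best validation epoch.
    """
    x_tr, y_tr = train
    x_va, y_va = val
    if x_tr.shape[0] != np.asarray(y_tr).shape[0]:
        raise ValueError("training inputs and targets disagree in length")
    net = model.network
    rng = np.random.default_rng(config.seed)
    net.set_rng(np.random.default_rng(rng.integers(0, 2**31 - 1)))
    opt = Adam(lr=config.lr)
    sched = PlateauScheduler(config.lr, config.plateau_factor,
                             config.plateau_patience, config.min_lr)
    stopper = EarlyStopping(config.early_stop_patience)
    history = TrainHistory()
    best_state: dict[str, np.ndarray] | None = None
    n = x_tr.shape[0]

    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        running, seen = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            out = net.forward(x_tr[idx], training=True)
            loss, dout = loss_grad(out, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {i // config.batch_size}"
                )
            net.backward(dout)
            opt.lr = sched.lr
            trainable = net.trainable_param_items()
            grads = net.grad_items()
            opt.step(trainable, {k: grads[k] for k in trainable})
            running += loss * idx.size
            seen += idx.size

        val_loss = _batched_eval(model, x_va, loss_grad, y_va, config.batch_size)
        history.train_loss.append(running / seen)
        history.val_loss.append(val_loss)
        history.lr.append(sched.lr)
        if metric_fn is not None:
            pred = model.predict_batched(x_va, batch_size=config.batch_size)
            history.val_metric.append(metric_fn(pred, y_va))
        else:
            history.val_metric.append(np.nan)

        improved = val_loss < stopper.best - stopper.min_delta
        stop = stopper.step(val_loss, epoch)
        if improved:
            best_state = {k: v.copy() for k, v in net.state_items().items()}
        sched.step(val_loss)
        if stop:
            break

    if best_state is not None:
        net.load_state(best_state)
    history.best_epoch = stopper.best_epoch
    return history
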