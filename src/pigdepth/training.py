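"""Training: shuffled 7:3 split, summed per-target MSE loss, mini-batch
Adam, best-on-validation checkpoint retention.

The loss is the sum over the six targets of their per-target mean squared
errors, in raw label units (kg^2 + cm^2, no per-target weighting or
standardization). "Iterations" in the reference hyper-parameters is read
as epochs; validation loss is computed on the full validation set after
every epoch and the parameters of the best epoch are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from pigdepth.labels import N_TARGETS

__all__ = [
    "TrainConfig",
    "TrainResult",
    "TrainingDivergedError",
    "split_dataset",
    "total_loss",
    "Adam",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 150
    split_ratio: float = 0.7
    shuffle_seed: int = 0
    # Adam defaults beyond the learning rate follow the published optimizer
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if not 0 < self.split_ratio < 1:
            raise ValueError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")


@dataclass
class TrainResult:
    val_loss_history: list[float]
    best_epoch: int  # 1-based
    best_val_loss: float
    best_weights: list[np.ndarray]

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss_history)


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}; training aborted")
        self.epoch = epoch


def split_dataset(data, ratio: float, seed: int):
    """Shuffled disjoint/exhaustive partition; the training part has
    round(ratio * n) samples (round half up)."""
    n = len(data)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n_train = int(math.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    if isinstance(data, np.ndarray):
        return data[train_idx], data[val_idx]
    if hasattr(data, "__getitem__") and not isinstance(data, (list, tuple)):
        try:
            return data[train_idx], data[val_idx]
        except (TypeError, KeyError, IndexError):
            pass
    return [data[i] for i in train_idx], [data[i] for i in val_idx]


def total_loss(estimates, measured) -> float:
    """Summed per-target MSE: sum_V mean_m (y_m^V - yhat_m^V)^2."""
    est = np.asarray(estimates, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.ndim == 1:
        est = est[None]
    if meas.ndim == 1:
        meas = meas[None]
    if est.shape != meas.shape or est.ndim != 2 or est.shape[1] != N_TARGETS:
        raise ValueError(
            f"expected matching (m, {N_TARGETS}) batches, got "
            f"{est.shape} vs {meas.shape}"
        )
    return float(np.sum(np.mean((meas - est) ** 2, axis=0)))


def _loss_grad(estimates, measured) -> np.ndarray:
    """d total_loss / d estimates for a batch: 2 (yhat - y) / m."""
    m = estimates.shape[0]
    return 2.0 * (estimates - measured) / m


class Adam:
    """Adam optimizer over a list of trainable parameters (with .grad)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _val_loss(model, images, labels, batch_size=128) -> float:
    preds = model.predict(images, batch_size=batch_size)
    return total_loss(preds, labels)


def train(model, images, labels, config: TrainConfig = TrainConfig()) -> TrainResult:
    """Train a (trainable) regressor on gray images and 6-label rows.

    Splits the data 7:3 (shuffled, seeded), runs mini-batch Adam on the
    summed per-target MSE, evaluates the validation loss each epoch and
    retains the parameters of the best epoch. On return the model holds the
    retained best parameters.
    """
    if not getattr(model, "trainable", False):
        raise NotImplementedError(
            f"backbone {getattr(model, 'spec', None)} has no gradient support "
            "in this NumPy engine; train the 'tinycnn' backbone"
        )
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=float)
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    idx = np.arange(len(images))
    train_idx, val_idx = split_dataset(idx, config.split_ratio, config.shuffle_seed)
    x_tr, y_tr = images[train_idx], labels[train_idx]
    x_va, y_va = images[val_idx], labels[val_idx]

    opt = Adam(
        model.trainable_parameters(),
        config.learning_rate,
        config.beta1,
        config.beta2,
        config.eps,
    )
    rng = np.random.default_rng(config.shuffle_seed)
    history: list[float] = []
    best_loss = math.inf
    best_epoch = 0
    best_weights = model.get_weights()

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(x_tr), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            model.zero_grads()
            preds = model.forward(xb, training=True)
            loss = total_loss(preds, yb)
            if not math.isfinite(loss):
                raise TrainingDivergedError(epoch)
            model.backward(_loss_grad(preds, yb))
            opt.step()
        vloss = _val_loss(model, x_va, y_va)
        if not math.isfinite(vloss):
            raise TrainingDivergedError(epoch)
        history.append(vloss)
        if vloss < best_loss:
            best_loss = vloss
            best_epoch = epoch
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    return TrainResult(
        val_loss_history=history,
        best_epoch=best_epoch,
        best_val_loss=best_loss,
        best_weights=best_weights,
    )
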