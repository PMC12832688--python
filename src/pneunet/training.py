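"""Optimization recipe: Adam on binary cross-entropy with L2 kernel decay,
dropout, early stopping on validation loss, and best-checkpoint selection.

Defaults mirror the published protocol: Adam(lr=0.001, beta1=0.9,
beta2=0.999), batch 32, up to 50 epochs, early-stopping patience 7,
dropout 0.3, L2 lambda 0.001.  "Improvement" means a strict decrease of
validation loss; the counter restarts at the last improvement, so a best
epoch b with patience p halts at epoch b + p.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .model import PneuNet

logger = logging.getLogger(__name__)

EPS = 1e-7

__all__ = ["TrainConfig", "TrainHistory", "bce_loss", "l2_penalty",
           "early_stopping_trace", "train"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 7
    l2_lambda: float = 0.001
    dropout_rate: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.learning_rate < 0 or self.l2_lambda < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss, "train_acc": self.train_acc,
            "val_loss": self.val_loss, "val_acc": self.val_acc,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy -[y ln p + (1-y) ln(1-p)] with
    probabilities clamped to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))


def l2_penalty(model: PneuNet, lam: float) -> float:
    """lam * sum of squared kernel entries (biases and batch-norm
    parameters excluded)."""
    params = model.params()
    return lam * float(sum(np.sum(params[k].astype(np.float64) ** 2)
                           for k in model.kernel_names()))


def early_stopping_trace(val_losses, patience: int) -> tuple[int, int]:
    """Replay early stopping on a validation-loss trace.

    Returns 1-based (stopped_epoch, best_epoch): best is the earliest
    minimum; training halts at the first epoch reaching ``patience``
    consecutive epochs without strict improvement, or at the end of the
    trace.
    """
    losses = list(val_losses)
    if not losses:
        raise ValueError("empty validation-loss trace")
    best, best_epoch, wait = np.inf, 0, 0
    for epoch, loss in enumerate(losses, start=1):
        if loss < best:
            best, best_epoch, wait = loss, epoch, 0
        else:
            wait += 1
            if wait >= patience:
                return epoch, best_epoch
    return len(losses), best_epoch


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            p -= c.learning_rate * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + 1e-8)


def _evaluate(model: PneuNet, x, y, lam: float, batch_size: int) -> tuple[float, float]:
    p = model.predict(x, batch_size=batch_size)
    loss = bce_loss(p, y) + l2_penalty(model, lam)
    acc = float(np.mean((p >= 0.5) == (np.asarray(y) >= 0.5)))
    return loss, acc


def train(
    model: PneuNet,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig | None = None,
) -> tuple[dict, TrainHistory]:
    """Fit the model; returns (best checkpoint state, full history).

    The checkpoint state is a dict with deep-copied ``params`` and
    ``buffers`` captured at every new validation-loss minimum, plus
    ``best_epoch`` and ``val_loss_at_best``.  Shuffling and dropout are
    seeded by ``cfg.seed``; dropout is active only during training.
    The tracked loss (train and validation) includes the L2 term.
    """
    cfg = cfg or TrainConfig()
    xtr, ytr = train_data
    xva, yva = val_data
    if len(xtr) == 0:
        raise ValueError("empty training set")
    shuffle_rng = np.random.default_rng(cfg.seed)
    model.set_dropout_rng(np.random.default_rng(cfg.seed + 1))
    for blk in model.blocks:
        blk["drop"].rate = cfg.dropout_rate
    model.head_drop.rate = cfg.dropout_rate

    params = model.params()
    adam = _Adam(params, cfg)
    kernels = set(model.kernel_names())
    history = TrainHistory()
    best_loss, wait = np.inf, 0
    checkpoint: dict = {}

    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(len(xtr))
        batch_losses, batch_accs = [], []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            p = model.forward(xb, train=True)
            loss = bce_loss(p, yb) + l2_penalty(model, cfg.l2_lambda)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, batch {start // cfg.batch_size}")
            # d(mean BCE)/d(logit) = (p - y)/B for a sigmoid output
            dlogit = (p - yb).astype(model.dtype) / len(yb)
            grads = model.backward(dlogit)
            if cfg.l2_lambda:
                for k in kernels:
                    grads[k] = grads[k] + 2.0 * cfg.l2_lambda * params[k]
            adam.step(params, grads)
            batch_losses.append(loss)
            batch_accs.append(float(np.mean((p >= 0.5) == (yb >= 0.5))))

        # precise-BN refresh so validation sees statistics that match the
        # current weights rather than a lagging moving average
        model.recalibrate_bn(xtr, cfg.batch_size)
        val_loss, val_acc = _evaluate(model, xva, yva, cfg.l2_lambda, cfg.batch_size)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.train_acc.append(float(np.mean(batch_accs)))
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        logger.info("epoch %d: train_loss=%.4f train_acc=%.4f val_loss=%.4f val_acc=%.4f",
                    epoch, history.train_loss[-1], history.train_acc[-1], val_loss, val_acc)

        if val_loss < best_loss:
            best_loss, wait = val_loss, 0
            checkpoint = {
                "params": {k: v.copy() for k, v in params.items()},
                "buffers": {k: v.copy() for k, v in model.buffers().items()},
                "best_epoch": epoch,
                "val_loss_at_best": val_loss,
            }
            history.best_epoch = epoch
        else:
            wait += 1
            if wait >= cfg.patience:
                logger.info("early stopping at epoch %d (best %d)", epoch, history.best_epoch)
                history.stopped_epoch = epoch
                break
    if history.stopped_epoch == 0:
        history.stopped_epoch = len(history.val_loss)
    return checkpoint, history


def restore(model: PneuNet, checkpoint: dict) -> PneuNet:
    """Load a training checkpoint state back into a model."""
    model.set_params(checkpoint["params"])
    model.set_buffers(checkpoint["buffers"])
    return model
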