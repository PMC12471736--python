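"""Optimization of the additive network.

Adam with L2 weight decay on binary cross-entropy, a reduce-on-plateau
learning-rate schedule, early stopping, and best-weight restoration.  The
backward pass is written out explicitly (the architecture is a stack of
scalar-input two-hidden-layer MLPs, so the gradient is a few einsums); it is
verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import FeatureTable
from .nam import NAMParams, _forward_stack

EPS_CLIP = 1e-7
#: an improvement must beat the incumbent by this much to reset patience
IMPROVE_TOL = 1e-6


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 1e-5
    max_epochs: int = 150
    early_stop_patience: int = 20
    scheduler_patience: int = 10
    scheduler_factor: float = 0.5
    batch_size: int = 64
    monitor: str = "loss"  # "loss" or "accuracy" on the monitor set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.monitor not in ("loss", "accuracy"):
            raise ValueError("monitor must be 'loss' or 'accuracy'")
        if not 0 < self.scheduler_factor < 1:
            raise ValueError("scheduler_factor must be in (0, 1)")
        for name in ("learning_rate", "max_epochs", "early_stop_patience",
                     "scheduler_patience", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainTrace:
    """Per-epoch record of the optimization, plus best/stop bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    monitor_value: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_epoch: int = 0
    monitor: str = "loss"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "monitor": self.monitor_value,
            "lr": self.learning_rate,
        })


def bce_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    p = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _backward(params: NAMParams, X: np.ndarray, dlogit: np.ndarray,
              hidden, dropout_masks) -> dict[str, np.ndarray | float]:
    """Gradient of the batch loss w.r.t. every parameter array.

    ``dlogit`` is dL/dlogit per sample; hidden activations come from the
    forward pass (post-dropout where applicable).
    """
    Z1, A1, Z2, A2 = hidden
    rate = params.config.dropout_rate
    dcontrib = np.broadcast_to(dlogit[:, None], A2.shape[:2])   # (n, p)
    gW3 = np.einsum("npk,np->pk", A2, dcontrib)
    gB3 = dcontrib.sum(axis=0)
    dA2 = dcontrib[:, :, None] * params.W3[None]                # (n, p, h2)
    if dropout_masks is not None and rate > 0:
        dA2 = dA2 * dropout_masks[1] / (1.0 - rate)
    dZ2 = dA2 * (Z2 > 0)
    gW2 = np.einsum("nph,npk->phk", A1, dZ2)
    gB2 = dZ2.sum(axis=0)
    dA1 = np.einsum("npk,phk->nph", dZ2, params.W2)
    if dropout_masks is not None and rate > 0:
        dA1 = dA1 * dropout_masks[0] / (1.0 - rate)
    dZ1 = dA1 * (Z1 > 0)
    gW1 = np.einsum("np,nph->ph", X, dZ1)
    gB1 = dZ1.sum(axis=0)
    return {"W1": gW1, "B1": gB1, "W2": gW2, "B2": gB2, "W3": gW3,
            "B3": gB3, "bias": float(dlogit.sum())}


class _Adam:
    """Plain Adam; L2 weight decay is added to the gradient of weights only."""

    def __init__(self, params: NAMParams, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.keys = ["W1", "B1", "W2", "B2", "W3", "B3", "bias"]
        self.m = {k: np.zeros_like(self._get(k)) for k in self.keys}
        self.v = {k: np.zeros_like(self._get(k)) for k in self.keys}

    def _get(self, key: str):
        return np.asarray(getattr(self.params, key), dtype=float)

    def step(self, grads: dict) -> None:
        self.t += 1
        decayed = {"W1", "W2", "W3"}
        for k in self.keys:
            g = np.asarray(grads[k], dtype=float)
            if k in decayed and self.wd > 0:
                g = g + self.wd * self._get(k)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if k == "bias":
                self.params.bias = float(self._get(k) - update)
            else:
                getattr(self.params, k)[...] -= update


def _evaluate(params: NAMParams, X: np.ndarray, y: np.ndarray,
              monitor: str) -> tuple[float, float]:
    """(bce loss, monitor value) in evaluation mode."""
    contrib, _ = _forward_stack(params, X)
    logits = contrib.sum(axis=1) + params.bias
    probs = expit(logits)
    loss = bce_loss(probs, y)
    if monitor == "loss":
        return loss, loss
    acc = float(np.mean((probs >= 0.5).astype(int) == y))
    return loss, acc


def train_nam(init: NAMParams, train: FeatureTable,
              monitor_set: FeatureTable,
              config: TrainConfig) -> tuple[NAMParams, TrainTrace]:
    """Train the additive network and restore the best-epoch weights.

    The monitor value (loss or accuracy on ``monitor_set``) drives both the
    plateau scheduler (lr *= factor after ``scheduler_patience`` epochs
    without improvement) and early stopping (``early_stop_patience``).
    Fully reproducible under ``config.seed``, including batch shuffling and
    dropout masks.
    """
    params = init.copy()
    X, y = train.values, train.labels.astype(float)
    Xm, ym = monitor_set.values, monitor_set.labels.astype(float)
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    opt = _Adam(params, config.learning_rate, config.weight_decay)
    rate = params.config.dropout_rate
    h1, h2 = params.config.hidden_sizes

    better = ((lambda a, b: a < b - IMPROVE_TOL) if config.monitor == "loss"
              else (lambda a, b: a > b + IMPROVE_TOL))
    best_value = np.inf if config.monitor == "loss" else -np.inf
    best_params = params.copy()
    best_epoch = 0
    sched_wait = 0
    stop_wait = 0
    trace = TrainTrace(monitor=config.monitor)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb, yb = X[idx], y[idx]
            masks = None
            if rate > 0:
                masks = (rng.random((len(idx), params.p, h1)) >= rate,
                         rng.random((len(idx), params.p, h2)) >= rate)
            contrib, hidden = _forward_stack(params, Xb, masks,
                                             keep_hidden=True)
            logits = contrib.sum(axis=1) + params.bias
            probs = expit(logits)
            if not np.isfinite(logits).all():
                raise FloatingPointError(
                    f"non-finite logits at epoch {epoch}; aborting")
            dlogit = (probs - yb) / len(idx)
            grads = _backward(params, Xb, dlogit, hidden, masks)
            opt.step(grads)

        train_loss, _ = _evaluate(params, X, y, "loss")
        _, monitor_value = _evaluate(params, Xm, ym, config.monitor)
        trace.train_loss.append(train_loss)
        trace.monitor_value.append(monitor_value)
        trace.learning_rate.append(opt.lr)

        if better(monitor_value, best_value):
            best_value = monitor_value
            best_params = params.copy()
            best_epoch = epoch
            sched_wait = 0
            stop_wait = 0
        else:
            sched_wait += 1
            stop_wait += 1
            if sched_wait >= config.scheduler_patience:
                opt.lr *= config.scheduler_factor
                sched_wait = 0
            if stop_wait >= config.early_stop_patience:
                break

    trace.best_epoch = best_epoch if best_epoch else 1
    trace.stop_epoch = len(trace.train_loss)
    return best_params, trace
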