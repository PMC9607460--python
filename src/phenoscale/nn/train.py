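"""Adam optimizer, MAE loss and the mini-batch training loop."""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..errors import TrainingError
from .layers import Sequential


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mae_loss(pred, target):
    """Mean absolute error and its (sub)gradient wrt pred."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def predict_batched(model: Sequential, x, batch_size=64):
    outs = [
        model.forward(x[i : i + batch_size], train=False)
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def fit(
    model: Sequential,
    x_train,
    y_train,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    epochs: int = 30,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
    lr_decay: float = 0.3,
    restore_best: bool = True,
) -> dict:
    """Train with Adam on the MAE objective; returns per-epoch history
    {"train_mae": [...], "val_mae": [...]}.

    Targets are expected already standardized by the caller. The learning
    rate is multiplied by ``lr_decay`` after 2/3 of the epochs; when a
    validation set is given and ``restore_best`` is set, the weights of
    the best-validation epoch are restored at the end (early-stopping
    checkpoint), which damps run-to-run variance of the final model.
    Raises :class:`TrainingError` with the epoch index if the loss goes
    non-finite.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr)
    n = len(x_train)
    y_train = y_train.reshape(n, -1)
    history = {"train_mae": [], "val_mae": []}
    best = None
    for epoch in range(epochs):
        if epoch == (2 * epochs) // 3:
            opt.lr = lr * lr_decay
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            pred = model.forward(x_train[idx], train=True)
            loss, dpred = mae_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingError("non-finite training loss", epoch=epoch)
            model.backward(dpred)
            opt.step(model.grads)
            losses.append(loss)
        history["train_mae"].append(float(np.mean(losses)))
        if x_val is not None and len(x_val):
            vp = predict_batched(model, x_val, batch_size)
            vloss, _ = mae_loss(vp, y_val.reshape(len(y_val), -1))
            history["val_mae"].append(vloss)
            if restore_best and (best is None or vloss < best[0]):
                best = (vloss, {k: v.copy() for k, v in model.get_state().items()})
    if best is not None:
        model.set_state(best[1])
    return history
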