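"""Desk-scale training loop for the dense denoising network.

Treats the rib shadow as structured noise: inputs are raw images, targets
the rib-suppressed ground truth, and the network learns the mapping under
the composite PSNR/MS-SSIM/L1 loss with the Adam optimiser.  Everything is
seeded and single-threaded numpy, sized for small phantom corpora rather
than GPU-scale corpora.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ribsuppress.sadxnet.losses import LossConfig, composite_loss
from ribsuppress.sadxnet.network import NetConfig, SADXNet

__all__ = ["TrainConfig", "TrainHistory", "TrainingError", "train", "predict", "rmse"]


class TrainingError(RuntimeError):
    """Raised when the loss turns non-finite."""


@dataclass
class TrainConfig:
    """Optimisation settings: Adam, initial learning rate 0.001, 200 epochs max."""

    max_epochs: int = 200
    lr: float = 0.001
    batch_size: int = 1
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class TrainHistory:
    """Per-epoch mean training loss and validation RMSE (NaN when no val set)."""

    train_loss: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_rmse: float = float("inf")

    def save_csv(self, path):
        with open(Path(path), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_rmse"])
            for i, (tl, vr) in enumerate(zip(self.train_loss, self.val_rmse)):
                w.writerow([i, tl, vr])


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square error, the evaluation metric for suppressed scans."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


class _Adam:
    def __init__(self, params: dict, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self, params: dict):
        self.t += 1
        c = self.cfg
        bc1 = 1 - c.beta1 ** self.t
        bc2 = 1 - c.beta2 ** self.t
        for k, p in params.items():
            if p.grad is None:
                continue
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * p.grad
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * p.grad ** 2
            p.data -= c.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + c.eps)


def _stack(pairs: Sequence, idx) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([np.asarray(pairs[i][0], dtype=float) for i in idx])[:, None]
    ys = np.stack([np.asarray(pairs[i][1], dtype=float) for i in idx])[:, None]
    return xs, ys


def train(pairs: Sequence, net_cfg: NetConfig = NetConfig(),
          train_cfg: TrainConfig = TrainConfig(),
          loss_cfg: LossConfig = LossConfig(),
          val_pairs: Optional[Sequence] = None,
          net: Optional[SADXNet] = None) -> tuple[SADXNet, TrainHistory]:
    """Train the network on (input, target) image pairs.

    Records the mean training loss per epoch and, when a validation set is
    given, the mean validation RMSE; the parameter state with the best
    validation RMSE (or, without a validation set, the best epoch training
    loss) is restored at the end.  Zero epochs leave the freshly initialised
    (or provided) network untouched.  A non-finite loss aborts with
    diagnostics.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    net = net or SADXNet(net_cfg, seed=train_cfg.seed)
    history = TrainHistory()
    if train_cfg.max_epochs == 0:
        return net, history
    opt = _Adam(net.params, train_cfg)
    rng = np.random.default_rng(train_cfg.seed)
    best_state = None
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for b0 in range(0, len(order), train_cfg.batch_size):
            idx = order[b0:b0 + train_cfg.batch_size]
            xs, ys = _stack(pairs, idx)
            pred = net.forward(xs, training=True)
            loss = composite_loss(pred, ys, loss_cfg)
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss {loss.data} at epoch {epoch}, batch {b0}")
            loss.backward()
            opt.step(net.params)
            losses.append(loss.item())
        history.train_loss.append(float(np.mean(losses)))
        if val_pairs:
            vr = float(np.mean([rmse(net.predict(x), y) for x, y in val_pairs]))
        else:
            vr = float("nan")
        history.val_rmse.append(vr)
        if val_pairs:
            if vr < history.best_val_rmse:
                history.best_val_rmse = vr
                history.best_epoch = epoch
                best_state = net.state_dict()
        elif history.train_loss[-1] == min(history.train_loss):
            history.best_epoch = epoch
            best_state = net.state_dict()
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, history


def predict(image: np.ndarray, net: SADXNet) -> np.ndarray:
    """Suppress one image with a trained network (eval-mode forward pass)."""
    return net.predict(image)
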