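"""Optimizers and the shared mini-batch training loop."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network
from .ops import Param


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * np.square(p.grad)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def dice_loss_and_grad(probs: np.ndarray, targets: np.ndarray):
    """Smoothed Dice loss over the whole batch and its gradient w.r.t. probs.

    loss = 1 - (2*sum(p*y) + 1) / (sum(p) + sum(y) + 1)
    """
    if probs.shape != targets.shape:
        raise ValueError("shape mismatch between prediction and target")
    num = 2.0 * float((probs * targets).sum()) + 1.0
    den = float(probs.sum()) + float(targets.sum()) + 1.0
    loss = 1.0 - num / den
    dprobs = -(2.0 * targets * den - num) / (den * den)
    return loss, dprobs.astype(np.float32)


def batch_iou(probs: np.ndarray, targets: np.ndarray,
              threshold: float = 0.5) -> float:
    """Mean per-image IoU of thresholded predictions (empty∩empty -> 1)."""
    pred = probs > threshold
    gt = targets > 0.5
    inter = (pred & gt).sum(axis=(1, 2, 3)).astype(np.float64)
    union = (pred | gt).sum(axis=(1, 2, 3)).astype(np.float64)
    scores = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return float(scores.mean())


@dataclass
class FitResult:
    history: list[dict]
    best_val_iou: float
    best_epoch: int


def fit(net: Network, x_train: np.ndarray, y_train: np.ndarray,
        x_val: np.ndarray, y_val: np.ndarray, *, epochs: int,
        learning_rate: float, batch_size: int, rng: np.random.Generator,
        log=None, eval_batch: int = 16) -> FitResult:
    """Train ``net`` with Dice loss + Adam, retaining best-val-IoU weights.

    History gets one entry per epoch: ``{epoch, train_loss, val_iou}``.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    opt = Adam(net.params(), lr=learning_rate)
    history: list[dict] = []
    best = (-1.0, -1, None)  # (val_iou, epoch, state)
    n = len(x_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            tape = net.forward(xb, train=True)
            probs = tape.acts[net.output_name]
            loss, dprobs = dice_loss_and_grad(probs, yb)
            opt.zero_grad()
            net.backward(tape, dprobs)
            opt.step()
            losses.append(loss)
        val_iou = evaluate_iou(net, x_val, y_val, batch=eval_batch)
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(losses)),
                        "val_iou": val_iou})
        if val_iou > best[0]:
            best = (val_iou, epoch, net.state_dict())
        if log is not None:
            log.info("epoch %d/%d train_loss=%.4f val_iou=%.4f",
                     epoch + 1, epochs, history[-1]["train_loss"], val_iou)
    if best[2] is not None:
        net.load_state_dict(best[2])
    return FitResult(history=history, best_val_iou=best[0], best_epoch=best[1])


def evaluate_iou(net: Network, x: np.ndarray, y: np.ndarray,
                 batch: int = 16) -> float:
    if len(x) == 0:
        return float("nan")
    scores = []
    for start in range(0, len(x), batch):
        probs = net(x[start : start + batch])
        scores.append(batch_iou(probs, y[start : start + batch])
                      * len(x[start : start + batch]))
    return float(np.sum(scores) / len(x))
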