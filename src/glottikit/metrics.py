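"""Shared evaluation metrics: IoU, Dice loss, Pearson correlation, MSE."""

from __future__ import annotations

import numpy as np

__all__ = ["iou", "dice_loss", "pearson", "mse"]


def _as_binary(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def iou(a, b) -> float:
    """Intersection over union of two binary masks.

    Both masks empty counts as perfect agreement (returns 1.0).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ab = _as_binary(a, "a")
    bb = _as_binary(b, "b")
    union = np.logical_or(ab, bb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ab, bb).sum() / union)


def dice_loss(y, yhat) -> float:
    """Smoothed Dice loss: 1 - (2*sum(y*yhat) + 1) / (sum(y) + sum(yhat) + 1).

    Accepts binary masks or soft predictions in [0, 1]; the +1 smoothing term
    makes the all-empty case exactly 0.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    num = 2.0 * (y * yhat).sum() + 1.0
    den = y.sum() + yhat.sum() + 1.0
    return float(1.0 - num / den)


def pearson(x, y) -> float:
    """Sample Pearson correlation with (n-1)*s_x*s_y denominator.

    Returns 0.0 if either series has zero variance, so correlation maps over
    constant pixels stay well defined.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum() / (n - 1))
    sy = np.sqrt((dy * dy).sum() / (n - 1))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float((dx * dy).sum() / ((n - 1) * sx * sy))


def mse(a, b) -> float:
    """Mean squared element-wise difference."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))
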