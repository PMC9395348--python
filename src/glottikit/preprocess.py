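"""Intensity normalization for frames and masks.

Frames map linearly from 8-bit [0, 255] to [-1, 1]; masks threshold at 127.5
to {0, 1} (soft network outputs use 0.5 instead, see ``binarize``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["normalize_frame", "denormalize_frame", "normalize_mask", "binarize"]

MASK_THRESHOLD_8BIT = 127.5
SOFT_THRESHOLD = 0.5


def normalize_frame(raw) -> np.ndarray:
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError("empty image")
    if raw.min() < 0 or raw.max() > 255:
        raise ValueError("raw intensities must lie in [0, 255]")
    return raw.astype(np.float64) * (2.0 / 255.0) - 1.0


def denormalize_frame(frame) -> np.ndarray:
    """Inverse of :func:`normalize_frame` (float result, not rounded)."""
    frame = np.asarray(frame, dtype=np.float64)
    return (frame + 1.0) * (255.0 / 2.0)


def normalize_mask(raw) -> np.ndarray:
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError("empty image")
    return (raw > MASK_THRESHOLD_8BIT).astype(np.uint8)


def binarize(soft, threshold: float = SOFT_THRESHOLD) -> np.ndarray:
    """Binarize a soft prediction in [0, 1]."""
    return (np.asarray(soft) > threshold).astype(np.uint8)
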