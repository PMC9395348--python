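"""Protocol-level experiments: channel/skip ablation, dataset-size ablation.

Each experiment trains one segnet per configuration at the run seed,
retains the best-validation checkpoint, and evaluates on a fixed held-out
test set, returning a tidy results table plus per-run convergence curves.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .segnet import (SegNetSpec, TrainConfig, build_segnet, evaluate_segnet,
                     train_segnet)

__all__ = ["channel_ablation", "dataset_size_ablation"]

log = logging.getLogger(__name__)

DEFAULT_CHANNELS = (1, 2, 4, 8, 16, 32, 64, 128, 256)


def channel_ablation(train_data, test_data, base_spec: SegNetSpec,
                     config: TrainConfig, channels=None,
                     skip_settings=(True, False)):
    """One training run per (latent channels, skips) combination.

    Returns ``(table, curves)``: rows of
    ``f_L, skips, best_val_iou, test_iou`` and a dict mapping
    ``(f_L, skips)`` to the per-epoch history DataFrame.
    """
    channels = list(DEFAULT_CHANNELS if channels is None else channels)
    if not channels:
        raise ValueError("channel list must not be empty")
    rows, curves = [], {}
    for skips in skip_settings:
        for f_l in channels:
            spec = replace(base_spec, latent_channels=int(f_l), skips=skips)
            model = build_segnet(spec, seed=config.seed)
            history = train_segnet(model, train_data, config)
            test_iou = evaluate_segnet(model, test_data)
            rows.append({"f_L": int(f_l), "skips": skips,
                         "best_val_iou": float(history["val_iou"].max()),
                         "test_iou": test_iou})
            curves[(int(f_l), skips)] = history
            log.info("f_L=%d skips=%s test_iou=%.3f", f_l, skips, test_iou)
    return pd.DataFrame(rows), curves


def dataset_size_ablation(train_data, test_data, spec: SegNetSpec,
                          config: TrainConfig, fractions=(0.1, 0.25, 0.5, 1.0)):
    """Train on random subsets of the training data; fixed test set.

    Returns ``(table, curves)`` with rows ``fraction, n_train, val_iou,
    test_iou``.
    """
    frames, masks = train_data
    n = len(frames)
    rows, curves = [], {}
    rng = np.random.default_rng(config.seed)
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        k = n if frac == 1.0 else max(2, int(round(n * frac)))
        idx = rng.permutation(n)[:k] if k < n else np.arange(n)
        model = build_segnet(spec, seed=config.seed)
        history = train_segnet(model, (frames[idx], masks[idx]), config)
        test_iou = evaluate_segnet(model, test_data)
        rows.append({"fraction": float(frac), "n_train": int(k),
                     "val_iou": float(history["val_iou"].max()),
                     "test_iou": test_iou})
        curves[float(frac)] = history
        log.info("fraction=%.2f test_iou=%.3f", frac, test_iou)
    return pd.DataFrame(rows), curves
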