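"""Lean decoders: minimal upsampling-convolution stacks over the latent.

A decoder is UC blocks of [Upsample(s) -> convs x (3x3 conv, no bias -> BN
-> ReLU)] followed by a bias-free 1x1 projection to one channel + sigmoid,
where the per-block scale s = upscale_total**(1/UC) (16, 4, 2 for UC = 1, 2,
4 at a total of 16).  With L = UC * convs_per_block convolution layers of f
filters, the trainable parameter count is exactly

    W = 12 f + (L - 1) (9 f^2 + 2 f)

(first 3x3 conv from the single latent channel: 9f weights + 2f batchnorm;
each further conv layer: 9f^2 + 2f; output projection: f).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import (BatchNorm2D, Conv2D, Network, ReLU, Sigmoid, Upsample,
                 evaluate_iou, fit)
from .quantization import uint8_to_latent
from .segnet import TrainConfig

__all__ = ["DecoderSpec", "decoder_param_count", "build_lean_decoder",
           "train_lean_decoder", "decoder_grid_experiment", "PAPER_GRID"]

log = logging.getLogger(__name__)

BLOCK_CHOICES = (1, 2, 4)
CONV_CHOICES = (1, 2)
FILTER_CHOICES = (1, 2, 4, 8)

#: the full evaluation grid: 3 block counts x 2 conv depths x 4 filter sizes
PAPER_GRID = [
    {"blocks": b, "convs_per_block": c, "filters": f}
    for c in CONV_CHOICES for b in BLOCK_CHOICES for f in FILTER_CHOICES
]


@dataclass(frozen=True)
class DecoderSpec:
    blocks: int
    convs_per_block: int
    filters: int
    interpolation: str = "nearest"
    upscale_total: int = 16

    def __post_init__(self):
        if self.blocks < 1 or self.convs_per_block < 1 or self.filters < 1:
            raise ValueError("blocks, convs_per_block, filters must be >= 1")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError("interpolation must be 'nearest' or 'bilinear'")
        self.block_scale  # validates integrality

    @property
    def block_scale(self) -> int:
        s = round(self.upscale_total ** (1.0 / self.blocks))
        if s ** self.blocks != self.upscale_total:
            raise ValueError(
                f"upscale_total={self.upscale_total} has no integer "
                f"per-block scale for {self.blocks} blocks")
        return s


def decoder_param_count(blocks: int, convs_per_block: int,
                        filters: int) -> int:
    """Exact trainable-parameter count of a lean decoder configuration."""
    if blocks < 1 or convs_per_block < 1 or filters < 1:
        raise ValueError("all arguments must be positive")
    layers = blocks * convs_per_block
    f = filters
    return 12 * f + (layers - 1) * (9 * f * f + 2 * f)


def build_lean_decoder(spec: DecoderSpec, latent_height: int,
                       latent_width: int, seed: int = 0) -> Network:
    """Build the decoder network; its trainable count matches the formula."""
    rng = np.random.default_rng(seed)
    s = spec.block_scale
    net = Network()
    c_in = 1
    for b in range(spec.blocks):
        net.add(f"up{b}", Upsample(s, mode=spec.interpolation))
        for j in range(spec.convs_per_block):
            name = f"b{b}c{j}"
            net.add(f"{name}_conv",
                    Conv2D(c_in, spec.filters, 3, bias=False, rng=rng))
            net.add(f"{name}_bn", BatchNorm2D(spec.filters))
            net.add(f"{name}_act", ReLU())
            c_in = spec.filters
    net.add("logit", Conv2D(c_in, 1, 1, bias=False, rng=rng))
    net.add("prob", Sigmoid())
    expected = decoder_param_count(spec.blocks, spec.convs_per_block,
                                   spec.filters)
    assert net.n_parameters() == expected, \
        f"introspected {net.n_parameters()} != formula {expected}"
    return net


def _latents_to_batch(latents) -> np.ndarray:
    """Accept float latents or uint8-coded ones; return (N,1,h,w) float32."""
    arr = np.asarray(latents)
    if arr.dtype == np.uint8:
        arr = uint8_to_latent(arr)
    arr = arr.astype(np.float32)
    if arr.ndim == 3:
        arr = arr[:, None]
    return arr


def train_lean_decoder(decoder: Network, latents, masks,
                       config: TrainConfig) -> pd.DataFrame:
    """Dice-loss training of a decoder on (latent, mask) pairs.

    ``latents`` may be float arrays or uint8-coded images (the on-disk
    format); uint8 inputs pass through the fixed [0, 6] codec first.
    """
    x = _latents_to_batch(latents)
    y = np.asarray(masks, dtype=np.float32)
    if y.ndim == 3:
        y = y[:, None]
    if len(x) != len(y):
        raise ValueError("latent and mask counts differ")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(len(x) * config.validation_fraction)))
    order = rng.permutation(len(x))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx = order
    result = fit(decoder, x[train_idx], y[train_idx], x[val_idx], y[val_idx],
                 epochs=config.epochs, learning_rate=config.learning_rate,
                 batch_size=config.batch_size, rng=rng, log=log)
    return pd.DataFrame(result.history)


def evaluate_lean_decoder(decoder: Network, latents, masks) -> float:
    x = _latents_to_batch(latents)
    y = np.asarray(masks, dtype=np.float32)
    if y.ndim == 3:
        y = y[:, None]
    return evaluate_iou(decoder, x, y)


def decoder_grid_experiment(latents, masks, config: TrainConfig,
                            grid=None, test_latents=None, test_masks=None,
                            upscale_total: int = 16,
                            dry_run: bool = False) -> pd.DataFrame:
    """Train/evaluate every grid point with both interpolation modes.

    Rows are ordered by (convs_per_block, blocks, filters).  With
    ``dry_run`` only the weight counts are tabulated (no training).
    """
    grid = PAPER_GRID if grid is None else grid
    rows = []
    if not dry_run:
        x = _latents_to_batch(latents)
        h, w = x.shape[2], x.shape[3]
        if test_latents is None:
            test_latents, test_masks = latents, masks
    for point in grid:
        b, c, f = (point["blocks"], point["convs_per_block"],
                   point["filters"])
        row = {"blocks": b, "convs": c, "filters": f,
               "weights": decoder_param_count(b, c, f)}
        for interp in ("nearest", "bilinear"):
            spec = DecoderSpec(blocks=b, convs_per_block=c, filters=f,
                               interpolation=interp,
                               upscale_total=upscale_total)
            if dry_run:
                row[f"iou_{interp}"] = float("nan")
                continue
            net = build_lean_decoder(spec, h, w, seed=config.seed)
            train_lean_decoder(net, latents, masks, config)
            row[f"iou_{interp}"] = evaluate_lean_decoder(
                net, test_latents, test_masks)
            if interp == "nearest":
                row["file_kb"] = net.serialized_size() / 1024.0
        rows.append(row)
        log.info("grid point blocks=%d convs=%d filters=%d done", b, c, f)
    df = pd.DataFrame(rows)
    return df.sort_values(["convs", "blocks", "filters"],
                          kind="stable").reset_index(drop=True)
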