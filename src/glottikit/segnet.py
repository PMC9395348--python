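"""The ablatable segmentation encoder-decoder family.

The architecture is a U-Net-style encoder-decoder: per encoder level two
3x3 conv + batchnorm + ReLU blocks followed by 2x2 max pooling, with the
filter count at depth ``d`` given by ``f_base * 2**d``.  The bottleneck can
be overridden to any channel count ``f_L`` (down to a single latent image)
and is passed through ReLU6, clipping latent values to [0, 6].  The decoder
mirrors the encoder with 2x upsampling + convolution per level and optional
concatenative skip connections; a final 1x1 convolution + sigmoid produces
the soft mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import (INPUT, BatchNorm2D, Concat, Conv2D, MaxPool2, Network, ReLU,
                 ReLU6, Sigmoid, Upsample, evaluate_iou, fit)
from .preprocess import binarize

__all__ = ["SegNetSpec", "TrainConfig", "SegNet", "filters_at_depth",
           "relu6", "build_segnet", "train_segnet", "predict_mask",
           "extract_latent", "decode_latent", "load_segnet"]

log = logging.getLogger(__name__)

LATENT_NODE = "latent"
LOGIT_NODE = "logit"
OUTPUT_NODE = "prob"


def filters_at_depth(f_base: int, d: int) -> int:
    """Filter-count schedule: f_base * 2**d."""
    if d < 0:
        raise ValueError("depth must be nonnegative")
    if f_base < 1:
        raise ValueError("f_base must be >= 1")
    return f_base * 2 ** d


def relu6(x):
    """Elementwise min(max(0, x), 6)."""
    return np.clip(x, 0.0, 6.0)


@dataclass(frozen=True)
class SegNetSpec:
    f_base: int = 16
    depth: int = 4
    latent_channels: int | str = "schedule"  # int override or full schedule
    skips: bool = True
    input_height: int = 512
    input_width: int = 256

    def __post_init__(self):
        if self.f_base < 1:
            raise ValueError("f_base must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        step = 2 ** self.depth
        if self.input_height % step or self.input_width % step:
            raise ValueError(
                f"input dims {self.input_height}x{self.input_width} must be "
                f"divisible by 2**depth = {step}")
        if self.f_latent < 1:
            raise ValueError("latent_channels must be >= 1")

    @property
    def f_latent(self) -> int:
        if self.latent_channels == "schedule":
            return filters_at_depth(self.f_base, self.depth)
        return int(self.latent_channels)

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        step = 2 ** self.depth
        return (self.input_height // step, self.input_width // step,
                self.f_latent)

    def to_dict(self) -> dict:
        return {"f_base": self.f_base, "depth": self.depth,
                "latent_channels": self.latent_channels, "skips": self.skips,
                "input_height": self.input_height,
                "input_width": self.input_width}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    batch_size: int = 8
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class SegNet:
    """A built network plus its spec, with encoder/decoder access points."""

    spec: SegNetSpec
    net: Network

    @property
    def layer_names(self) -> list[str]:
        return self.net.node_names

    def forward(self, frames: np.ndarray, train: bool = False):
        return self.net.forward(_as_batch(frames), train=train)

    def save(self, path) -> None:
        self.net.save(path, meta={"spec": self.spec.to_dict()})


def _as_batch(frames: np.ndarray) -> np.ndarray:
    """Accept (H,W), (N,H,W) or (N,1,H,W); return (N,1,H,W) float32."""
    arr = np.asarray(frames, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = arr[:, None]
    if arr.ndim != 4:
        raise ValueError(f"cannot interpret input of shape {frames.shape}")
    return arr


def _conv_block(net: Network, name: str, c_in: int, c_out: int, src: str,
                rng, activation="relu") -> str:
    net.add(f"{name}_conv", Conv2D(c_in, c_out, 3, bias=True, rng=rng), src)
    net.add(f"{name}_bn", BatchNorm2D(c_out), f"{name}_conv")
    act = ReLU6() if activation == "relu6" else ReLU()
    net.add(f"{name}_act", act, f"{name}_bn")
    return f"{name}_act"


def build_segnet(spec: SegNetSpec, seed: int = 0) -> SegNet:
    """Construct the (untrained) network for ``spec``.

    Node naming: ``enc{i}_a/_b`` conv blocks, ``pool{i}``, ``bott_a``,
    ``latent`` (post-ReLU6), ``up{i}``, ``dec{i}_a/_b``, ``logit``, ``prob``.
    """
    rng = np.random.default_rng(seed)
    net = Network()
    src, ch = INPUT, 1
    skip_nodes: list[tuple[str, int]] = []
    for i in range(spec.depth):
        f = filters_at_depth(spec.f_base, i)
        src = _conv_block(net, f"enc{i}_a", ch, f, src, rng)
        src = _conv_block(net, f"enc{i}_b", f, f, src, rng)
        skip_nodes.append((src, f))
        net.add(f"pool{i}", MaxPool2(), src)
        src, ch = f"pool{i}", f

    f_sched = filters_at_depth(spec.f_base, spec.depth)
    src = _conv_block(net, "bott_a", ch, f_sched, src, rng)
    net.add("bott_b_conv", Conv2D(f_sched, spec.f_latent, 3, bias=True,
                                  rng=rng), src)
    net.add("bott_b_bn", BatchNorm2D(spec.f_latent), "bott_b_conv")
    net.add(LATENT_NODE, ReLU6(), "bott_b_bn")
    src, ch = LATENT_NODE, spec.f_latent

    for i in reversed(range(spec.depth)):
        f = filters_at_depth(spec.f_base, i)
        net.add(f"up{i}", Upsample(2, mode="nearest"), src)
        src = f"up{i}"
        if spec.skips:
            skip_src, skip_ch = skip_nodes[i]
            net.add(f"cat{i}", Concat(), src, skip_src)
            src, ch = f"cat{i}", ch + skip_ch
        src = _conv_block(net, f"dec{i}_a", ch, f, src, rng)
        src = _conv_block(net, f"dec{i}_b", f, f, src, rng)
        ch = f
    net.add(LOGIT_NODE, Conv2D(ch, 1, 1, bias=True, rng=rng), src)
    net.add(OUTPUT_NODE, Sigmoid(), LOGIT_NODE)
    return SegNet(spec=spec, net=net)


def load_segnet(path) -> SegNet:
    """Rebuild a segnet from a weights file written by :meth:`SegNet.save`."""
    with np.load(path) as data:
        if "__meta__" not in data.files:
            raise IOError(f"{path} has no architecture metadata")
    import json
    meta = json.loads(bytes(np.load(path)["__meta__"]).decode())
    spec = SegNetSpec(**meta["spec"])
    model = build_segnet(spec)
    model.net.load(path)
    return model


# ---------------------------------------------------------------------------
# training and inference


def _dataset_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept (frames, masks) arrays or a sequence of (frame, mask) pairs."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        frames, masks = dataset
    else:
        pairs = list(dataset)
        if not pairs:
            raise ValueError("empty dataset")
        frames = np.stack([p[0] for p in pairs])
        masks = np.stack([p[1] for p in pairs])
    x = _as_batch(np.asarray(frames, dtype=np.float32))
    y = _as_batch(np.asarray(masks, dtype=np.float32))
    if len(x) == 0:
        raise ValueError("empty dataset")
    if x.shape != y.shape:
        raise ValueError("frames and masks disagree in shape")
    return x, y


def train_segnet(model: SegNet, dataset, config: TrainConfig) -> pd.DataFrame:
    """Dice-loss training with Adam; returns per-epoch history.

    A ``validation_fraction`` split is drawn with the config seed; the
    weights of the best-validation-IoU epoch are retained on the model.
    """
    x, y = _dataset_arrays(dataset)
    rng = np.random.default_rng(config.seed)
    n = len(x)
    n_val = max(1, int(round(n * config.validation_fraction))) if n > 1 else 0
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx = order
    result = fit(model.net, x[train_idx], y[train_idx],
                 x[val_idx], y[val_idx],
                 epochs=config.epochs, learning_rate=config.learning_rate,
                 batch_size=config.batch_size, rng=rng, log=log)
    return pd.DataFrame(result.history)


def evaluate_segnet(model: SegNet, dataset) -> float:
    """Mean per-image IoU of binarized predictions on a dataset."""
    x, y = _dataset_arrays(dataset)
    return evaluate_iou(model.net, x, y)


def predict_mask(model: SegNet, frame: np.ndarray) -> np.ndarray:
    """Binarized (0.5) sigmoid output, shaped like the input frame(s)."""
    batch = _as_batch(frame)
    probs = model.net(batch)
    masks = binarize(probs[:, 0])
    return masks[0] if np.asarray(frame).ndim == 2 else masks


def predict_soft(model: SegNet, frame: np.ndarray) -> np.ndarray:
    batch = _as_batch(frame)
    probs = model.net(batch)[:, 0]
    return probs[0] if np.asarray(frame).ndim == 2 else probs


def extract_latent(model: SegNet, frame: np.ndarray) -> np.ndarray:
    """Bottleneck activation; (h, w) for a single frame with f_L = 1."""
    single = np.asarray(frame).ndim == 2
    tape = model.net.forward(_as_batch(frame))
    lat = tape[LATENT_NODE]
    if model.spec.f_latent == 1:
        lat = lat[:, 0]
    return lat[0] if single else lat


def decode_latent(model: SegNet, latent: np.ndarray,
                  frame: np.ndarray | None = None) -> np.ndarray:
    """Soft prediction obtained by running the decoder on ``latent``.

    For skip architectures the encoder activations are required, so the
    originating frame must be supplied.
    """
    lat = np.asarray(latent, dtype=np.float32)
    single = lat.ndim == 2
    if lat.ndim == 2:
        lat = lat[None, None]
    elif lat.ndim == 3:
        lat = lat[:, None]
    h, w, c = model.spec.latent_shape
    if lat.shape[1:] != (c, h, w):
        raise ValueError(f"latent shape {lat.shape[1:]} does not match the "
                         f"network's ({c}, {h}, {w})")
    base_tape = None
    if model.spec.skips:
        if frame is None:
            raise ValueError("skip architectures need the source frame to "
                             "decode a latent")
        base_tape = model.net.forward(_as_batch(frame))
    tape = model.net.forward_from({LATENT_NODE: lat}, tape=base_tape)
    probs = tape[OUTPUT_NODE][:, 0]
    return probs[0] if single else probs
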