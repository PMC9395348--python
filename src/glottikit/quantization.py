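"""Histogram-bin quantization of latent images and the bit-depth sweep.

A b-bit quantization splits the per-image value range [min, max] into 2**b
equal-width bins and replaces every pixel with the empirical mean of its
bin.  The sweep compares decoded reconstructions of quantized latents
against the full-precision reconstruction (IoU, MSE) and re-runs the
waveform-proxy correlation on quantized latents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import iou, mse
from .preprocess import binarize

__all__ = ["QuantSpec", "quantize_latent", "bit_sweep", "latent_to_uint8",
           "uint8_to_latent", "RELU6_MAX"]

RELU6_MAX = 6.0


@dataclass(frozen=True)
class QuantSpec:
    bits: int
    bin_edges: np.ndarray   # 2**bits + 1, strictly increasing (or degenerate)
    bin_means: np.ndarray   # mean of occupied bins, NaN where empty

    def __post_init__(self):
        if not 1 <= self.bits <= 8:
            raise ValueError("bits must lie in [1, 8]")


def quantize_latent(psi1, bits: int) -> tuple[np.ndarray, QuantSpec]:
    """Replace each pixel by the empirical mean of its equal-width bin.

    Bins span this image's own [min, max]; the maximum value falls in the
    last bin.  A constant image is returned unchanged (degenerate range).
    """
    if not 1 <= bits <= 8:
        raise ValueError("bits must lie in [1, 8]")
    v = np.asarray(psi1, dtype=np.float64)
    vmin, vmax = float(v.min()), float(v.max())
    n_bins = 2 ** bits
    if vmax == vmin:
        edges = np.linspace(vmin, vmin + 1.0, n_bins + 1)
        means = np.full(n_bins, np.nan)
        means[0] = vmin
        return v.copy(), QuantSpec(bits, edges, means)
    edges = np.linspace(vmin, vmax, n_bins + 1)
    idx = np.clip(((v - vmin) / (vmax - vmin) * n_bins).astype(np.int64),
                  0, n_bins - 1)
    flat = idx.ravel()
    counts = np.bincount(flat, minlength=n_bins).astype(np.float64)
    sums = np.bincount(flat, weights=v.ravel(), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    out = means[idx]
    return out, QuantSpec(bits, edges, means)


def latent_to_uint8(psi1) -> np.ndarray:
    """Fixed-range codec: [0, 6] -> [0, 255] with rounding."""
    v = np.asarray(psi1, dtype=np.float64)
    if v.min() < 0 or v.max() > RELU6_MAX:
        raise ValueError("latent values must lie in [0, 6]")
    return np.rint(v / RELU6_MAX * 255.0).astype(np.uint8)


def uint8_to_latent(img) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("expected uint8 input")
    return (img.astype(np.float32) * (RELU6_MAX / 255.0)).astype(np.float32)


def bit_sweep(latents, decode, gt_masks=None, bits_list=range(1, 9),
              t_hi: float | None = None) -> pd.DataFrame:
    """Reconstruction quality of b-bit latents versus full precision.

    ``decode`` maps an (h, w) latent to a soft mask.  Per bit depth the
    table reports median and quartile IoU between binarized reconstructions,
    mean MSE between soft reconstructions, and — when ``gt_masks`` is given
    (the latents are then treated as one temporal clip) — the correlation of
    the thresholded-proxy waveform from quantized latents with the GAW.
    """
    from .gaw import gaw_from_masks, thresholded_latent_waveform
    from .latent_analysis import latent_stats, subtype_threshold
    from .metrics import pearson

    bits_list = list(bits_list)
    if not bits_list:
        raise ValueError("bits_list must not be empty")
    lat_list = [np.asarray(l, dtype=np.float64) for l in latents]
    if t_hi is None:
        _, t_hi = subtype_threshold(latent_stats(lat_list))
    full_soft = [np.asarray(decode(l)) for l in lat_list]
    full_masks = [binarize(s) for s in full_soft]

    gaw = None
    if gt_masks is not None:
        gaw = gaw_from_masks(gt_masks)
        if len(gaw) != len(lat_list):
            raise ValueError("gt_masks and latents disagree in length")

    rows = []
    for bits in bits_list:
        qlats = [quantize_latent(l, bits)[0] for l in lat_list]
        ious, mses = [], []
        for ql, fs, fm in zip(qlats, full_soft, full_masks):
            qs = np.asarray(decode(ql))
            ious.append(iou(binarize(qs), fm))
            mses.append(mse(qs, fs))
        row = {
            "bits": bits,
            "iou_median": float(np.median(ious)),
            "iou_q25": float(np.percentile(ious, 25)),
            "iou_q75": float(np.percentile(ious, 75)),
            "mse": float(np.mean(mses)),
        }
        if gaw is not None and len(gaw) >= 2:
            wf = thresholded_latent_waveform(np.stack(qlats), t_hi)
            row["corr"] = pearson(wf, gaw)
        else:
            row["corr"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
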