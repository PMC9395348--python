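"""Characterization of the single-channel latent image.

Pooled value statistics, percentile thresholds, alpha/beta/gamma pixel
subtype maps, artificial latent construction and perturbation sweeps, and
per-pixel correlation of latent time series with the glottal area waveform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import pearson

__all__ = ["LatentStats", "SubtypeMap", "latent_stats", "subtype_threshold",
           "classify_subtypes", "make_artificial_latent",
           "perturbation_sweep", "perpixel_gaw_correlation",
           "ALPHA", "BETA", "GAMMA", "SUBTYPE_PALETTE"]

# subtype codes and the fixed PNG palette
ALPHA, BETA, GAMMA = 0, 1, 2
SUBTYPE_PALETTE = {ALPHA: 64, BETA: 128, GAMMA: 255}


@dataclass
class LatentStats:
    """Pooled pixel-value statistics of a collection of latent images."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    median: float
    mode: float
    max: float
    values: np.ndarray  # sorted pooled sample, kept for exact percentiles

    def percentile(self, q: float) -> float:
        """Linear-interpolation percentile of the pooled distribution."""
        return float(np.percentile(self.values, q))

    def percentile_table(self, qs=(1, 5, 25, 50, 75, 95, 99)) -> pd.DataFrame:
        return pd.DataFrame({"percentile": list(qs),
                             "value": [self.percentile(q) for q in qs]})


def latent_stats(latents, n_bins: int = 256) -> LatentStats:
    """Pool all pixels of all images; histogram over [0, observed max]."""
    arrs = [np.asarray(l, dtype=np.float64).ravel() for l in latents]
    if not arrs or sum(a.size for a in arrs) == 0:
        raise ValueError("empty latent collection")
    pooled = np.concatenate(arrs)
    vmax = float(pooled.max())
    hi = vmax if vmax > 0 else 1.0
    counts, edges = np.histogram(pooled, bins=n_bins, range=(0.0, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    pooled.sort()
    return LatentStats(
        bin_edges=edges,
        counts=counts,
        mean=float(pooled.mean()),
        median=float(np.percentile(pooled, 50)),
        mode=float(centers[np.argmax(counts)]),
        max=vmax,
        values=pooled,
    )


def subtype_threshold(stats: LatentStats, upper_pct: float = 95,
                      lower_pct: float = 5) -> tuple[float, float]:
    """(t_lo, t_hi) = (lower, upper) percentiles of the pooled distribution."""
    if lower_pct >= upper_pct:
        raise ValueError("lower_pct must be below upper_pct")
    return stats.percentile(lower_pct), stats.percentile(upper_pct)


@dataclass
class SubtypeMap:
    labels: np.ndarray  # uint8 of ALPHA/BETA/GAMMA codes
    t_lo: float
    t_hi: float

    def count(self, code: int) -> int:
        return int((self.labels == code).sum())

    def to_uint8(self) -> np.ndarray:
        out = np.empty_like(self.labels, dtype=np.uint8)
        for code, val in SUBTYPE_PALETTE.items():
            out[self.labels == code] = val
        return out


def classify_subtypes(psi1, t_lo: float, t_hi: float) -> SubtypeMap:
    """gamma where v > t_hi, alpha where v < t_lo, beta on [t_lo, t_hi]."""
    if t_lo >= t_hi:
        raise ValueError("t_lo must be below t_hi")
    v = np.asarray(psi1, dtype=np.float64)
    labels = np.full(v.shape, BETA, dtype=np.uint8)
    labels[v > t_hi] = GAMMA
    labels[v < t_lo] = ALPHA
    return SubtypeMap(labels=labels, t_lo=float(t_lo), t_hi=float(t_hi))


def make_artificial_latent(height: int, width: int, beta_value: float,
                           blobs=(), rings=()) -> np.ndarray:
    """Constant-beta canvas with gamma disks and alpha annuli painted on.

    ``blobs``: iterables of (x, y, radius, gamma_value);
    ``rings``: (x, y, inner_r, outer_r, alpha_value).  Later entries
    overwrite earlier ones.  All values must lie in the ReLU6 range [0, 6].
    """

    def _check_value(v):
        if not 0.0 <= v <= 6.0:
            raise ValueError(f"latent value {v} outside [0, 6]")

    def _check_coord(x, y):
        if not (0 <= x < width and 0 <= y < height):
            raise ValueError(f"coordinate ({x}, {y}) outside image")

    _check_value(beta_value)
    canvas = np.full((height, width), beta_value, dtype=np.float32)
    yy, xx = np.mgrid[0:height, 0:width]
    for x, y, r, val in blobs:
        if r < 0:
            raise ValueError("radius must be nonnegative")
        _check_value(val)
        _check_coord(x, y)
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        canvas[d2 <= r * r] = val
    for x, y, r_in, r_out, val in rings:
        if r_in < 0 or r_out < r_in:
            raise ValueError("ring radii must satisfy 0 <= inner <= outer")
        _check_value(val)
        _check_coord(x, y)
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        canvas[(d2 > r_in * r_in) & (d2 <= r_out * r_out)] = val
    return canvas


_SWEEP_DEFAULTS = {"x": 0, "y": 0, "radius": 2.0, "gamma_value": 1.0,
                   "alpha_value": 0.4, "beta_value": 0.8, "ring_width": 1.5}


def perturbation_sweep(decode, height: int, width: int,
                       grid: dict, base: dict | None = None) -> pd.DataFrame:
    """Decode artificial latents across a parameter grid.

    ``decode`` maps an (h, w) latent to a soft mask; ``grid`` maps parameter
    names (x, y, radius, gamma_value, alpha_value) to value lists.  Each grid
    point paints one gamma disk surrounded by an alpha ring and records the
    decoded mask's area and centroid.
    """
    params = {**_SWEEP_DEFAULTS, "x": width // 2, "y": height // 2,
              **(base or {})}
    unknown = set(grid) - set(params)
    if unknown:
        raise ValueError(f"unknown sweep parameters: {sorted(unknown)}")
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        p = dict(params, **dict(zip(keys, combo)))
        lat = make_artificial_latent(
            height, width, p["beta_value"],
            blobs=[(p["x"], p["y"], p["radius"], p["gamma_value"])],
            rings=[(p["x"], p["y"], p["radius"],
                    p["radius"] + p["ring_width"], p["alpha_value"])],
        )
        soft = np.asarray(decode(lat))
        mask = soft > 0.5
        area = int(mask.sum())
        if area:
            ys, xs = np.nonzero(mask)
            cy, cx = float(ys.mean()), float(xs.mean())
        else:
            cy = cx = float("nan")
        rows.append({**{k: p[k] for k in keys}, "area": area,
                     "centroid_y": cy, "centroid_x": cx})
    return pd.DataFrame(rows)


def perpixel_gaw_correlation(latents, gaw) -> np.ndarray:
    """Pearson correlation of each pixel's time series with the waveform.

    Zero-variance pixels map to 0.  Matches :func:`glottikit.metrics.pearson`
    applied per pixel, vectorized.
    """
    stack = np.asarray(latents, dtype=np.float64)
    g = np.asarray(gaw, dtype=np.float64).ravel()
    if stack.shape[0] != g.size:
        raise ValueError("latent sequence and waveform lengths differ")
    n = g.size
    if n < 2:
        raise ValueError("need at least two time points")
    ds = stack - stack.mean(axis=0)
    dg = g - g.mean()
    cov = np.tensordot(dg, ds, axes=(0, 0)) / (n - 1)
    s_px = np.sqrt((ds * ds).sum(axis=0) / (n - 1))
    s_g = np.sqrt((dg * dg).sum() / (n - 1))
    out = np.zeros(stack.shape[1:], dtype=np.float64)
    ok = (s_px > 0) & (s_g > 0)
    np.divide(cov, s_px * s_g, out=out, where=ok)
    out[~ok] = 0.0
    return out
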