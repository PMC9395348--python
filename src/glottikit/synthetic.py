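"""Synthetic endoscopy-like clips with exact masks and analytic area.

Each clip shows a dark, vertically elongated elliptic opening near the image
center whose area oscillates quasi-periodically as
``A(t) = A_max * |sin(pi * cycles * t / n_frames)|**p`` over the clip, on a
textured, vignetted, noisy background.  Masks are the exact rasterization of
the analytic ellipse, so every downstream stage has a ground truth oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import normalize_frame

__all__ = ["ClipSpec", "ClipSample", "AugmentSpec", "generate_clip",
           "generate_dataset", "augment", "random_augment_spec",
           "load_dataset_dir"]


@dataclass(frozen=True)
class ClipSpec:
    """Parameters of one synthetic clip."""

    height: int = 128
    width: int = 64
    n_frames: int = 30
    cycles: float = 3.0
    max_area_fraction: float = 0.05
    aspect: float = 3.0
    center_jitter: float = 3.0
    noise_sigma: float = 0.02
    vignette_strength: float = 0.5
    flicker: float = 0.08
    drift: float = 0.0
    distractors: int = 0
    distractor_strength: float = 0.35
    area_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.max_area_fraction <= 0.2:
            raise ValueError("max_area_fraction must lie in [0, 0.2]")
        if self.aspect <= 1.0:
            raise ValueError("aspect must exceed 1 (vertical elongation)")
        if self.cycles <= 0:
            raise ValueError("cycles must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0.0 <= self.flicker < 1.0:
            raise ValueError("flicker must lie in [0, 1)")
        if self.drift < 0:
            raise ValueError("drift must be nonnegative")
        if self.distractors < 0:
            raise ValueError("distractors must be nonnegative")
        if not 0.0 <= self.distractor_strength < 1.0:
            raise ValueError("distractor_strength must lie in [0, 1)")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must lie in [0, 1]")


@dataclass
class ClipSample:
    """Frames in [-1, 1], exact binary masks, and the analytic area series."""

    frames: np.ndarray  # (T, H, W) float32
    masks: np.ndarray   # (T, H, W) uint8
    true_area: np.ndarray  # (T,) float64, pixels

    def __len__(self) -> int:
        return self.frames.shape[0]


def _texture(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Low-frequency mucosa-like texture in [0, 1] intensity."""
    coarse = rng.uniform(0.45, 0.8, size=(max(h // 16, 2), max(w // 16, 2)))
    zoom = (h / coarse.shape[0], w / coarse.shape[1])
    return ndimage.zoom(coarse, zoom, order=1, mode="nearest", grid_mode=True)


def _vignette(h: int, w: int, strength: float) -> np.ndarray:
    """Camera-fixed radial intensity falloff."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2
    return 1.0 - strength * np.clip(r2, 0.0, 1.0)


def _ellipse_mask(h: int, w: int, cy: float, cx: float,
                  a: float, b: float) -> np.ndarray:
    """Exact pixel-center rasterization of an axis-aligned ellipse."""
    if a <= 0 or b <= 0:
        return np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    return inside.astype(np.uint8)


def area_waveform(spec: ClipSpec) -> np.ndarray:
    """Analytic area A(t) in pixels for t = 0..n_frames-1."""
    a_max = spec.max_area_fraction * spec.height * spec.width
    t = np.arange(spec.n_frames, dtype=np.float64)
    phase = np.pi * spec.cycles * t / spec.n_frames
    return a_max * np.abs(np.sin(phase)) ** spec.area_exponent


def generate_clip(spec: ClipSpec) -> ClipSample:
    """Render one clip; identical spec (incl. seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    true_area = area_waveform(spec)

    # bound check: the tallest ellipse must fit inside the image
    a_peak = math.sqrt(true_area.max() * spec.aspect / math.pi) if \
        true_area.max() > 0 else 0.0
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    if a_peak + spec.center_jitter >= min(cy0, h - 1 - cy0) + 1:
        raise ValueError(
            "max_area_fraction/aspect makes the glottal region exceed the "
            f"image bounds (semi-axis {a_peak:.1f}px in a {h}px-high image)")

    base_dy, base_dx = rng.uniform(-spec.center_jitter, spec.center_jitter, 2)

    # camera drift: the texture slides under a fixed vignette (random walk)
    if spec.drift > 0:
        steps = rng.normal(0.0, spec.drift, size=(spec.n_frames, 2))
        walk = np.cumsum(steps, axis=0)
        margin = int(np.ceil(np.abs(walk).max())) + 1
        walk = np.rint(walk).astype(int)
    else:
        walk = np.zeros((spec.n_frames, 2), dtype=int)
        margin = 0
    tex = _texture(rng, h + 2 * margin, w + 2 * margin)
    vig = _vignette(h, w, spec.vignette_strength)

    frames = np.empty((spec.n_frames, h, w), dtype=np.float32)
    masks = np.empty((spec.n_frames, h, w), dtype=np.uint8)
    for t in range(spec.n_frames):
        wob_dy, wob_dx = rng.uniform(-spec.center_jitter / 4.0,
                                     spec.center_jitter / 4.0, 2)
        cy, cx = cy0 + base_dy + wob_dy, cx0 + base_dx + wob_dx
        area = true_area[t]
        a = math.sqrt(area * spec.aspect / math.pi)
        b = a / spec.aspect
        mask = _ellipse_mask(h, w, cy, cx, a, b)
        oy = margin + int(np.clip(walk[t, 0], -margin, margin))
        ox = margin + int(np.clip(walk[t, 1], -margin, margin))
        bg = tex[oy : oy + h, ox : ox + w] * vig
        # per-frame illumination flicker, as in real endoscopy lighting
        gain = 1.0 + rng.uniform(-spec.flicker, spec.flicker)
        img = bg * gain
        # transient dark blobs (shadows / secretions), uncorrelated with the
        # glottal cycle — they perturb the latent background code
        for _ in range(spec.distractors):
            dy_, dx_ = rng.uniform(0, h), rng.uniform(0, w)
            r_ = rng.uniform(2.0, 6.0)
            yy, xx = np.mgrid[0:h, 0:w]
            blob = np.exp(-((yy - dy_) ** 2 + (xx - dx_) ** 2) / (2 * r_ * r_))
            img *= 1.0 - spec.distractor_strength * blob
        if mask.any():
            # darken the opening with a soft rim so edges look organic
            soft = ndimage.gaussian_filter(mask.astype(np.float64), 0.7)
            img *= 1.0 - 0.85 * np.clip(soft, 0.0, 1.0)
        img += rng.normal(0.0, spec.noise_sigma, size=(h, w))
        raw = np.clip(img, 0.0, 1.0) * 255.0
        frames[t] = normalize_frame(raw)
        masks[t] = mask
    return ClipSample(frames=frames, masks=masks, true_area=true_area)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentSpec:
    blur_kernel: int = 3
    blur_sigma: float = 0.8
    rotation_deg: float = 0.0
    hflip: bool = False
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.blur_kernel not in (3, 5, 7):
            raise ValueError("blur_kernel must be an odd integer in [3, 7]")
        if not 0.8 <= self.blur_sigma <= 1.4:
            raise ValueError("blur_sigma must lie in [0.8, 1.4]")
        if not -30.0 <= self.rotation_deg <= 30.0:
            raise ValueError("rotation_deg must lie in [-30, 30]")
        if not 0.8 <= self.gamma <= 1.2:
            raise ValueError("gamma must lie in [0.8, 1.2]")


def random_augment_spec(seed: int) -> AugmentSpec:
    """Draw one augmentation from the configured training ranges."""
    rng = np.random.default_rng(seed)
    return AugmentSpec(
        blur_kernel=int(rng.choice([3, 5, 7])),
        blur_sigma=float(rng.uniform(0.8, 1.4)),
        rotation_deg=float(rng.uniform(-30.0, 30.0)),
        hflip=bool(rng.random() < 0.5),
        gamma=float(rng.uniform(0.8, 1.2)),
        seed=seed,
    )


def _gaussian_kernel1d(ksize: int, sigma: float) -> np.ndarray:
    half = ksize // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def augment(frame: np.ndarray, mask: np.ndarray,
            spec: AugmentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Blur + gamma on the frame; rotation + hflip on frame and mask alike.

    Order: blur -> gamma -> rotate -> flip.  Frames rotate with bilinear
    interpolation, masks with nearest, and masks are re-binarized.
    """
    frame = np.asarray(frame, dtype=np.float32)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")

    k = _gaussian_kernel1d(spec.blur_kernel, spec.blur_sigma)
    f = ndimage.convolve1d(frame.astype(np.float64), k, axis=0, mode="nearest")
    f = ndimage.convolve1d(f, k, axis=1, mode="nearest")

    # gamma acts on [0,1] intensity, then back to [-1,1]
    f01 = np.clip((f + 1.0) / 2.0, 0.0, 1.0)
    f = np.power(f01, spec.gamma) * 2.0 - 1.0

    m = mask.astype(np.float64)
    if spec.rotation_deg != 0.0:
        f = ndimage.rotate(f, spec.rotation_deg, reshape=False, order=1,
                           mode="nearest")
        m = ndimage.rotate(m, spec.rotation_deg, reshape=False, order=0,
                           mode="constant", cval=0.0)
    if spec.hflip:
        f = f[:, ::-1]
        m = m[:, ::-1]
    return (np.clip(f, -1.0, 1.0).astype(np.float32),
            (m > 0.5).astype(np.uint8))


# ---------------------------------------------------------------------------
# dataset on disk (BAGLS-style pairing)


def generate_dataset(n_clips: int, template: ClipSpec, out_dir,
                     overwrite: bool = False) -> pd.DataFrame:
    """Write ``<clip>_<frame>.png`` / ``<clip>_<frame>_seg.png`` pairs.

    Per-clip RNG streams are spawned from ``(template.seed, clip index)`` so
    regeneration is byte-identical and clips are mutually independent.
    Returns the table of analytic areas (also written as ``true_areas.csv``).
    """
    from .imgio import write_image, write_mask
    from .preprocess import denormalize_frame

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for c in range(n_clips):
        clip_seed = int(np.random.SeedSequence([template.seed, c])
                        .generate_state(1)[0])
        clip = generate_clip(replace(template, seed=clip_seed))
        for t in range(len(clip)):
            stem = f"{c}_{t}"
            raw = np.clip(np.rint(denormalize_frame(clip.frames[t])),
                          0, 255).astype(np.uint8)
            write_image(out / f"{stem}.png", raw)
            write_mask(out / f"{stem}_seg.png", clip.masks[t])
            rows.append({"clip": c, "frame": t,
                         "true_area": clip.true_area[t]})
    table = pd.DataFrame(rows)
    table.to_csv(out / "true_areas.csv", index=False)
    return table


def load_dataset_dir(path) -> tuple[np.ndarray, np.ndarray]:
    """Load every ``N.png`` / ``N_seg.png`` pair from a BAGLS-style folder.

    Returns normalized frames (N, H, W) and binary masks (N, H, W).
    """
    from .imgio import read_image, read_mask

    path = Path(path)
    pairs = sorted(p for p in path.glob("*.png")
                   if not p.stem.endswith("_seg"))
    frames, masks = [], []
    for p in pairs:
        seg = p.with_name(p.stem + "_seg.png")
        if not seg.exists():
            continue
        frames.append(normalize_frame(read_image(p)))
        masks.append(read_mask(seg))
    if not frames:
        raise IOError(f"no image/mask pairs found in {path}")
    return np.stack(frames), np.stack(masks)
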