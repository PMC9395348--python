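"""8-bit grayscale PNG and waveform-CSV I/O."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["read_image", "write_image", "write_mask", "read_mask",
           "write_waveform_csv", "read_waveform_csv"]


def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale image as a 2-D uint8 array."""
    path = Path(path)
    try:
        img = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}") from exc
    if img.ndim == 3:  # collapse accidental RGB
        img = img[..., :3].mean(axis=-1).round()
    return img.astype(np.uint8)


def write_image(path, img) -> None:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("write_image expects uint8 data; quantize first")
    iio.imwrite(Path(path), img)


def write_mask(path, mask) -> None:
    """Store a binary mask as 0/255 PNG (lossless round trip)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    write_image(path, (mask * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    from .preprocess import normalize_mask
    return normalize_mask(read_image(path))


def write_waveform_csv(waveform, path) -> None:
    """CSV with header ``frame,value`` and 0-based frame index."""
    values = np.asarray(waveform).ravel()
    df = pd.DataFrame({"frame": np.arange(len(values)), "value": values})
    df.to_csv(Path(path), index=False)


def read_waveform_csv(path) -> np.ndarray:
    df = pd.read_csv(Path(path))
    if not {"frame", "value"} <= set(df.columns):
        raise IOError(f"{path} is not a waveform CSV (frame,value)")
    return df.sort_values("frame")["value"].to_numpy()
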