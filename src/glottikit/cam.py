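"""Seg-Grad-CAM: rectified, gradient-weighted feature-map sums.

For a chosen layer with feature maps A_k, the heatmap is
``ReLU(sum_k alpha_k A_k)`` where ``alpha_k`` is the spatial mean of the
gradient of the class score y^c with respect to A_k.  The class score of
the single-channel sigmoid head is the summed pre-sigmoid logit over a
pixel region (whole image by default), negated for the background class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.ops import _interp_matrix
from .segnet import LOGIT_NODE, SegNet, _as_batch

__all__ = ["CAMHeatmap", "seg_grad_cam", "cam_montage"]


@dataclass
class CAMHeatmap:
    values: np.ndarray  # (h, w), nonnegative
    layer: str
    class_id: int
    alphas: np.ndarray  # per-kernel weights

    def normalized_uint8(self) -> tuple[np.ndarray, float]:
        """8-bit rendering after per-map max normalization.

        Returns the image and the normalization factor used.
        """
        peak = float(self.values.max())
        scale = peak if peak > 0 else 1.0
        img = np.rint(self.values / scale * 255.0).astype(np.uint8)
        return img, scale


def seg_grad_cam(model: SegNet, layer: str, c: int, frame: np.ndarray,
                 region: np.ndarray | None = None) -> CAMHeatmap:
    """Heatmap at ``layer`` for class ``c`` (1 glottis, 0 background).

    ``region`` optionally restricts the summed class score to a binary
    pixel subset of the output; default is the whole image.
    """
    if layer not in model.net.node_names:
        raise ValueError(f"unknown layer {layer!r}; see model.layer_names")
    if c not in (0, 1):
        raise ValueError("class must be 0 or 1")
    tape = model.net.forward(_as_batch(frame))
    logit = tape[LOGIT_NODE]
    if region is None:
        d_logit = np.ones_like(logit)
    else:
        reg = np.asarray(region, dtype=np.float32)
        if reg.sum() == 0:
            raise ValueError("empty region")
        d_logit = np.broadcast_to(reg, logit.shape).copy()
    if c == 0:
        d_logit = -d_logit
    grads = model.net.backward(tape, d_logit, output=LOGIT_NODE)
    if layer not in grads:
        raise ValueError(f"layer {layer!r} does not feed the logit")
    a = tape[layer][0]          # (K, h, w)
    da = grads[layer][0]
    alphas = da.mean(axis=(1, 2))
    pre = np.tensordot(alphas, a, axes=(0, 0))
    return CAMHeatmap(values=np.maximum(pre, 0.0), layer=layer, class_id=c,
                      alphas=alphas)


def _resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    if img.shape == (out_h, out_w):
        return img
    if out_h % img.shape[0] or out_w % img.shape[1]:
        raise ValueError("only integer upsampling factors are supported")
    uh = _interp_matrix(img.shape[0], out_h // img.shape[0], "bilinear")
    uw = _interp_matrix(img.shape[1], out_w // img.shape[1], "bilinear")
    return uh @ img @ uw.T


def cam_montage(model: SegNet, frame: np.ndarray, layers,
                resize: bool = True) -> list[CAMHeatmap]:
    """Heatmaps for c=0 and c=1 at every requested layer (2 per layer).

    With ``resize`` the maps are bilinearly upsampled to the input
    resolution for display; values stay nonnegative.
    """
    maps = []
    h, w = model.spec.input_height, model.spec.input_width
    for layer in layers:
        for c in (0, 1):
            hm = seg_grad_cam(model, layer, c, frame)
            if resize:
                hm = CAMHeatmap(
                    values=np.maximum(
                        _resize_bilinear(hm.values, h, w), 0.0),
                    layer=hm.layer, class_id=hm.class_id, alphas=hm.alphas)
            maps.append(hm)
    return maps
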