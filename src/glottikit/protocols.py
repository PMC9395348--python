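"""Desk-scale reference protocols.

These are the shipped configurations that let the full pipeline run on one
CPU in minutes: 128x64 frames, f_base=8 networks, short Adam/Dice training.
They are configuration only — the full-scale settings (512x256, f_base=16,
25 epochs) remain plain :class:`SegNetSpec`/:class:`TrainConfig` values.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .segnet import SegNet, SegNetSpec, TrainConfig, build_segnet, train_segnet
from .synthetic import ClipSample, ClipSpec, generate_clip

__all__ = ["DESK_CLIP", "PROXY_EVAL_CLIP", "DESK_SPEC", "DESK_TRAIN",
           "clip_seed", "make_clips", "clips_to_arrays",
           "train_desk_segnet"]

#: clean training/testing distribution (no illumination transients)
DESK_CLIP = ClipSpec(height=128, width=64, n_frames=30, flicker=0.0)

#: evaluation distribution for the waveform-proxy experiment: transient
#: dark blobs perturb the latent background code, which corrupts the raw
#: latent sum but not the suprathreshold pixel count
PROXY_EVAL_CLIP = replace(DESK_CLIP, flicker=0.08, distractors=12,
                          distractor_strength=0.6)

DESK_SPEC = SegNetSpec(f_base=8, depth=4, latent_channels=1, skips=False,
                       input_height=128, input_width=64)

DESK_TRAIN = TrainConfig(epochs=8, learning_rate=1e-3, batch_size=8, seed=0)


def clip_seed(seed: int, index: int) -> int:
    """Independent per-clip RNG stream derived from (seed, clip index)."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0])


def make_clips(n_clips: int, seed: int,
               template: ClipSpec = DESK_CLIP) -> list[ClipSample]:
    return [generate_clip(replace(template, seed=clip_seed(seed, i)))
            for i in range(n_clips)]


def clips_to_arrays(clips) -> tuple[np.ndarray, np.ndarray]:
    frames = np.concatenate([c.frames for c in clips])
    masks = np.concatenate([c.masks for c in clips])
    return frames, masks


def train_desk_segnet(seed: int = 0, latent_channels: int = 1,
                      depth: int = 4, epochs: int = 8,
                      n_clips: int = 17) -> tuple[SegNet, "object"]:
    """Train the desk-scale reference net on n_clips x 30 clean frames.

    With the defaults this is the f_L=1, no-skip, depth-4 network used by
    every latent-space analysis; returns (model, history).
    """
    clips = make_clips(n_clips, seed)
    frames, masks = clips_to_arrays(clips)
    spec = replace(DESK_SPEC, latent_channels=latent_channels, depth=depth)
    model = build_segnet(spec, seed=seed)
    config = replace(DESK_TRAIN, epochs=epochs, seed=seed)
    history = train_segnet(model, (frames, masks), config)
    return model, history
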