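# glottikit

Latent-space analysis toolkit for glottis-segmentation encoder–decoder
networks, exercisable end to end on synthetic high-speed-videoendoscopy-like
data — no downloads, no GPU.

The package implements, in pure numpy (no deep-learning framework required):

- **`glottikit.segnet`** — the ablatable U-Net-style family: filter schedule
  `f_base * 2^d`, latent-channel override down to a single latent image Ψ₁,
  skip-connection toggle, ReLU6 bottleneck, Dice-loss/Adam training.
- **`glottikit.synthetic`** — BAGLS-style clip generator: grayscale frames
  with an oscillating dark elliptic opening, exact ground-truth masks, the
  analytic area waveform, and the standard augmentations (blur, gamma,
  rotation, horizontal flip).
- **`glottikit.latent_analysis`** — pooled latent statistics, percentile
  thresholds, α/β/γ pixel-subtype maps, artificial-latent construction and
  perturbation sweeps, per-pixel waveform correlation maps.
- **`glottikit.gaw`** — glottal area waveform extraction and its two latent
  proxies (raw sum, suprathreshold pixel count) plus the per-clip
  correlation experiment.
- **`glottikit.quantization`** — histogram-bin quantization of latent
  images, the 1–8-bit reconstruction sweep, and the fixed-range 8-bit
  storage codec.
- **`glottikit.lean_decoder`** — the minimal upsampling–convolution decoder
  grid ({1,2,4} blocks × {1,2} convs × {1,2,4,8} filters × nearest/bilinear)
  with exact trainable-parameter accounting
  (`W = 12f + (L−1)(9f² + 2f)`).
- **`glottikit.cam`** — Seg-Grad-CAM heatmaps for any layer, foreground and
  background classes.
- **`glottikit.experiments`** / **`glottikit.cli`** — channel/skip and
  dataset-size ablation protocols behind a seeded, manifest-writing CLI.

The small autodiff stack lives in `glottikit.nn` (im2col convolution,
batchnorm, max-pool, separable-matrix upsampling, Adam) and is verified by
finite-difference gradient checks in the test suite.

## CLI

```sh
glottikit simulate --clips 10 --frames 30 --out data/        # synthetic dataset
glottikit train --data data/ --config cfg.yaml --out run/    # train a segnet
glottikit analyze-latent --model run/weights.npz --data data/ --out latent/
glottikit gaw-correlate  --model run/weights.npz --out gaw/
glottikit quantize-sweep --model run/weights.npz --out bits/
glottikit decoder-grid --dry-run                             # 24 configs + weights
glottikit ablate-channels --data data/ --test-data test/ --out ablation/
glottikit cam --model run/weights.npz --data data/ --out cam/
```

Every subcommand takes `--seed` and writes a `manifest.json` (config hash,
seed, versions) beside its CSV/PNG outputs; identical manifests reproduce
outputs bit-identically.

Desk-scale defaults (128×64 frames, `f_base=8`, short training) are plain
configuration; the full-scale settings (512×256, `f_base=16`, 25 epochs)
remain available through the same dataclasses. A loader for a real
BAGLS-style directory of `N.png` / `N_seg.png` pairs is provided
(`glottikit.synthetic.load_dataset_dir`) but never required.

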