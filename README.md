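# speckgen

Physics-guided ultrasound speckle synthesis and a mask-conditioned GAN, with
a full evaluation metric suite, running entirely on synthetic IVUS-like
phantom data.

The core primitive is a Fourier-optics speckle transform: an image is
multiplied by i.i.d. uniform random phases, low-passed by a (soft) square
window of edge length `d` in the frequency domain, and the magnitude is
taken. `d` controls the speckle grain size (smaller windows, larger grains)
and is differentiable through a soft-edged window, so it can be learned
inside a network. Around this sit:

- **`speckgen.speckle`** — the speckle transform (FFT route plus an
  explicit-convolution verification oracle), spectral windows, polar ↔
  Cartesian warping for centric ultrasound views, a multi-size speckle bank
  with channel attention, and an autocorrelation-FWHM speckle-size
  estimator.
- **`speckgen.gan`** — a SPADE-conditioned residual generator and a
  stride-2 residual discriminator with spectral weight normalization,
  non-saturating GAN losses, Adam, and a seeded training loop with periodic
  FID validation. Built on a small numpy reverse-mode autodiff engine
  (`speckgen.gan.autodiff`) — no deep-learning framework required. The
  speckle bank sits after the penultimate generator block (8 → 32 channels,
  4 learnable window sizes); speckle phases are resampled every forward
  pass, so mode collapse can only affect morphology, never the speckle.
- **`speckgen.synthesis`** — artificial artery masks (randomly rotated,
  radially disturbed ellipses; classes 0/1/2 for lumen, intima/media,
  adventitia/background) and speckle phantoms rendered from them.
- **`speckgen.metrics`** — FID over Gaussian feature fits (pluggable
  embedder; default is a deterministic no-download "desk" embedder),
  per-class gray-value Jensen–Shannon divergence, SSIM, Dice, and the
  Dubuisson–Jain modified Hausdorff distance.
- **`speckgen.io` / `speckgen.cli`** — 8-bit grayscale PNG I/O and the
  unified command line.

## CLI

```bash
# speckle one image (optionally through the polar pipeline)
speckgen speckle --input img.png --d 16 --softness 0 --seed 7 --polar --output out.png

# synthetic data
speckgen masks --n 100 --size 256 --seed 3 --out masks/
speckgen phantoms --masks masks/ --out phantoms/
speckgen dataset --n 8 --size 64 --seed 1 --out pairs/

# GAN
speckgen train --data pairs/ --config cfg.yml --out runs/exp1
speckgen generate --checkpoint runs/exp1/best.npz --masks masks/ --n 100 --seed 1 --out gen/

# metrics
speckgen metrics fid --set-a gen/ --set-b phantoms/
speckgen metrics seg --pred pred_masks/ --truth true_masks/ --out seg.csv
```

`train` expects a directory of `phantom_NNNN.png` / `mask_NNNN.png` pairs
(as written by `dataset`) and a YAML config mirroring
`speckgen.gan.GanConfig`; every run directory receives a reproducibility
record (config + seeds), a CSV loss/FID log and the best-FID checkpoint.

## Notes

- Images are 8-bit grayscale PNG, mapped linearly to [0, 1]; masks store
  literal label values {0, 1, 2}.
- Coordinates are (row, col), 0-based; angles counterclockwise from the
  positive column axis.
- Absolute FID values depend on the embedder; only comparisons sharing an
  embedder are meaningful.
- Training at the full 256×256 scale is supported by the code but sized for
  GPU-class budgets; tests exercise a scaled-down 64×64 configuration.
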