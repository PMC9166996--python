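# ctdenoise

Denoising toolkit for CT-like grayscale images, built around **patch-based
independent component analysis (ICA) with sparse code shrinkage**, with a
wavelet-threshold denoiser and the classical spatial filters (mean, median,
adaptive Wiener) as comparators, objective quality metrics, and a benchmark
harness that runs entirely on synthetic phantoms — no clinical data needed.

It is aimed at people evaluating denoising algorithms for medical X-ray CT,
where quantum and photon noise are well modelled as pixelwise-independent
Gaussian fields and where edge detail (organ and lesion contours) must
survive the filtering.

## The method

A noisy image is degraded as `g = z + n` (additive) or `g = z(1 + n)`
(multiplicative; made additive by a log transform), with `n ~ N(mu, phi^2)`
i.i.d. per pixel.

**ICA denoiser.** Overlapping 8×8 patches (stride 4, per-patch DC removed)
are treated as observations of a linear mixture of independent sparse
sources. FastICA — centering/whitening followed by the fixed-point iteration

```
w  <-  E[x g(wᵀx)] − E[g′(wᵀx)] w,     w <- w / ‖w‖
```

with the log-cosh contrast `G(u) = (1/a1) log cosh(a1 u)` and deflationary
orthogonalization — is fitted to the noisy patches themselves. Patch codes
`s = Wᵀ V (x − x̄)` are then soft-thresholded per component at
`t_j = σ_j² / scale_j`, where `σ_j` is the image noise std propagated
through component *j*'s analysis filter and `scale_j` is a robust estimate
of that component's *signal* scale; thresholded codes are re-synthesized and
overlap-added. Components dominated by noise are annihilated, components
carrying sparse image structure (edges) pass nearly untouched.

**Wavelet denoiser.** Classical VisuShrink: orthogonal 2-D DWT (Daubechies
filters generated by spectral factorization, periodized boundaries, exact
perfect reconstruction), soft threshold `t = σ √(2 ln AB)` on the detail
bands, inverse transform. The noise std `σ` is estimated, when unknown, as
`median(|d|)/0.6745` over the finest diagonal band.

**Quality metrics.** `MSE = (1/AB) Σ (z − z′)²`, `RMSE = √MSE`,
`PSNR = 10 log10(L²/MSE)` dB with the gray range `L` carried explicitly on
every image. A diagnostic-accuracy helper converts a 2×2 confusion table to
sensitivity / specificity / accuracy percentages.

## Worked example

```bash
ctdenoise phantom --out phantom.png --seed 0
ctdenoise addnoise phantom.png noisy.png --sigma 20 --seed 1
ctdenoise score phantom.png noisy.png
ctdenoise denoise noisy.png denoised_ica.png --method ica --sigma 20 --seed 0
ctdenoise score phantom.png denoised_ica.png
ctdenoise denoise noisy.png denoised_mean.png --method mean --k 3
ctdenoise score phantom.png denoised_mean.png
```

prints (JSON, one line per `score` call):

```
{"psnr": 22.47207008125503, "rmse": 19.183890037291462, "mse": 368.0216369628906, "gray_range": 255.0}
{"psnr": 31.445904470320812, "rmse": 6.827236650235607, "mse": 46.61116027832031, "gray_range": 255.0}
{"psnr": 30.440065088494666, "rmse": 7.665437129844688, "mse": 58.75892639160156, "gray_range": 255.0}
```

Reading: Gaussian noise at σ=20 pulls the 256×256 phantom down to
22.5 dB PSNR; the ICA denoiser restores it to 31.4 dB (RMSE 6.8 gray
levels), about 1 dB above the 3×3 mean filter (30.4 dB, RMSE 7.7) — the box
filter pays for its noise suppression with blurred lesion edges, which the
sparse-code shrinkage largely preserves.

The same experiment grid programmatically:

```python
from ctdenoise.benchmark import run_sweep, summarize
table = run_sweep(["none", "ica", "wavelet", "mean"], sigmas=[10, 20, 30, 40], n_seeds=3, seed=0)
print(summarize(table))
```

or from the shell, with a YAML config (keys: `methods`, `sigmas`,
`n_seeds`, `seed`, `k`, `phantom:` with `PhantomSpec` fields):

```bash
ctdenoise benchmark --methods ica,wavelet,mean,none --sigmas 10,20,30,40 --out sweep.csv --plot sweep.png
```

Every file-writing command drops a `<output>.manifest.json` beside its
output recording the full parameter set and seed. Exit codes: 0 success,
1 usage error, 2 data error.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default phantom, degrades it at σ ∈ {10, 20, 30, 40},
runs all six methods (including the raw noisy image), and prints the
per-method PSNR/RMSE summary to stderr before writing the results JSON.

## Layout

- `ctdenoise.image_io` — `Image` container, PNG/TIFF I/O, normalization
- `ctdenoise.noise` — degradation models, noise statistics, σ estimation
- `ctdenoise.metrics` — PSNR/RMSE/MSE, diagnostic summaries
- `ctdenoise.ica` — FastICA, patches, sparse code shrinkage, separation mode
- `ctdenoise.wavelet` — orthogonal DWT, threshold denoiser
- `ctdenoise.baselines` — mean / median / adaptive Wiener filters
- `ctdenoise.phantom` — synthetic kidney-CT-like phantoms
- `ctdenoise.benchmark` — sweeps, summaries, CSV/plot output
- `ctdenoise.cli` — the `ctdenoise` command

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
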