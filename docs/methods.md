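# Methods

## Noise model

Image degradation is modelled as `g = z + n` (additive) or `g = z(1 + n)`
(multiplicative) with `n(x, y)` i.i.d. Gaussian, mean `mu`, std `sigma` —
the standard idealization of quantum/photon noise in X-ray CT. Pixels are
uncorrelated by assumption; structured artifacts (streaks, beam hardening)
are out of scope. Noise mean and variance estimators use the population
normalization `1/(A·B)`, not `1/(AB−1)`.

Two numerical choices follow from the models:

- **Multiplicative sampling truncation.** Gaussian `n` can reach `n ≤ −1`,
  where the log transform `log g = log z + log(1 + n)` that makes the model
  additive is undefined. The sampler resamples such draws, so `1 + n > 0`
  always holds and the log-domain route is exact, not approximate.
- **Additive residual rounding.** `degrade` computes `z + n` in float64;
  `(z + n) − z` recovers the sampled field to ~1e−13 relative, not bitwise
  (IEEE rounding), which is what the tests assert.

The blind noise-level estimator is the wavelet-domain MAD:
`sigma ≈ median(|d|)/0.6745` over the level-1 diagonal detail coefficients.
It is exact for pure Gaussian fields in expectation, insensitive to DC
shifts, and biased upward only when the image has strong fine diagonal
texture.

## FastICA

Estimation is the fixed-point iteration with deflation. Data are centered
and whitened by eigen-decomposition of the population covariance;
eigenvalues below `1e−10 ×` the largest are dropped (rank control — for
DC-removed patches the covariance is always rank-deficient by one).
Per component: random unit initialization (seeded), iterate
`w ← E[x g(wᵀx)] − E[g′(wᵀx)] w`, Gram–Schmidt against earlier components,
renormalize; converged when `|⟨w_k, w_{k−1}⟩| > 1 − tol` with `tol = 1e−6`,
`max_iter = 200`. Non-convergence (typical for near-Gaussian directions)
is flagged on the model, not raised: the returned basis is orthonormal and
usable regardless. Sign is fixed so each component's largest-magnitude
entry is positive, making fits reproducible across runs.

Contrasts: `G1(u) = (1/a1) log cosh(a1 u)` (default, `a1 ∈ [1,2]`, robust
for general sources) and `G2(u) = −(1/a2) exp(−a2 u²/2)` (selectable; more
robust to outliers, suited to strongly super-Gaussian sources). The
negentropy proxy `|E[G(y)] − E[G(v)]|^p` uses `E[G(v)]` computed once by
adaptive quadrature over the standard normal; `p = 2` by default — `p` is a
monotone rescaling and never changes which direction wins.

## ICA image denoising (sparse code shrinkage)

How a *single* noisy image becomes ICA data is a design decision: we use
overlapping patches of the noisy image itself, so the method is fully
self-contained (an optional pre-fitted model can be supplied instead, and a
separate `ica_separate` entry point handles the multi-observation
blind-separation setting).

Pipeline: extract 8×8 patches at stride 4 (final row/column clamped to the
border so coverage is complete), remove per-patch DC, fit FastICA, project
patches onto the components, shrink, re-synthesize, overlap-add with
per-pixel coverage averaging.

Shrinkage is per-component soft thresholding at `t_j = σ_j² / scale_j`:

- `σ_j = σ · ‖a_j‖` — the image-domain noise std propagated through
  component j's analysis filter `a_j` (row of `W·V`, with `V` the whitening
  map); whitening amplifies noise-dominated directions, and this term
  tracks that exactly.
- `scale_j` — the component's **signal** scale: the MAD-based robust scale
  of the observed responses with the noise contribution removed in
  quadrature, `sqrt(max(MAD²/0.6745² − σ_j², 0))`. Components whose
  responses are statistically indistinguishable from noise get scale 0 and
  are annihilated; strongly signal-bearing components get a small threshold
  and pass nearly untouched. We evaluated the simpler alternative of using
  the raw response MAD as the scale: it thresholds noise-dominated
  components at only ~1 noise-std, leaves them mostly intact, and on the
  default phantom at σ=20 lands *below* the 3×3 mean filter (30.1 vs
  30.2 dB, 3-seed means); the signal-scale rule reaches 31.9 dB and is the
  package default.

With `σ = 0` the pipeline is an exact analysis–synthesis round trip (up to
the dropped null eigendirection), so a noise-free image passes through
essentially unchanged. Patch DC means are never thresholded; their noise is
attenuated only by the overlap averaging, which bounds achievable PSNR at
very high noise but protects the image's local brightness exactly.

## Wavelet denoising

VisuShrink defaults: `db4`, 3 decomposition levels (capped at
`log2(min(A,B)) − 2` for small images), soft thresholding of all detail
bands at the universal threshold `t = σ √(2 ln AB)`, approximation band
untouched. Daubechies filters are generated by spectral factorization of
the half-band polynomial (minimum-phase root selection) and verified
against the orthonormality conditions in the tests.

Boundary handling is **periodization** (odd dimensions edge-replicated to
even per level, cropped on reconstruction). A symmetric extension was
considered but rejected: for an orthogonal filter bank only periodization
makes the transform an exactly orthogonal matrix, giving machine-precision
perfect reconstruction and Parseval energy conservation — properties the
denoiser's contracts (round trip ≤ 1e−9, energy ≤ 1e−6 relative) are built
on. The cost is potential wrap-around artifacts on images with strongly
mismatched opposite borders; the phantoms and typical CT fields of view
(dark air border) are unaffected.

Multiplicative-noise inputs can be routed through `log`/`exp` wrapping
(flag), which requires strictly positive intensities and guarantees a
strictly positive output.

## Baselines

Mean and median filters are `scipy.ndimage` with reflect padding, default
k=3. The adaptive Wiener filter is the local-statistics (Lee) form:
`out = m + max(0, s² − v)/max(s², v) · (x − m)` with window mean `m`,
window variance `s²`, and noise variance `v` (auto: mean of the local
variances). `v = 0` is the identity; flat windows return the local mean.

## Synthetic phantoms

The phantom emulates a single abdominal CT slice at kidney level: dark
background (30), a bright rotated-ellipse parenchyma (120), an embedded
lesion ellipse (200) — piecewise-constant in the Shepp–Logan tradition —
plus optional smooth texture (Gaussian white noise blurred at scale 4 px,
amplitude 4 gray levels by default) emulating parenchymal inhomogeneity.
Sharp analytic edges give an exact ground truth for PSNR/RMSE and directly
probe edge preservation. Default size 256×256 on an 8-bit range.

What the phantom does **not** emulate: real CT noise texture (which is
correlated by reconstruction), Hounsfield calibration, anatomy beyond two
nested ellipses, partial-volume effects. A green benchmark therefore
establishes the *ordering* of methods under the stated Gaussian model, not
clinical performance.

The benchmark grid is additive Gaussian noise at σ ∈ {10, 20, 30, 40},
3 seeds per cell by default, with every cell's noise and fit seeds derived
deterministically from the top-level seed. Denoisers receive the true σ
(known in simulation); blind σ estimation is exercised separately in unit
tests. Benchmarks assert orderings (denoised > noisy; ICA > mean filter at
σ=20), not absolute dB values, since there are no published numbers to
anchor to. `runtime_s` in the CSV is informational wall-clock time and is
excluded from determinism guarantees.

## Known limitations

- DICOM is not supported (no DICOM library in the supported environment);
  PNG and TIFF at 8/16 bit cover the toolkit's scope. Physical pixel
  spacing is not modelled anywhere.
- The DWT is implemented in-package (periodized orthogonal transform,
  Daubechies/Haar families only); no biorthogonal or symmetric-extension
  modes, no translation-invariant cycle spinning.
- FastICA on patch data routinely leaves some components unconverged at
  `max_iter`; this is inherent to near-Gaussian directions and harmless
  for denoising, but callers doing source *interpretation* should check
  `model.converged`.
- 2-D single-frame only; no volumes, no color.
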