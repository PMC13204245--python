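# Methods

This note documents the models and procedures implemented in `wavepool`,
the parameter choices that matter, what the synthetic phantom generator
does and does not emulate, and the numerical conventions a user relying on
exact reproducibility should know.

## Wavelet engine

All transforms use orthonormal Symlet (least-asymmetric) filter banks of
order N ∈ {2, 4, 6}: filter length 2N, support width 2N−1, N vanishing
moments. The trade-off is the classical one — Sym2's 4-tap support gives
the sharpest spatial localization (fine margins, spiculations), Sym6's
12-tap support favors sparser representation of smooth regions at the cost
of blurring narrow edges, which is also why orders ≥ 8 are not offered.

Conventions (the literature admits several equally valid ones; these are
fixed and tested here):

* `dec_lo` is the standard orthonormal Symlet scaling filter
  (Σh = √2, Σh² = 1); the high-pass obeys
  `dec_hi[k] = (−1)^k · dec_lo[2N−1−k]`; synthesis filters are the
  time-reversals of the analysis pair. This choice fixes the *sign* of
  the wavelet; the mirrored convention spans the same basis.
* Boundary handling defaults to **periodization**, which maps an even
  H×W image to four (H/2)×(W/2) subbands, conserves energy exactly
  (Parseval), and makes LL-extraction's adjoint equal to the zero-detail
  inverse transform. Half-sample symmetric extension is available but
  has neither property.
* Odd dimensions are edge-replicated to the next even size; the original
  shape is recorded and restored on inversion.
* The transform equals explicit circular convolution
  `y[n] = Σ_k f[k] · x[(2n + L/2 − k) mod N]` followed by
  downsampling-by-2, applied separably (this phase convention is pinned
  by an independent oracle in the test suite). Subband naming: LH is
  high-pass along the vertical axis, HL along the horizontal.
* All arithmetic is float64.

## Despeckling

Input denoising is VisuShrink-style: 2-level decomposition, a single
global noise scale σ̂ = median(|HH₁|)/0.6745 (the Gaussian-consistency MAD
constant), per-subband universal threshold λ = σ̂·√(2 ln N) with N the
pixel count of that subband (natural logarithm), soft shrinkage of all six
detail subbands, approximation band untouched, inverse transform, clip to
[0, 1]. Setting the MAD constant to ∞ drives λ to 0 and reduces the
pipeline to transform + inverse — a wiring check used in the tests.
Despeckling runs immediately after noise injection and before the network,
at both training and evaluation time.

## Noise model

Speckle is modeled as first-order multiplicative Gaussian noise,
`I_noisy = I·(1+n)`, `n ~ N(0, σ²)` i.i.d. per pixel, σ ∈ {0.1, 0.2} for
the "10%/20%" stress levels, clipped to [0, 1] after corruption. σ is a
standard deviation — the percentage naming only makes sense that way. The
Rayleigh-type variant standardizes a Rayleigh draw to a unit-mean,
std-`level` multiplier, because a raw unit-mean Rayleigh multiplier has a
fixed coefficient of variation (≈ 0.523) and could not express a "10%"
level. Neither model has spatial correlation; real speckle is correlated
at the scale of the system point-spread function, and log-compression and
vendor post-processing are not modeled. The levels are engineering
stress-test parameters, not calibrated physical SNRs.

## Network and training

The classifier is a compact CNN: B ∈ {3, 4} blocks of
[3×3 conv ("same") → batch norm → ReLU → pool], channels 32→64→128(→256),
then global average pooling, dense 128 + ReLU, dropout 0.5, dense 2 +
softmax; He-normal initialization; grayscale single-channel input. The
pooling stage is pluggable (avg / max / wavelet-LL) and parameter-free, so
parameter counts are identical across pooling variants at fixed depth
(109,890 for B=3 with one input channel — the count is asserted against a
closed-form hand sum, not against any externally printed figure).

Wavelet pooling deliberately does **not** renormalize the LL gain: a
constant map c pools to 2c (low-pass DC gain √2 per axis). The following
batch norm absorbs the scale; stated explicitly because it changes raw
activation magnitudes. Max pooling's backward pass routes gradient to the
first (row-major) argmax of each 2×2 block; wavelet pooling's backward is
the exact linear adjoint (zero-detail inverse DWT), verified by
inner-product identities and finite differences.

The engine is plain numpy (forward/backward layers, Adam). Every layer's
gradient is checked against central finite differences in the test suite.
Network compute runs in float32 by default (the usual training precision;
~2× faster on CPU BLAS); parameters, the optimizer state and the loss are
kept in float64, and `ModelConfig(dtype="float64")` switches the whole
forward/backward to double precision. The wavelet module itself always
computes in float64; its pooling entry points preserve a float32 caller's
dtype.

Training: cross-entropy over the 2-way softmax on one-hot targets (the
two-class form of binary cross-entropy; log clamped at 1e−12), Adam with
lr 1e-3, β = (0.9, 0.999), coupled L2 weight decay 1e-4 on weights only
(not biases or BN parameters), reduce-on-plateau (halve after 5
non-improving validation epochs), early stopping with patience 10 (max
100 epochs) restoring the best-validation-loss weights. Augmentation
(training only) is geometric: horizontal flip p = 0.5, rotation ±15°,
translation up to 10%, isotropic zoom in [0.9, 1.1]; no intensity jitter.
Splits are stratified 70/15/15 at the image level with a fixed split seed;
per-class banker's rounding sets the val/test cell sizes.

## Metrics and statistics

Positive class = malignant. Conventions: precision := 0 when no positive
predictions exist; F1 := 0 when precision + recall = 0; report tables
round percentages half-even to 2 decimals. AUC is the empirical ROC /
Mann–Whitney statistic with ties counted ½. ECE uses ten equal-width bins
of the positive-class probability (no bin straddles 0.5, so this equals
predicted-class-confidence binning for binary problems); empty bins are
skipped. Platt scaling is a 1-D logistic fit on raw scores; isotonic
regression is clipped to [0, 1].

The Friedman statistic is the plain (tie-uncorrected) formula with average
ranks on ties, referred to χ² with k−1 df; Kendall's W = χ²_F/(N(k−1)).
Nemenyi critical differences use a packaged studentized-range table
(k = 2…10, α ∈ {0.05, 0.10}, infinite df). The exact Wilcoxon signed-rank
test enumerates all 2ⁿ sign assignments (zeros dropped first, n ≤ 20); the
default alternative is one-sided (`greater`), since that is the form under
which five concordant seeds yield p = 1/32; report tables *truncate*
p-values to 4 decimals so 1/32 prints as 0.0312. DeLong's test uses the
structural-components (midrank placement) covariance estimator. BCa
intervals compute the bias correction from the fraction of bootstrap
replicates below the point estimate and the acceleration from jackknife
skewness; degenerate (zero-variance) statistics return a zero-width
interval; statistics accepting an `axis` argument are evaluated on all
resamples at once.

## Grad-CAM

Maps are taken from the last convolutional block's post-ReLU activations:
α_k is the spatial mean of ∂y_c/∂A_k (y_c the pre-softmax class score),
the map is ReLU(Σ_k α_k A_k), bilinearly upsampled to the input size and
max-normalized (all-zero maps stay zero). Pointing-Game hits require the
first row-major argmax pixel to fall inside the lesion mask; ties are
broken by that same first-index rule.

## Phantom generator

Each phantom is a textured background (Gaussian-filtered white noise,
default amplitude 0.06 around mean echogenicity 0.55) containing one
hypoechoic lesion (contrast 0.30, radius 12–20% of the frame) with a
radial-harmonic boundary r(θ) = r₀(1 + Σ_m a_m cos(mθ + φ_m)):

* benign — orders {2, 3}, amplitude 0.03: smooth, oval, circumscribed;
* malignant — orders {4…9}, per-order amplitude 0.10 (drawn in
  [0.5, 1]×amplitude): irregular, spiculated margins with peak boundary
  excursions near half the radius, matching the qualitative morphology
  radiologists use (margin irregularity is the class signal; lesion size,
  position and background statistics are identically distributed across
  classes so no shortcut feature exists).

Margins are softened by a 1 px Gaussian blur; speckle, when requested, is
applied last so the pre-speckle image is a clean reference for despeckling
experiments. Generation is deterministic per (label, spec, seed), and
each dataset sample carries its own child seed.

What the generator does *not* emulate: point-spread-function physics,
spatially correlated speckle, log-compression, acoustic shadowing and
posterior enhancement, heterogeneous tissue layers, multi-lesion frames,
and inter-patient appearance correlation. Tests that pass on phantoms
therefore demonstrate that the pipeline's mechanics are correct and that
its robustness ordering holds under the stated noise model — not that any
accuracy level transfers to clinical data.

## Desk-scale problem sizes

The package's benchmarks run on CPU-sized problems, chosen once:

* end-to-end training benchmark: 400 phantoms at 64×64 (280/60/60 split),
  high-contrast setting (contrast 0.35, texture 0.05), B=3, Sym2, batch 8,
  ≤ 30 epochs;
* 5-seed robustness comparison (Sym2+despeckling vs max pooling, trained
  and evaluated at 20% speckle, matching the factorial-grid semantics):
  240 phantoms at 64×64, batch 8, ≤ 25 epochs. 64×64 is the smallest
  frame at which both arms rise above chance under this noise level —
  at 32×32 the lesion-margin signal is sub-pixel after despeckling and
  the comparison degenerates;
* grid runner defaults: 240 phantoms at 32×32 (a smoke-scale default;
  pass a larger `image_size` for scientifically meaningful sweeps).

The architecture, optimizer and protocol are exactly those described
above; only data volume and image size are scaled down. The full
224×224 input (spatial trace 224→112→56→28 for B=3) is supported and
tested at the shape level.

## Known limitations

* The numpy engine is single-threaded (BLAS aside) and meant for
  desk-scale studies, not GPU-scale training.
* Image-level (not patient-level) splitting is the only option for
  phantoms; on real data this can inflate internal estimates when
  multiple frames share a lesion.
* The despeckler's universal threshold is derived for additive Gaussian
  noise; it is applied here to multiplicative speckle without a log
  transform, which is the standard practical shortcut but not optimal.
* Exact Wilcoxon enumeration is limited to n ≤ 20 pairs; larger samples
  need an approximation that is deliberately out of scope.
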