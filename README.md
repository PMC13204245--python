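# wavepool

Wavelet pooling and wavelet-domain despeckling for robust classification of
speckle-corrupted ultrasound-style images, with a full evaluation,
statistics and interpretability stack and a built-in synthetic
lesion-phantom generator.

## The problem

B-mode ultrasound is cheap, portable and non-ionizing, which makes it the
workhorse of breast-lesion triage in low-resource settings — but coherent
imaging produces *speckle*: granular, signal-dependent multiplicative
interference that blurs lesion margins and texture, precisely the cues that
separate benign from malignant masses. Standard CNN downsampling is part of
the problem: max pooling latches onto noise spikes, average pooling smears
fine margins.

`wavepool` implements an architectural alternative: replace 2×2 pooling
with **wavelet-LL pooling**. Each feature map `F` is decomposed by a
one-level 2-D discrete wavelet transform with a least-asymmetric
orthonormal (Symlet) basis, and only the approximation band is kept:

    P(F) = LL = W_symN(F)|_LL ,   N ∈ {2, 4, 6}

This halves each spatial dimension like stride-2 pooling, but the reduction
happens *after* a multiscale filter bank, so high-frequency speckle is
pushed into the discarded LH/HL/HH bands. Optionally, inputs are first
despeckled in the wavelet domain by VisuShrink-style soft thresholding:

    d~ = sign(d) · max(|d| − λ, 0),   λ = σ̂ · sqrt(2 ln N),
    σ̂ = median(|HH₁|) / 0.6745

The package provides:

* `wavepool.wavelets` — Symlet filter banks (4/8/12 taps, N vanishing
  moments) and separable 2-D DWT/IDWT with exact reconstruction;
* `wavepool.noise` — multiplicative Gaussian speckle `I·(1+n)`,
  `n ~ N(0, σ²)`, plus a standardized Rayleigh-type variant and PSNR;
* `wavepool.despeckle` — the 2-level soft-threshold despeckler;
* `wavepool.pooling` / `wavepool.nn` / `wavepool.model` — average, max and
  wavelet-LL pooling with exact adjoint backward passes inside a compact
  CNN (3–4 conv–BN–ReLU–pool blocks, 32→64→128(→256) channels, GAP,
  128-unit head, dropout 0.5, softmax), implemented on numpy with
  finite-difference-verified gradients;
* `wavepool.training` — Adam (lr 1e-3), L2 1e-4, reduce-on-plateau,
  early stopping, geometric augmentation, per-noise-level evaluation;
* `wavepool.metrics` — confusion metrics, ROC AUC, Brier, ECE,
  reliability curves, Platt/isotonic recalibration;
* `wavepool.stats` — Friedman + Kendall's W, Nemenyi critical differences,
  exact Wilcoxon signed-rank with rank-biserial effect size, DeLong's test
  for correlated AUCs, BCa bootstrap CIs;
* `wavepool.gradcam` — Grad-CAM heatmaps and Pointing-Game scoring;
* `wavepool.phantom` — seeded B-mode-like phantoms (textured background,
  one hypoechoic lesion; smooth oval margins for benign, spiculated
  radial-harmonic margins for malignant) with ground-truth masks;
* `wavepool.experiments` + the `wavepool` CLI — the 108-configuration
  factorial grid (6 pooling × 2 depths × 3 batch sizes × 3 noise levels,
  5 seed-repeats each) and report generation.

## Worked example

```python
import numpy as np
from wavepool import (PhantomSpec, generate_dataset, ModelConfig,
                      PoolingConfig, build_model, TrainConfig,
                      train_model, evaluate)
from wavepool.phantom import dataset_arrays

spec = PhantomSpec(size=64, lesion_contrast=0.35, texture_amplitude=0.05)
samples, manifest = generate_dataset(400, 0.5, spec, seed=2024)
x_tr, y_tr = dataset_arrays(samples, manifest, "train")
x_va, y_va = dataset_arrays(samples, manifest, "val")
x_te, y_te = dataset_arrays(samples, manifest, "test")

model = build_model(ModelConfig(blocks=3,
                                pooling=PoolingConfig("wavelet", order=2),
                                input_size=64), seed=0)
train_model(model, x_tr, y_tr, x_va, y_va,
            TrainConfig(batch_size=8, seed=0, max_epochs=30))
report = evaluate(model, x_te, y_te, noise_levels=[0.0])[0]
print(f"test accuracy {report.accuracy:.3f}  AUC {report.auc:.3f}")
```

This trains the 3-block Sym2-pooled network on 280 clean phantoms and
prints (on this seed):

```
test accuracy 1.000  AUC 1.000
```

meaning all 60 held-out phantoms are classified correctly and the
malignant/benign score ordering is perfect. Degrading the test
set with 20% speckle (`noise_levels=[0.2]`) lowers both numbers, which is
the robustness axis the package exists to measure.

A quick look at the statistics layer:

```python
from wavepool.stats import wilcoxon_signed_rank_exact, truncate_p
res = wilcoxon_signed_rank_exact([.93, .91, .95, .90, .92],
                                 [.85, .86, .84, .83, .88], "greater")
print(truncate_p(res.p_value), res.effect_size)   # 0.0312 1.0
```

With five paired seeds all favoring one method, the exact one-sided
signed-rank tail is 1/32 — printed as 0.0312 — with a rank-biserial
effect size of 1.0.

## Command line

```bash
wavepool phantoms --n 600 --balance 0.5 --seed 1 --out data/
wavepool corrupt --kind speckle --level 0.2 --seed 7 in.png out.png
wavepool denoise --order 2 --levels 2 in.png out.png
wavepool dwt --order 2 --levels 2 in.png subbands/
wavepool summary --blocks 3 --pooling sym2
wavepool grid --out results.csv --n-phantoms 240 --image-size 32
wavepool stats results.csv --out report/
```

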