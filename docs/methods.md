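# Methods

## Counting by density estimation

Egg counting is cast as per-pixel regression rather than detection. A dot
annotation places one labelled pixel at each egg centre; the training
target is a density map in which every dot contributes a unit-integral
2-D Gaussian, so that the sum of the map over any region equals the egg
count of that region. A tree ensemble learns to map local image appearance
(a multiscale filter-bank descriptor) to density, and the count of an
unseen image is the sum of its predicted map. Because no per-egg decision
is ever made, the approach degrades gracefully where eggs touch, overlap
or sit half-buried in the medium — exactly where detectors fail.

### Density kernel

`DensityConfig(sigma=1.0, truncation_radius=4.0)`. The kernel is evaluated
at pixel centres over a `(2⌈Rσ⌉+1)²` window and divided by its window sum,
so each interior dot carries **exactly** unit mass and count-by-summation
is an identity, not an approximation. σ is in pixels and should stay
smaller than the egg so neighbouring kernels barely interact; it scales
with image resolution. The truncation radius must be ≥ 3σ (untruncated
tail mass < 1e-3). Mass clipped at the image border is lost, matching what
convolving a dot grid with a finite kernel does; note that for a dot on
the border the *discrete* retained mass is larger than the continuous
intuition suggests (a corner dot keeps ≈ 0.49, not 0.25, at σ = 1,
because the kernel's centre row and column are not split between
quadrants).

### Feature descriptor

Four rotation-invariant responses per channel and scale: Gaussian gradient
magnitude, Laplacian of Gaussian, and the two eigenvalues of the structure
tensor (gradients at inner scale σ/2, tensor smoothed at outer scale σ).
Defaults: scales (0.8, 1.6, 3.2, 6.4, 12.8) on R, G, B → 60 features.
All filtering uses reflect boundaries; integer images are scaled to [0, 1]
(8-bit ÷ 255, 16-bit ÷ 65535) so models transfer across bit depths.

The Laplacian is computed by composing two first-derivative Gaussian
kernels (each at σ/√2 per axis) rather than sampling the second-derivative
kernel directly: sampled second-derivative kernels have a nonzero DC term
at small σ (≈ 4·10⁻⁴ at σ = 0.8), which would give constant image patches
a spurious response, while first-derivative kernels are exactly
antisymmetric and therefore exactly null on constants. The structure
tensor is PSD by construction; its closed-form minimum eigenvalue is
clipped at zero only to absorb floating-point round-off.

### Regressor

`sklearn.ensemble.ExtraTreesRegressor`, which implements the required
split family (per candidate: one random feature with one uniformly random
threshold between the node's observed min and max; best of `sqrt(F)`
candidates by variance reduction). Defaults: 30 trees, fully grown,
min 1 sample per leaf, no bootstrap, single thread. Predictions are leaf
averages of non-negative targets, so predicted densities are non-negative
by construction and no clamping stage exists. A single integer seed makes
training deterministic.

Training rows are all pixels of the labelled ROIs; density targets are
computed on the full image and then cropped, so kernel tails from eggs
just outside an ROI still contribute. Whole 600×600 images are ~360k
pixels each, so `max_pixels` offers a seeded uniform row subsample
(the LOOCV driver defaults to 40 000 pixels per fold); uniform subsampling
leaves the regression function unbiased and, in practice, counts shift by
well under the ensemble's own seed-to-seed variability.

One consequence of fully grown trees worth knowing: a model evaluated on
its *own* training image with *all* pixels used reproduces the training
density exactly, so training-region (PC, AC) pairs are collinear on the
identity and the bias fit (below) degenerates. Any of subsampling,
held-out regions, or cross-prediction breaks the interpolation and yields
an informative bias line; the CLI warns when the degenerate case occurs.

### Bias correction

Raw summed counts regress toward the mean of the training counts. The
correction is ordinary least squares of actual on predicted region counts
(slope β, offset c, via `numpy.polyfit`), requiring ≥ 3 regions with ≥ 2
distinct predictions; corrected counts are CC = β·PC + c, reported as-is
(a negative extrapolation warns rather than clamps). Uncertainty feedback
is the standard OLS *new-observation* prediction interval at 95%
(t-distribution, n − 2 df) — a prediction interval rather than a
confidence-of-mean interval because the user's question concerns a single
new vial. Exactly collinear pairs give a zero-width interval and are
flagged (`BiasModel.degenerate`); residual sums of squares at round-off
level (≤ 1e-20 relative) are snapped to zero so that exact collinearity is
recognised in floating point.

### Evaluation protocol

Percent accuracy is `100 − mean(|PC − GT|/GT)·100`; the raw mean relative
error is also exposed. The formula divides by GT, so images with zero
ground truth are rejected by name. LOOCV holds out each image in turn,
trains on the rest (whole images as training regions), refits the bias
line *inside the fold* on the training images' own (predicted, actual)
pairs — the only leakage-free reading — and evaluates the held-out image.
The sweep is repeated for `n_replicates` (default 5) with seeds derived
from a master seed, and summarised as mean ± SE (ddof = 1, n =
replicates). `n_training_images` optionally subsamples the training pool
per fold, which produces training-curve experiments; with fewer than 3
training images the bias line cannot be fitted and only raw accuracy is
reported.

## Synthetic vial images

The generator renders what the counting problem actually contends with,
not photorealism: a circular food surface under a radial illumination
falloff; bright anti-aliased ellipsoidal eggs (half-axes 4–7 × 1.5–2.5 px,
random orientation, per-egg intensity jitter, 30% of eggs placed within
one egg-length of another to form clumps, overlap permitted); artefacts —
bubbles (dark discs with bright refraction rims), broad specular streaks,
dark marks near the vial base; and additive sensor noise. Dot ground truth
is the rounded ellipse centres, exact by construction. All randomness
flows from one seed; datasets derive per-image seeds from a master seed
and record them in a manifest, so every image is independently
regenerable.

Two media are modelled. *Translucent* (defined medium): pale, smooth,
low-texture — eggs stand out cleanly. *Opaque* (yeast-based): darker
yellow-brown with egg-scale speckle, small bright grains whose size and
colour overlap the dimmer eggs, a wider per-egg visibility range
(partial burial), and surface roughness composited over the eggs. These
choices were iterated until the opaque medium is *genuinely* harder for
the pipeline, reproducing the transparent > opaque accuracy ordering that
motivates treating the two media separately; with the final settings the
ordering holds on every one of five matched-seed dataset replicates, not
just on their average.

What passing tests on this generator does and does not show: the
synthetic scenes exercise clustering, occlusion, confuser textures,
artefact robustness and the count-range bias phenomenon, and the pipeline's
behaviour on them mirrors the qualitative structure expected on real vial
photographs (raw accuracy in the 80s, corrected in the 90s, correction
helping in nearly every replicate). They do not capture real optics
(defocus, chromatic effects), real yeast-surface statistics, cracked or
furrowed media, or eggs inserted vertically into crevices — absolute
accuracies on real images can differ even though the relative effects
(bias correction helps; more training helps; translucent beats opaque) are
the ones the test suite pins down.

## Problem sizes of the gating experiments

The held-out-recovery experiment uses the full stated conditions: 8
translucent 600×600 images spanning counts 15–410, hold-one-out with 5
replicates, 30 trees, 40k training pixels per fold. The
repeated-training experiment uses one 400×400 image with 150 eggs and 30
seeds; the training-curve experiment 6 images at 300×300 (counts 20–100,
1 vs 2 training images, 3 replicates, raw accuracy); interval coverage
2000 simulated 10-point datasets; reproducibility checks 160×160
3-image datasets. These sizes are the package's own desk-scale choices
and are recorded here so the experiments are interpretable and exactly
repeatable.

## Known limitations

- The mask annotation dialect cannot express two eggs on the same pixel;
  the CSV dialect can (duplicates are legal dots).
- Counts are real-valued; no rounding is applied anywhere, since sums of
  densities are the estimator the whole chain is calibrated for.
- The bias line is affine only; strongly nonlinear miscalibration (e.g.
  saturation at extreme densities) is out of scope.
- Model archives refuse to load across scikit-learn versions rather than
  risk silently different tree predictions.
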