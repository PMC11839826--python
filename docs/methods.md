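# Methods

## Model and assumptions

A planar scintigraphic image is a grid of independent Poisson counts: pixel
(i, j) records N_ij ~ Poisson(λ_ij · t), where λ is the expected emission
rate imaged into that pixel and t the frame duration. Two consequences
drive everything in this package: the variance of a pixel equals its mean
(relative noise 1/√mean), and binning events into larger pixels — spatially
or temporally — is again Poisson. Resizing operators are therefore judged
by whether their output is distributed like an image the camera itself
could have produced at the target grid.

The two corrected operators follow directly:

* **Downsampling by an integer factor f** sums non-overlapping f×f blocks.
  Sums of independent Poisson variates are Poisson, so counts and noise are
  exact by construction.
* **Upsampling by f** linearly interpolates onto the fine grid, rounds half
  up to integers, and binomially thins each pixel with p = 1/f². Thinning a
  Poisson(m) variate gives Poisson(p·m), so the expected total returns to
  the source total while each output pixel acquires the counting noise of
  its (f²-times smaller) expected count. The thinning itself performs the
  count rescaling: applying a global 1/f² scaling *before* thinning with the
  same p would shrink the total twice, so the scaling step belongs only to
  the naive (interpolation-only) comparator.

The naive comparators are plain separable linear interpolation: upsampling
without noise injection (total corrected by a global 1/f² scale), and
bilinear downsampling (optionally rescaled by f²), deliberately without an
anti-aliasing pre-filter — the comparator is the plain resampling a generic
image library would perform.

## Interpolation convention

All linear resampling uses half-pixel-centre alignment with replicate
padding: output sample j reads source coordinate (j + 0.5)·(n_src/n_dst) −
0.5, clamped to the grid. This convention is load-bearing:

* each source pixel receives total interpolation weight f per axis, so a
  factor-f upsample multiplies the total by exactly f² (the worked 2×2→4×4
  example: 134 counts → 536.0, exactly, since all weights are binary
  fractions for power-of-two factors);
* a factor-2 downsample lands exactly mid-way between pixel centres, making
  each output the exact mean of its 2×2 block — hence f²·(2× bilinear
  downsample) ≡ 2×2 block summation, and the two downsampling methods only
  diverge for f ≥ 4, where the bilinear kernel sees just the central 2×2
  neighbourhood of each block. That blindness is the documented failure
  mode of naive downsampling, so it is preserved, not patched.

The resampler is implemented as an explicit 1-D weight-matrix operator
(W_rows · X · W_colsᵀ) rather than through a generic zoom routine, because
the convention above and its exact count arithmetic are the substance being
tested. Non-divisible shapes and non-integer factors are rejected.
Rounding before thinning is round-half-up, fixed and documented.

## Similarity metrics

Both metrics operate on images normalized to [0, 1] by their own maximum
pixel; an all-zero image has no defined normalization and raises. SSIM is
the *global*, single-window statistic: means, population variances
(divide by M·N) and covariance over the whole image, with stabilizing
constants c₁ = 0.01·L and c₂ = 0.03·L (L = 1 after normalization) — the
constants as written, not the conventional squared form (k·L)², which is
available via `SsimParams(constant_mode="squared")` and is the form
cross-checked against scikit-image in the tests (full-image window, uniform
weights, population covariance). A Gaussian-windowed mean-local SSIM is
exposed as `windowed_ssim` for sensitivity analysis only. Log MSE is
log₁₀ of the pixelwise mean squared error; it is undefined for identical
images and raises rather than returning a sentinel, because a silent
sentinel would corrupt curve averages.

## The phantom simulator

The simulator emulates a dynamic planar acquisition of a torso phantom
whose only activity lies in two lung fields: 100 frames of 1 s, ~11,000
expected counts per frame (1.1 Mcnts total), on 64×64 / 128×128 / 256×256
grids covering one fixed field of view (pixel spacings 6.59 / 3.29 /
1.64 mm, zoom 1.45). The activity map lives on a 512×512 "physical" grid —
a common multiple of all acquisition grids — so rendering to any grid is an
exact block-sum integral and the projections nest exactly (the grid-n image
is the f×f block sum of the grid-f·n image). Every frame pixel is an
independent Poisson draw from the rendered expectation.

The map itself is parametric: two tilted ellipses (the left slightly
smaller, a nod to the cardiac notch) with a smooth radial falloff, modulated
by a multiplicative log-normal texture with ~21 mm correlation length
(extent/20) and 0.35 log-amplitude, then normalized to the per-frame count
total. The texture scale represents the lung filling heterogeneity *as
imaged*: real collimated cameras suppress structure much below ~10 mm, so
the effective image content is smooth at the 64-grid pixel scale. This
matters: structure finer than the coarse grid cannot be recreated by any
upsampling method, so a phantom with strong sub-6.6 mm detail would make
even the corrected method fail against a fine-grid reference — a statement
about simulation fidelity, not about the operators. Each of the six
planar views (ANT/POST/LAO/RPO/LPO/RAO) gets a distinct map via
rotation/mirroring of the base geometry and its own texture stream.

Not modelled: attenuation, scatter, collimator blur, detector
non-uniformity, decay and dead time. Passing experiments therefore show
that the operators preserve Poisson count statistics of an idealized
acquisition; they do not probe resolution- or scatter-related effects in
real data.

All randomness flows from one root seed through `numpy.random.SeedSequence`
spawn keys per (view, grid, purpose), so every simulation and experiment is
bit-reproducible, and independent acquisitions of the same object are drawn
from independent child streams.

## Permutation experiments

Count level is expressed in summed frames k (nominal 11·k kcnts); the
full-count image sums 50 frames so two disjoint full-count images fit in
one 100-frame series. Per level and permutation:

* **reference**: two disjoint k-frame subsets → two native images → metrics;
* **low-count**: two disjoint 50-frame images, each thinned with p = k/50;
* **up/downsampling**: a k-frame image at the source grid, resized by the
  method under test, against an independently drawn k-frame native image at
  the target grid (source and target come from independently simulated
  series of the same activity map, so independence is automatic).

Curves aggregate the mean and the 2.5th–97.5th percentile band over
permutations (1,000 by default; the bundled validation runs use 200
permutations and levels {1, 5, 10, 50}, which keeps the full suite under a
minute while leaving the method contrasts unambiguous). The percentile
band was chosen over a normal approximation because the metric
distributions are skewed at low counts. Curve agreement is quantified per
level by closed-interval intersection of the bands; `overlap_fraction` is
the share of levels whose bands intersect, and `max_ci_distance` normalizes
the largest band gap by the mean half-width of the two bands.

## Observed behaviour of the global SSIM under per-image normalization

One directional result deserves a caveat. With the global SSIM and
per-image max normalization, naively upsampled images score *below* the
reference curve (while their Log MSE sits above it, and the curves separate
cleanly from the reference band). The mechanism is intrinsic: at low count
densities the native image's maximum pixel is noise-inflated several-fold
relative to the smooth interpolated image's maximum, so per-image
normalization leaves the smooth image with a larger normalized mean and a
larger normalized global variance, depressing both the luminance and
structure terms. A mean-local windowed SSIM, or normalizing both images by
a shared maximum, can flip this direction (each at the cost of other
contrasts). The package treats the band-separation verdict — naive
upsampling is *not* statistically exchangeable with native acquisition,
corrected upsampling is — as the operative result; the sign of the SSIM
deviation depends on metric implementation details and should not be
interpreted on its own.

## Numerical and degenerate-input choices

* Count images are immutable int64 arrays; negative or fractional pixels
  are rejected (integral floats are accepted and cast).
* Thinning requires p ∈ [0, 1]; p = 1 is the exact identity, p = 0 the
  empty image.
* 16-bit storage (PNG/DICOM) raises on overflow rather than truncating;
  at the simulated count levels the per-pixel maximum stays far below
  65,535.
* The printed pixel spacings are rounded values, so spacing validation
  checks inverse proportionality to grid size at 1% rather than exactly.
* `curve_agreement` requires matching metrics and levels; empty curves are
  vacuously in full agreement.

## Known limitations

Only integer resize factors (2 and 4 validated) on divisible grids;
non-integer factors would need spatially varying summation windows or
up-then-down cascades. 2-D planar images only — tomographic volumes pass
through reconstruction steps that break the raw-count assumptions, and
PET-style activity-density units do not encode counts at all. The
simulator's idealizations (no scatter/blur) are listed above; conclusions
about metric *directions* (as opposed to band separations) transfer to real
acquisitions only with care.
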