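# Methods

This note documents the models and numerical choices behind `octavd`:
what each processing stage computes, how the synthetic phantoms are
built and calibrated, and what the phantom-based evaluation can and
cannot say about real conjunctival OCTA.

## Images, regions and conventions

Images are 8-bit single-channel rasters with 0-based row-major
coordinates.  Non-conjunctival regions (cornea, eyelids) are excluded
by an ROI mask: excluded pixels are set to 0 *and* flagged invalid.
Filters run over the full raster — morphology and frequency filters
need spatial context — but every statistic (vessel density, confusion
counts, global thresholds) is computed over valid pixels only, so
denominators are always explicit.  The VD denominator defaults to the
valid region (`valid_only`); `full_frame` is available where the whole
raster is the region of interest.

Filters compute in floating point and quantize to 8 bits (round half
up) only at the module boundary.  Binarization is strict (`intensity >
threshold`), so flat regions under mean/median/Otsu thresholds
binarize to background deterministically.  A guard epsilon of 1e-6
protects the strict comparison against FFT round-off in the
convolution-based local statistics; it is an order of magnitude below
the smallest possible nonzero margin of any disk statistic of 8-bit
data (1/709 gray level for a radius-15 disk), so results equal exact
arithmetic.

## Filtering stages

- **Gaussian blur** — `scipy.ndimage.gaussian_filter`, reflect
  borders; default σ = 4 px in the 3-step recipes.
- **Grayscale closing / white top-hat** — discrete Euclidean disk
  (radius 1–2 px for closing, 15 px default for top-hat), reflect
  borders.  Closing is extensive and idempotent; the top-hat is
  bounded by 0 ≤ out ≤ in and vanishes on flats.  The top-hat radius
  is a package default: the protocol names no structuring element
  size, so it is exposed in the config.
- **FFT bandpass** — removes structures ≤ 2 px and ≥ 50 px.  The
  transfer function is a difference of two Gaussians in the Fourier
  domain; a structure of diameter d maps to a spatial Gaussian of
  σ = d/3, which places the band so that a 20-px-period wave passes
  essentially unattenuated, a 2-px wave is suppressed ~100×, and a
  200-px wave retains < 20 % of its amplitude.  The image is
  mirror-extended before the transform; the DC component is removed by
  construction; the response is min-max rescaled to [0, 255]
  (the autoscale convention of the common FFT-bandpass tools).
- **Frangi vesselness** — `skimage.filters.frangi`, bright ridges,
  maximum over scales {1…5} px, β = 0.5, structureness normalization
  at half the maximal Hessian norm per scale (standard defaults; the
  protocol does not state them); output scaled so the peak response
  maps to 255.
- **Cornea suppression** — pixels below the mean of three avascular
  reference intensities are zeroed.  The references default to three
  13×13 patches from the image's avascular corner (see phantoms).

## Thresholding operators

Global operators use the valid-pixel mean or an exhaustive Otsu search
over all 256 cutoffs (maximizing between-class variance; smallest
maximizer on ties; a single-level histogram is flagged degenerate).

Local operators use a discrete disk neighborhood, radius 15 px by
default with offset C = 0 (the protocol states the radius only for
Phansalkar; the same radius is applied to mean/median/Otsu, and both
are configurable).  Mean and Phansalkar statistics come from FFT
convolution with reflect padding; the rank-based local median (upper
median on even counts) and local Otsu crop the neighborhood at the
image border — both conventions agree away from the border, and
interior translation equivariance is tested.  A local-Otsu window with
a single gray level has no two-class split and binarizes to
background.

The Phansalkar threshold operates on intensities normalized to [0, 1]
with the original constants k = 0.25, r = 0.5, p = 2, q = 10.  Note a
formula consequence: on a flat region of normalized level μ the
threshold is μ·(0.75 + 2e^(−10μ)), which drops below μ once
μ > ≈ 0.21 — a featureless mid-gray image is classified entirely as
flow.  This is faithful to the published formula (its exponential
term is a *low*-mean correction) and is why the method is paired with
filters that darken the background.

## Method registry

The registry enumerates 27 combinations: the six 1-step thresholds
(manual, global mean/Otsu, local mean/Otsu/Phansalkar), closing (1 or
2 px) / top-hat / bandpass / Frangi each followed by the local
thresholds, and the 3-step recipes (Gaussian + bandpass + local,
cornea suppression + closing + mean local, bandpass + top-hat +
Otsu/Phansalkar).  Methods carrying a published reliability row are
named by their printed labels; figure-panel-only variants carry the
panel tag.  The Gaussian/bandpass 3-step method applies the blur
first, following the protocol text rather than the label's word
order.  `step_count` equals the number of stages (the top-hat + mean
recipe is a 2-stage method regardless of how the published table
groups it).

The manual threshold is automated as simulated graders: each of three
graders picks the image's valid-pixel mean plus an upward half-normal
miss (SD 8 gray levels), and their average cutoff is applied.  Upward
spread encodes that graders aim above the background-dominated mean;
it also makes a featureless image binarize to 0 % VD.

## Evaluation

Confusion counts, sensitivity, specificity and accuracy follow the
definitions in the README; metrics are computed per image and then
averaged (the published protocol is explicit only for accuracy;
pooled-count aggregation is available by flag).  The 95 % CI on mean
accuracy is t-based with n−1 degrees of freedom.  The AUC is the
sens/spec average rounded half-up to 3 decimals.

Reliability is ICC(A,1) — two-way random effects, absolute agreement,
single measure — computed from the two-way ANOVA mean squares with the
McGraw–Wong F-based confidence interval (cross-checked against
`pingouin` in the test suite).  The published protocol states
"absolute agreement" but not the model form; ICC(A,1) is the standard
choice for individual scores from fixed raters.  The ≥ 0.750 gate is
inclusive.  Bland-Altman limits are bias ± 1.96·SD of the paired
differences (sample SD); regression R² is ordinary least squares.

## Synthetic phantoms

Each phantom is a 400×400 raster with a known truth mask:

- **Vessels**: bounded random walks entering from a border, heading
  jitter SD 0.25 rad per step, caliber 2–10 px wandering within
  bounds, stamped as disks.  Vessels are added until the truth VD
  reaches its target (±3 percentage points; up to 8× the nominal
  vessel count before giving up).  A 40×40 corner is kept avascular
  as the stand-in cornea.
- **Rendering**: gamma speckle background (mean 28, SD 22, correlation
  length 2 px) plus a gamma-distributed flow signal (mean 88, shape 6)
  on vessel pixels, modulated by a smooth multiplicative illumination
  field (amplitude 0.5, correlation length 100 px, zero-centered per
  image), lightly blurred (σ 0.6) and quantized.

The illumination field models the uneven signal strength of
anterior-segment scans and is the feature that separates local from
global thresholds: without it a single global cutoff is near-optimal
and the comparison is uninformative.  Defaults were calibrated once so
that a 14-phantom battery reproduces the published image envelope —
per-image gray-value mean within [38, 73], SD within [45, 65],
skewness within [0.5, 1.8] — and a gold-standard VD distribution
around 33.9 ± 5.7 %; battery targets are drawn from N(33.9, 5),
clipped to [26, 42] %.

Grader variability is simulated by thresholding each phantom at its
Otsu level plus an independent normal miss per grader (SD in gray
levels), yielding an images × graders VD matrix for ICC exercises;
zero jitter gives ICC exactly 1, and the ICC decreases as the jitter
grows.

### What the phantoms do and do not show

The phantoms reproduce first-order gray statistics, vessel geometry,
speckle-like noise and spatial gain variation.  They do not model
OCTA decorrelation physics, projection or motion artifacts, imaging
depth effects, or the specific noise structure that manual grading
removes.  Consequently the pipeline's *mechanics* (density recovery,
confusion bookkeeping, reliability gating) transfer to real data, but
the published method *ranking* does not: on phantoms the bandpass +
Phansalkar recipe — the best performer on real conjunctival scans —
over-segments, because the bandpass autoscale leaves the phantom
background at mid-gray where the Phansalkar low-mean correction
vanishes, while plain Phansalkar and closing + Phansalkar perform
best.  Fewer methods pass the ICC gate on phantoms than in the
published study, and which ones pass is seed-dependent.  Holding the
comparison to the published per-method numbers would require the
original proprietary images and grader masks.

## Problem sizes and determinism

The default evaluation battery is 14 phantoms of 400×400 px — the
same image count and format as the study set — and the full 27-method
comparison over it completes in about a minute on one core.  All
randomness flows from integer seeds through `numpy.random.default_rng`;
a phantom, a battery, a grader matrix and a full comparison are
bit-reproducible given the seed.
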