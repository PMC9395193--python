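# Methods

## Scope and shape

The package quantifies population-level osteoblast displacement in
registered two-channel images of regenerating bony rays, plus the tabular
statistics that surround that readout (densities, subtype fractions, area
metrics, mitochondria size classes, internal-standard metabolite levels,
microarray differential expression, qPCR relative quantification). It does
not segment cells, register movies, integrate LC-MS peaks, or reconstruct
mitochondria — those steps are assumed done upstream and their outputs
(registered TIFFs, count/area/volume tables, peak areas, Ct values) are the
package's inputs.

## Boundary detection

Intersegment joints image as darker vertical lines in brightfield. The
detector is an edge-based front end:

1. Gaussian filter, σ = 2 px (both channels see the same filter).
2. Vertical-edge Sobel response (gradient across columns), absolute value.
3. Binarization at the 90th percentile of the magnitude distribution
   (scale-free; a constant image yields an empty mask and a
   `no-boundaries` error).
4. Morphological dilation with a vertical 15 × 1 line kernel, bridging
   breaks in a joint across the ray height.
5. Removal of 8-connected components smaller than 200 px.
6. Column-mean of the surviving mask → 1-D detection profile.
7. Gaussian smoothing of the profile (σ = 8 px) and peak finding with a
   minimum separation of 40 px and a prominence of 1.0 × the profile
   standard deviation.

Step 7's smoothing deserves a note: the absolute Sobel response of a
symmetric intensity dip is a *doublet* — two ridges flanking the dip
center, where the gradient itself vanishes. Peak-picking the raw profile
would localize a ridge (error ≈ the dip half-width); smoothing with a
symmetric kernel merges each doublet into a single peak at the dip center
exactly, for symmetric dips. σ = 8 px merges doublets for dip half-widths
up to ~6 px while leaving peaks ≥ 40 px apart resolved.

The prominence default of 1.0 × SD was chosen after measuring spurious-peak
rates on synthetic images: at boundary SNR 3 a 0.5 × SD threshold admits
occasional noise peaks (including mid-segment ones that corrupt segment
definitions), while 1.0 × SD removes them without missing any true
boundary down to SNR 1.5 on the synthetic benchmark.

Plateau ties in the peak finder resolve to the leftmost plateau sample.
An alternative `mask_mode="weighted"` profiles the Sobel magnitude under
the surviving mask instead of the binary mask itself.

**Segment labeling.** Boundaries strictly proximal to the amputation column
define segments. Because the amputation cut falls mid-segment, segment 0
defaults to the most distal *complete* segment (between two detected
boundaries), which has a well-defined length for the ratio denominator;
`mode="to_amputation"` instead spans the last boundary to the amputation
plane. Columns are 0-based; intervals half-open [x_start, x_end). A
`proximal_left` flag mirrors everything for the opposite orientation.

## Displacement ratio

Within a segment, the GFP channel (Gaussian-filtered at the same σ = 2 by
default) is summed over rows into a line profile; the intensity-weighted
mean column is the center of mass; the ratio is its position as a fraction
of segment length, oriented so that 0 always means anterior/proximal bias
and 1 posterior/distal bias. The center of mass is reported sub-pixel,
unrounded. Ratios are clamped only against floating-point spill ≤ 1e-9;
a genuinely out-of-segment center of mass raises an error.

For time-lapses, boundaries are detected once on frame 0 and reused
(`boundary_mode="first_frame"`): joints are static in registered movies and
re-detection would add frame-to-frame jitter to the motility signal.
Segments whose profile carries no positive net intensity (possible under
zero-mean noise when a segment holds no cells) yield NaN center-of-mass and
ratio rows rather than aborting the movie; the scalar operation
`profile_center_of_mass` itself still raises `empty-profile`.

Because the center of mass is sensitive to constant offsets, an optional
`background_percentile` subtraction is available; it defaults to off.

## Synthetic data

The generator renders what the detector assumes: a bright ray
(baseline 100 intensity units) with multiplicative Gaussian-profile dips
(depth 0.6, half-width 3 px) at the intersegment columns, and a GFP channel
of isotropic Gaussian blobs (amplitude 150, radius 8 px; an aspect-ratio
parameter allows elongation). Defaults place boundaries at columns
100/300/500 of a 120 × 600 px frame with the amputation plane at 550, so
segment 0 is the 200-px interval [300, 500).

Noise is additive Gaussian with an optional signal-proportional variance
term. Brightfield noise defaults to SD 20, i.e. a boundary signal-to-noise
ratio (dip depth × baseline / noise SD) of 3. GFP detector noise is a
separate physical quantity and defaults to SD 5, reflecting the high
contrast of a transgenic reporter under confocal imaging (blob peak SNR
30). Noise is deliberately **not** clipped at zero — clipping gives the
noise a positive mean, which drags every intensity-weighted center of mass
toward the segment midpoint; small negative excursions are the realistic
behaviour of offset-subtracted camera data, and all downstream statistics
tolerate them.

Ground truth is analytic: the rendered blob is separable, so the exact
noise-free column profile (and hence center of mass and ratio per segment)
follows from the blob parameters using discrete Gaussian row sums, matching
the rendered image to machine precision. Planted structure in the tabular
generators is exact by construction: expression matrices receive
±`effect_log2` group shifts for exactly `round(frac · n)` genes; Ct tables
shift the treated-condition mean Ct by −log2(fold) under perfect
amplification efficiency 2; mitochondria volumes come from a log-normal
mixture whose component medians and log-SDs are specified (log-SD 0
collapses a component to its center).

What the generator does **not** emulate: photorealistic texture, curved or
tapering rays, uneven illumination, blob shape changes, multi-ray frames,
registration error, and any regeneration biology (proliferation,
signalling). Passing recovery tests therefore demonstrate correctness of
the measurement machinery under the stated image model, not robustness to
every real-microscopy artifact.

## Expression statistics

**Quantile normalization** maps every sample onto the cross-sample mean of
sorted values; within-column ties receive the mean of the target values
their sorted positions span. The transform preserves the grand mean and
makes all column distributions identical — which also means a globally
uniform group shift is removed by construction, and genes at the extreme
tails of the common distribution can absorb rank-displacement artifacts
when strong unbalanced effects are present (visible in the test suite as
edge-gene call mismatches that vanish away from the tails).

**Welch's t-test** is computed from the closed form (mean difference over
√(s²x/nx + s²y/ny), Welch–Satterthwaite degrees of freedom, two-sided p
from the t distribution) so that t, df and p are all exposed. Two zero
variances with equal means return p = 1 by convention; with different
means they raise `degenerate-variance`. A caveat that matters at this
package's sample sizes: with n = 3 per group the Welch–Satterthwaite
approximation is conservative — on ideal normal equal-variance nulls its
true rejection rate at nominal 0.05 is ≈ 0.035 (reproduced independently
by scipy and by R's `t.test`). Null p-values are therefore approximately,
not exactly, uniform, and per-gene power at microarray-scale multiplicity
is limited; variance-moderated approaches (e.g. empirical-Bayes shrinkage)
trade that away but are a different method and are out of scope here.

**FDR adjustment** defaults to a two-stage adaptive Benjamini–Hochberg
procedure: a first-pass BH at α/(1+α) estimates the number of true nulls
m₀ = m − r₁, and the BH-adjusted p-values are scaled by m₀/m. This variant
always rejects a superset of plain BH at the same α; its rejection set sits
between statsmodels' `fdr_tsbky` (which multiplies by 1+α) and `fdr_tsbh`
(which estimates m₀ at level α). Plain BH (via statsmodels) is selectable.

**Calls** require significance (adjusted p below α by default; raw
selectable) *and* |log2FC| above the threshold (default 1), with log2FC the
difference of group means of log2-normalized intensities.

**2^−ΔΔCt** averages technical replicates per (sample, gene), takes ΔCt
against the housekeeping reference within each sample, ΔΔCt against the
baseline condition's mean ΔCt, and reports 2^−ΔΔCt. Amplification
efficiency is assumed exactly 2; no efficiency correction is applied.

## Scalar metrics

Densities are count / area × 100 (per 100 µm²); subtype fractions are
percentages of the listed markers' summed count; regenerated areas are
normalized per animal by fin width and expressed against the arithmetic
mean of the control group (so the control group averages 100%);
mitochondria volumes bin into <0.1 / [0.1, 1) / [1, 10) / ≥10 µm³ with
lower-inclusive edges; metabolite peak areas are divided by the AABA
internal-standard area of the same run before group means, folds and CV%
(sample, n−1 standard deviation) are taken. Bin edges and the 100-µm²
reference constant are configuration, surfaced in outputs.

## I/O conventions

Multi-page TIFF with two pages per frame in declared channel order
(brightfield then GFP by default; a `channel_order` flag covers the swapped
dialect); an odd page count is a `channel-mismatch` error. Tabular outputs
are UTF-8 CSV with floats at six significant digits; every pipeline run
writes a provenance JSON carrying the tool version and the complete
parameter set, which replays to a byte-identical results CSV. Ground truth
accompanies synthetic TIFFs as a JSON sidecar. A plain-text GEO
series-matrix reader is provided as a convenience for public expression
deposits.

## Problem sizes in the test and acceptance runs

The bundled benchmarks use 50 images (boundary localization), 100 images
(displacement recovery), 3-frame timelapses, 1000 random Welch instances,
200 random p-value sets, 5000-gene null matrices and 2000-gene planted
matrices — sizes at which every Monte-Carlo margin in the suite is stable
across seeds while the whole suite stays fast on a single CPU.

## Known limitations

- One ray per cropped frame; no multi-ray segmentation or curvature
  correction.
- The detector assumes joints are darker, roughly vertical, and ≥ 40 px
  apart at the default settings; heavily tilted rays need rotation
  upstream.
- Quantile normalization assumes mostly-unchanged distributions between
  groups; globally shifted or tail-heavy designs violate it (see above).
- Welch at n = 3 is conservative (see above); the package reports what the
  stated method computes rather than recalibrating it.
- The two-stage FDR variant is one of several in circulation; exact
  reproduction of counts from vendor pipelines with unpublished settings
  is not expected.
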