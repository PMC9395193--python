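# raydisp

Quantification toolkit for osteoblast behaviour in regenerating zebrafish
caudal fins. After fin amputation, mature osteoblasts dedifferentiate and
migrate distally toward the amputation plane along the bony rays. This
package implements the image-quantification machinery behind that readout —
detecting intersegment joints in brightfield, tracking the GFP population
center of mass within ray segments — together with the study-style
counting, expression and metabolite statistics, and a synthetic-data module
that generates every input with known ground truth so the whole pipeline is
testable without microscope data.

It is aimed at researchers quantifying fluorescence time-lapses of
segmented structures (bony rays, but nothing is fish-specific in the code)
and at anyone who wants a reproducible, scriptable version of this class of
analysis.

## The measurements

**Relative displacement ratio.** For a registered two-channel image
(brightfield *B*, reporter *G*), intersegment boundaries are detected on
*B* by: Gaussian filter (σ = 2 px) → vertical-edge Sobel magnitude →
quantile binarization → vertical dilation → removal of connected components
smaller than 200 px → column-mean profile → peak finding. Consecutive
boundaries proximal to the amputation plane define segment 0 (most distal
complete segment), segment −1, … Within a segment [x₀, x₁) the reporter
channel is summed over rows into a line profile *g(c)* and the intensity
center of mass is

&nbsp;&nbsp;&nbsp;&nbsp;x̄ = Σ c·g(c) / Σ g(c),&nbsp;&nbsp;&nbsp;
r = (x̄ − x₀) / (x₁ − x₀) ∈ [0, 1],

with r = 0 meaning anterior (proximal) bias and r = 1 posterior (distal)
bias toward the amputation plane.

**Expression statistics.** Microarray-style two-group comparison: rank-mean
quantile normalization, log2 transform, per-gene Welch unequal-variance
t-tests, two-stage adaptive Benjamini–Hochberg FDR adjustment (plain BH
selectable), and up/down/ns calls requiring adjusted p < α and
|log2FC| > 1. qPCR fold changes use the 2^−ΔΔCt method against an *ef1α*
housekeeping reference.

**Scalar metrics.** Cell densities per 100 µm², marker-subtype percentages,
regenerated area normalized to fin width with percent-of-control,
mitochondria volume binning into <0.1 / 0.1–1 / 1–10 / ≥10 µm³ classes, and
internal-standard (AABA) calibrated metabolite levels with CV%.

## Worked example

```python
from raydisp import generate_timelapse, quantify_timelapse
from raydisp.synthetic import SyntheticRaySpec

# a ray with joints at columns 100/300/500, amputation at 550, and one
# osteoblast blob starting at column 350 that moves +20 px per frame
spec = SyntheticRaySpec(blob_list=((350.0, 60.0, 150.0, 8.0),))
frames, truths = generate_timelapse(spec, [0, 20, 40], seed=1)
table = quantify_timelapse(frames)
print(table[table.segment_label == 0][["frame", "com_column", "ratio", "total_gfp"]]
      .round(3).to_string(index=False))
```

prints

```
 frame  com_column  ratio  total_gfp
     0     349.772  0.249  59464.995
     1     370.566  0.353  60437.840
     2     389.095  0.445  59743.043
```

Segment 0 spans columns [300, 500), so the blob at column 350 reads a
displacement ratio of 0.25 (slightly anterior of the segment midpoint), and
each 20-px distal step raises the ratio by 0.1 — the generator's ground
truth for these frames is (0.25, 0.35, 0.45), recovered here within ~0.005
despite the noise.

The same analyses are available from the shell:

```sh
raydisp simulate timelapse --seed 1 --out sim
raydisp displacement --tiff sim/timelapse.tif --amputation-col 550 --out run
raydisp de --matrix matrix.tsv --groups groups.csv --alpha 0.05 --lfc 1
raydisp qpcr --ct ct.csv --baseline control
```

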