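# Methods

## The agreement model

Two raters' ROI sets for one scan are compared slice by slice (the
analysis is deliberately 2D, matching how an operator views and marks
images; regions are never merged across slices). The union of the two
binary masks is partitioned into connected components; each component is
one *connected region* labeled CR1, CR2 or CR12 by which rater(s)
contributed pixels. Every region is routed to exactly one error sum:
single-rater regions contribute their whole area to the detection error
DE, dual-rater regions contribute their union-minus-intersection area to
the outline error OE. With MTA = (|R1|+|R2|)/2, the similarity index
obeys the exact identity SI = 1 − OE/(2 MTA) − DE/(2 MTA), which the
implementation verifies on every scan (the two forms must agree to 1e-12;
a disagreement indicates a corrupted region table and raises).

The burden model treats per-scan DE and OER = OE/MTA as draws around
rater-specific constants; the study means then predict SI at any burden:
SI_est(MTA) = 1 − meanOER/2 − meanDE/(2 MTA). SI_est can be negative for
MTA < meanDE/(2 − meanOER); the numeric API returns the negative value
(the model is honest about its domain) and only plotting clamps.

Related indices: JI = SI/(2−SI) and Cohen's kappa over a pixel frame that
contains the union plus a stated number of background pixels. Kappa
increases with the frame and converges to SI; the 2×2 table is counted at
the analysis resolution.

## Pixel geometry and rasterization

All areas are physical (mm²). Contour inputs are rasterized at a
configurable upsampling factor (default 5 in x and y): a fine pixel is set
iff its center lies inside or on the boundary of a polygon under the
even-odd rule. The pixel-center, boundary-inclusive, even-odd convention
is deterministic, handles self-intersecting outlines (with a logged
warning), and makes rasterization exactly equivariant to integer vertex
shifts. Upsampling exists to keep a single closed path with a sub-pixel
neck from fragmenting into several regions, so labeling always runs at
the fine resolution; a fine pixel has area (dx·dy)/factor², so physical
area is preserved up to discretization. Degenerate alignments (edges
passing exactly through pixel centers, e.g. an integer right triangle)
put the boundary row inside and can reach the worst-case discretization
error (~2% for a 50 mm² triangle at factor 5).

Connectivity is 8-connected within a slice by default (a thin diagonal
outline should not split one lesion); 4-connectivity is available. A
union component touched by both raters with empty pixel overlap is CR12
by the literal definition, and its whole area is outline error.

## Model comparison

Four models of SI against MTA are scored on a common scan set by residual
sum of squares and AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1): mean (k=1),
linear (k=2, OLS), quadratic (k=3, OLS), and the burden law (k=2). The
burden law is *not* least-squares fitted — its parameters are the
arithmetic means of per-scan DE and OER, so its RSS is conservative
relative to an optimized two-parameter curve; this mirrors how the
estimates would be produced in practice. k counts the free quantities per
model; a shared error-variance parameter would add one to every k and
cancel in comparisons. RSS = 0 yields a −inf AICc sentinel with a
warning. Relative likelihoods are exp((AICc_min − AICc_i)/2).

Spearman correlations (MTA against DE, OE, OER, SI) use the
t-approximation for n ≥ 10 and an exact two-sided permutation test over
all n! rank orders below that; ties get average ranks. Constant columns
are reported as NaN with a warning rather than an error.

## Synthetic studies

The generator produces paired mask studies with known error structure so
every metric, fit and graph is testable without patient data. Design,
reflecting the statistical shape of a real multi-scan inter-rater study:

- **Burden**: each scan draws a target MTA log-uniformly from
  `mta_range` (default 850–18000 mm²); default 17 scans of 8 slices at
  192×192, pixels 0.94×0.94 mm.
- **Two lesion populations.** A Poisson pool (mean 60) of small
  "ambiguous" lesions (lognormal areas, median 18 mm²) whose expected
  count does not depend on burden, plus "burden" lesions (lognormal,
  median 150 mm², resampled above a 60 mm² floor) added until the target
  area is reached. Lesions are ellipses (aspect 1–2, random orientation)
  placed without overlap by rejection sampling (60 tries, then a named
  error).
- **Detection disagreement.** Each rater independently omits each lesion
  with probability expit(a − b ln area), steep in log-area (defaults
  a = 17.3, b = 6: 50% at 18 mm², <0.1% at 60 mm²). Detection error
  therefore comes almost entirely from the ambiguous pool, making DE
  roughly constant (~260 mm²) across the burden range while OE grows with
  burden — a lesion missed by both raters never enters the union and
  contributes nothing.
- **Outline disagreement.** Each rater's outline of a kept lesion is the
  lesion offset by a signed normal distance δ, realized by thresholding
  the signed Euclidean distance transform with a half-pixel shift (raw
  pixel-center distances have a dead zone below 1 px that would bias the
  realized jitter low). Offsets of the same shape are nested, so the
  per-lesion outline error is |A1 − A2|. The δ scale is set per lesion
  from its area and Ramanujan perimeter so that E|A1 − A2| ≈
  jitter_strength · area, making the realized mean OER track
  `jitter_strength` (default 0.4); `calibrate_jitter` (two probe studies
  of 60 scans) absorbs the residual few-percent discretization bias.

What the generator does *not* emulate: image intensities or scanner
noise, irregular (non-elliptical) lesion morphology, spatially correlated
rater behaviour, and the overlap of lesions in crowded anatomy. Passing
tests therefore demonstrate the correctness and calibration of the
metrics and models, not performance on any particular clinical dataset.
One consequence of the mask-level noise being heteroscedastic (low-burden
scans have few lesions and noisy OER) is that on mask-level studies the
AICc choice between the burden law and the quadratic varies run to run;
on tables forward-simulated from the burden law with homoscedastic
Gaussian SI noise (sd 0.05, n = 17), the burden law is selected in >90%
of replicates.

The forward table generator (`generate_si_vs_mta_table`) emits per-scan
(MTA, SI) with consistent DE/OER records: DE is held at its mean and OER
absorbs the noise, so the identity SI = 1 − OER/2 − DE/(2 MTA) holds row
by row and a zero-noise refit recovers the generator parameters exactly.

## Numerical and interface choices

- Rounding on export only: areas 1 decimal, indices 3 decimals; full
  precision internally.
- Outline-distribution binning is symmetric about 0 (a positive statistic
  on a bin edge joins the bin to its left, a negative one the bin to its
  right), so swapping raters reflects the histogram exactly; statistics
  of exactly 0 go to the bin immediately right of 0. Default bin width
  0.1; the width must divide [−1, 1] evenly.
- The cumulative detection curve uses strict "greater than", is
  right-continuous, and uses the region's union area (the only area a
  single-rater region has); per-scan normalization divides by the scan
  count.
- Both raters empty on a scan is a named degenerate error (MTA = 0); an
  empty rater on one slice is ordinary background.
- NIfTI headers carry float32 pixel sizes; an explicit geometry argument
  wins over the header with a logged warning.
- Problem sizes in the test suite (mask fixtures ≤ 32², replicate counts
  40–200, 17-scan studies) are chosen so the full suite characterizes
  the statistical claims in well under a minute per test.

## Known limitations

- Per-slice 2D analysis by design; no volumetric connectivity.
- The burden-law RSS uses unweighted residuals; with strongly
  heteroscedastic SI noise a weighted comparison would be fairer to it.
- The proprietary JIM ROI format is not parsed; the contour JSON dialect
  is the format-neutral equivalent (pixel-center vertex convention,
  documented in `masks_io`).
- Exact permutation p-values are only used below n = 10 (n! growth).
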