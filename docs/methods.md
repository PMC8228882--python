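# Methods

## Problem

Mammographic breast density (MBD) — the share of radiodense fibroglandular
tissue in the breast — is a strong breast-cancer risk factor, and its
*spatial arrangement* (clustered vs scattered) carries information beyond the
overall amount. This package quantifies percent density (PD) of a masked
mammogram at three scales (whole breast, 48 grid sub-regions, three
chest-wall-to-nipple zones), classifies each breast's spatial pattern from
Moran's I over the regional PDs, and runs the cohort-level comparisons that a
screening-population study of these quantities needs. Because real screening
archives cannot ship with the package, a synthetic-phantom module provides
images with exact ground truth, and every pipeline stage is validated against
that ground truth or an independent brute-force oracle.

## Segmentation: maximum-entropy (Kapur) thresholding

The in-breast grey-level histogram (256 bins) is split at the level `t` that
maximizes the summed Shannon entropies of the two classes,

```
psi(t) = H_low(t) + H_high(t)
H_low  = - sum_{i<=t} (p_i/P_t)     ln(p_i/P_t)
H_high = - sum_{i> t} (p_i/(1-P_t)) ln(p_i/(1-P_t))
```

with `p_i` the bin probabilities and `P_t` the cumulative mass at `t`.
Numerical choices: natural log (the base rescales `psi` without moving the
argmax); empty bins skipped (`0 ln 0 := 0`); candidates restricted to
`0 < P_t < 1`; ties broken toward the smallest level, so the degenerate
two-level histogram thresholds at the lower level. Pixels **strictly above**
`t` are radiodense; the returned level belongs to the lower class. The
implementation is a cumulative-sum evaluation of `psi` and is tested for
exact agreement with an exhaustive per-level recomputation on random
histograms.

By default the histogram is built from in-mask pixels only. Thresholding the
whole cropped frame would let the black background dominate the low class;
because an interactive thresholding tool applied to a cropped image would see
that background, the frame-scope mode is kept available (`hist_scope=
"frame"`, CLI `--hist-scope`), and results record which was used.

Overall PD = 100 × (dense pixels) / (breast-mask pixels).

## Regional and zonal density

The breast bounding box is divided into an 8-row × 6-column grid of
near-equal rectangular tiles (remainder pixels widen the last tiles; tile
sizes differ by at most one pixel). Regional PD of a tile is 100 × dense
pixels / denominator, where the default denominator is the whole tile area
(a tile splitter applied to the segmented binary image has no notion of a
breast mask; off-breast pixels count as non-dense). A mask-aware mode
divides by in-breast pixels per tile instead and records zero denominators.
With the default mode and equal tiles, the mean of the 48 regional PDs
equals the frame-level dense share exactly — a conservation property the
tests assert.

Zones are contiguous 2-column bands along the chest-wall→nipple axis:
posterior (columns nearest the chest wall), middle, anterior. The 2/2/2
split is a configuration default (`ZoneDefinition`), not an anatomical
claim; the chest-wall side is an explicit parameter (left for an LMLO-like
frame). Zonal PD is the unweighted mean of the 16 regional PDs in the band.

## Spatial autocorrelation

For tile values `x_1..x_N` (N = 48) and weights `w_ij`,

```
I = N / (sum_ij w_ij) * sum_ij w_ij (x_i - x_bar)(x_j - x_bar)
                       / sum_i (x_i - x_bar)^2
```

over ordered pairs i ≠ j. Default weights are inverse squared distance,
`w_ij = 1/d_ij²`, between tile midpoints measured in tile units (adjacent
orthogonal midpoints at distance 1), filled for **all** tile pairs — the
literal reading of the weighting rule. Because "distance between midpoints
of adjacent sub-regions" can also be read as contiguity-only weighting,
rook (orthogonal neighbors, w = 1) and queen (plus diagonals, w = 1/2)
schemes are provided and every result records its scheme; any uniform
rescaling of distances cancels between numerator and normalizer. All 48
tiles enter the statistic, including breast-exterior tiles with PD 0, so the
fixed 48-region design is comparable across breasts.

Pattern label: I > ε clustered, |I| ≤ ε random, I < −ε scattered, with
ε = 0 by default (strict sign rule; ε is configurable for floating-point
robustness). A constant PD field has undefined I; `morans_i` raises, and the
image pipeline reports such fields as `random` with I = 0, since a
featureless field has no spatial structure either way.

## Synthetic phantoms

A phantom emulates what the pipeline consumes from an MLO view, not X-ray
physics: a half-ellipse breast (vertical semi-axis 0.48 × height, horizontal
0.92 × width) attached to the left image edge, minus a corner triangle for
the pectoral muscle (well under 15% of the breast area); adipose background
at intensity 80, dense blobs at 200 (defaults; 120 levels of separation),
Gaussian noise of sd 10 added inside the breast only, rounded and clipped to
8-bit; off-breast pixels are exactly 0. Ground-truth breast and dense masks
are exported, so planted PD is recoverable by pixel counting.

Dense tissue placement plants the spatial patterns on the same grid the
pipeline measures on: zone placements (`posterior`/`middle`/`anterior`) put
disc-blob centers in that zone's column band of the breast-bounding-box grid
(clustered, I > 0); `checkerboard` fills alternating tiles from their
centers outward (scattered, I < 0); `uniform` scatters blobs anywhere. The
target dense fraction is hit by bisection on a global radius scale (achieved
pixel fraction is monotone in the scale); generation stops within 0.004 of
the target and the contract guarantees 0.02, with an explicit shortfall
error when a fraction is unreachable (a checkerboard cannot exceed the
alternating tiles' share of the breast, ≈ 0.5, capped at 0.42 in cohorts).

Cohorts plant the study's qualitative effects as generator defaults: ages
uniform on 35–90; per-subject dense fraction `0.25 − 0.004·(age − 62.5) +
N(0, 0.08)` clipped to [0.02, 0.90] (a negative age–density slope); BI-RADS
label assigned from the planted fraction (cutoffs 0.12/0.25/0.40); subjects
are blob-clustered with probability 0.75 in groups A/B vs 0.45 in C/D and
checkerboard otherwise; clustered mature (<65) subjects favor the middle
zone (0.70/0.25/0.05 middle/posterior/anterior) while older subjects split
posterior-and-middle (0.50/0.40/0.10), planting the mature middle-zone
excess. Everything is reproducible bit-for-bit from the cohort seed.

What phantoms do **not** emulate: X-ray physics, breast thickness and
compression, digitization artifacts, skin-line gradients, texture within
tissue classes, or radiologist BI-RADS judgment (labels derive from the
planted fraction). Passing tests therefore demonstrate that the pipeline's
measurements recover known truth under controlled conditions — not that the
segmentation is accurate on clinical film-screen images.

## Cohort statistics

All tests are two-sided at α = 0.05. Pearson correlation for overall PD vs
age; chi-square independence test for pattern-by-group tables (warning, not
failure, when an expected count is below 5); Kruskal–Wallis for a zone's PD
across BI-RADS groups (all-identical data short-circuits to H = 0, p = 1,
where the rank-tie correction otherwise divides 0/0); Friedman across the
three within-subject zones with Wilcoxon signed-rank pairwise follow-ups
reported both raw and Bonferroni-adjusted (×3), since no single adjustment
convention is canonical; Mann–Whitney U between mature (<65) and older
(≥65) groups, exact for small samples and tie-corrected normal otherwise
(scipy's automatic selection). Heatmaps of per-group mean regional PD use a
yellow (≈0%) → orange (≈25%) → red (≥50%) scale.

## Problem sizes and validation design

Simulation-based checks run at desk scale, chosen once: phantoms 96×72
pixels (12×12-pixel tiles) for simulations, 192×144 for single-image
defaults; cohorts of 200 subjects; 100 seeds for pattern-recovery and
planted-effect power checks; 1000 seeds for type-I calibration, run on
record-level null cohorts (all variables independent) because calibration
exercises the statistics, not the imaging. Oracle checks (threshold and
Moran's I) compare the implementations with deliberately naive exhaustive
re-computations — exact equality for the threshold argmax, ≤1e-10 relative
error for Moran's I.

## Known limitations

- The ROI is an input (polygon or mask); there is no automatic skin-line or
  pectoral-muscle detection, so real mammograms need external delineation.
- The 2/2/2 zone split and the tile-area denominator are conventions;
  alternatives are configurable but results depend on the choice.
- Moran's I significance is not tested (no permutation test); the pattern
  label is a sign classification, and values very near 0 are fragile to
  noise unless ε is widened.
- BI-RADS labels in synthetic cohorts are fraction-derived, so planted
  group contrasts are cleaner than radiologist-assigned categories would be.
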