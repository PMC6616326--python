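# Methods

## Pipeline model and assumptions

The package assumes erect, green-to-yellow seedlings photographed against a
non-green background with the camera upright (row 0 at the image top), one
plant per analyzed frame. Tray images with many plants are expected to be
pre-cropped to per-plant sub-images before segmentation. Traits are defined
on the 2-D silhouette: *projected plant height* is the inclusive row extent
of the final mask — a proxy for shoot length that is exact for erect
seedlings and degrades for leaves bending out of the image plane — and
*pixel area* is the silhouette's foreground count. Pixel units are primary;
millimetre conversion is a separate, explicitly labelled linear calibration
(`mm_per_px`), since no calibration target is assumed to be present.

## Color transformation

HSI follows the geometric definition: intensity is the channel mean,
saturation 1 − min/mean, hue the arccos angle of the RGB vector around the
gray diagonal, reflected to (180°, 360°) when B > G. Hue is undefined at
achromatic pixels (saturation < 1e-6); these are stored as hue 0 with a
separate boolean flag so arrays stay dense and thresholding stays total.

CIELAB uses the standard sRGB chain (gamma expansion, the tabulated
linear-RGB→XYZ matrix, cube-root compression) under D65 / 2° observer, with
the white point implied by the matrix row sums so reference white maps
exactly to (100, 0, 0). The three threshold planes are rescaled to a common
0–255 axis: Y = ((a\*+100)/200)·255 and likewise for b\*, and Y = (H/360)·255
for hue. a\*/b\* values outside [−100, 100] are clipped first so the output
contract [0, 255] holds for extreme colors; within that interval the maps
are strictly increasing affine bijections onto [0, 255].

## Segmentation

The threshold rule is **hue-window ∧ (green-a\* ∨ yellow-b\*)**: the hue
window confines pixels to the plant color family, while the opponent
channels recover strongly green or senescent-yellow tissue inside it. The
boolean combination and all thresholds are calibration knobs, not measured
constants. Defaults: hue window (35, 120) on the rescaled axis (≈ 50°–170°),
`a_green_max` 120, `b_yellow_min` 135 — chosen to bracket green–yellow
vegetation and verified on the synthetic scenes.

Cleanup order: binary median (majority) filter (radius 1, replicate
padding — avoids spurious foreground loss at frame edges), morphological
opening with a 3×3 square element (1 iteration; the smallest element that
removes 1-px noise without erasing ~3-px leaf tips), hole filling (4-connected
background not reaching the border becomes foreground), and removal of
8-connected components below 25 px. Foreground uses 8-connectivity and
holes 4-connectivity — the standard complementary pairing. The chain is
deterministic; enlarging the hue window can only grow the thresholded mask.

Features narrower than the structuring element cannot survive opening; the
synthetic renderer therefore tapers blade tips to 3 px, and at other image
scales the element size should be kept below the expected blade width.

## Trait statistics

The phenotype model is one-way fixed effects (line), so least-square means
equal per-line arithmetic means for any replication pattern. Pearson
correlations between trait means use complete-case lines per pair, with a
two-sided p from the t transform on n−2 df. The residual-variance F test
compares two traits' deviations from their line means, F = s²ₓ/s²ᵧ on
(n_obs − n_lines) df each, with two-sided p = 2·min(P(F≤f), P(F≥f)) since
the null is equality with no direction. Because traits live in different
units, each trait is z-scaled by its grand SD before residuals are taken
(a raw-scale option exists); the standardized test asks whether the two
measurements are equally precise relative to their scales.

## QTL mapping

Haley–Knott regression interval mapping, deliberately without composite-
interval cofactors: at each pseudo-position (1 cM default grid plus all
marker positions) the line mean is regressed on E[genotype | flanking
markers], and LOD = (n/2)·log₁₀(RSS₀/RSS₁). Conditional probabilities use
the RIL Markov chain: Haldane r = (1 − e^(−2d/100))/2 (no interference) and
the selfed-RIL expansion R = 2r/(1+2r); lines are treated as fully inbred
(F∞), heterozygote input calls are recoded missing with a counted warning.
Conditioning uses the nearest informative flanking marker on each side, so
missing calls fall back to more distant markers, and lines with no
informative marker on a chromosome get P(AA) = 0.5.

Numerical choices: RSS₁ is floored at 1e-12·RSS₀ so a perfect fit yields a
large finite LOD that still dominates any threshold; monomorphic positions
(zero regressor variance) score LOD 0 with a warning; the scan is fully
vectorized (two matrix products per permutation stack), which is what makes
the 200-replicate calibration study tractable on one CPU.

Permutation thresholds shuffle line means across lines, rescan, and take the
empirical (1−α) quantile of the genome-wide maximum LOD with type-7 linear
interpolation; the RNG seed is a required input and recorded in the result,
so thresholds are bit-reproducible. The default 1000 permutations at
α = 0.05 match conventional genome-wide practice; the calibration study in
the acceptance suite uses 300 permutations per replicate to fit its budget,
which only adds quantile-estimation noise, not bias.

Peak calling (a reporting convention, not part of the model): per
chromosome, local maxima above the threshold are claimed in LOD order; each
claims a support interval — the contiguous run within `drop_lod` (default
1.5) of the peak. A candidate whose interval overlaps a claimed one, or that
lies within 30 cM of a claimed peak, is merged into it: a strong QTL's
linkage shadow (RIL genotype correlation 1−2R ≈ 0.25 at 30 cM) routinely
lifts shoulder maxima above genome-wide thresholds, and calling those as
separate loci would be double counting. Two genuine QTL closer than 30 cM
on one chromosome are therefore reported as one peak — a known limitation
shared with any single-QTL scan. The additive effect reported at a peak is
the regression slope on the −1/+1 genotype axis.

## Synthetic data

`generate_seedling_image` renders 1–5 quasi-vertical blades (hard color
boundaries, no anti-aliasing) rising from a base row, with per-blade length,
width, slant and jittered green shade, on a flat soil-brown background,
optionally salted with single-pixel green noise; it records the exact mask,
tip/base rows and area. Scenes default to 512×512 (blades 150–300 px long,
4–8 px wide) so the full 50-scene benchmark runs in seconds; this emulates
the geometry of erect 2-week seedlings, not the photometric complexity of
real trays — no shadows, specular highlights, soft edges, overlapping
plants or illumination gradients. Passing the imaging benchmark therefore
demonstrates correctness of the segmentation/measurement chain, not
field-readiness of the default thresholds, which real deployments must
recalibrate.

`simulate_ril_population` draws genotypes chromosome-wise as a Markov walk
with RIL-expanded Haldane transitions between adjacent markers (the fixture
map: 12 chromosomes × 19 markers at 6 cM ≈ 228 markers, echoing a ~224-marker
RIL map), plants additive QTL effects on the ±1 genotype axis, and scales
Gaussian replicate noise so the stated line-mean heritability holds against
the empirical genetic variance (a zero-effect architecture falls back to
unit noise, giving a pure-null phenotype). Trait values sit on a positive
scale (mean 200) so the non-negativity of trait records is never active.
There are no tray/spatial effects — edge plants are assumed removed.

`generate_study_fixture` pairs 12 rendered scenes (256×256) with a
162-line × 8-replicate population at h² = 0.5: a height-like trait with QTL
on chromosomes 1, 4 and 12 (effects 6.0, 3.5, 3.5) and a biomass-like trait
acting through the chromosome-1 locus plus a polygenic background sized so
the planted genetic-value correlation is 0.66. Observable consequences: the
line-mean correlation is attenuated to ≈ 0.66·h² ≈ 0.33, and the weaker
chromosome-4/12 loci (≈ 10% of line-mean variance each) sit near the
detection boundary at this population size — deliberately so, as a desk-
scale reflection of real marginal QTL. The acceptance studies that require
reliable three-locus recovery use an equal-effects architecture (4, 4, 4)
where each locus carries h²/3 ≈ 17% of line-mean variance.

## Problem sizes and benchmark design

The benchmark sizes are the package's own study conditions: 50 scenes for
imaging recovery; 200 null replicate datasets × 300 permutations for
threshold calibration (binomial 95% band around 5%: [2.0%, 8.0%]); 50 seeds
for localization (±5 cM) and for three-locus recovery (200 permutations per
seed). All generators are pure functions of (seed, params); every stochastic
step takes an explicit seed, and the CLI writes the seed and a config digest
into every artifact header so runs are replayable byte for byte.

## Known limitations

- Single-QTL scan: linked QTL within ~30 cM merge; no cofactor adjustment.
- Height is a silhouette extent: leaves bending out of plane shorten it.
- Default segmentation thresholds are tuned to the synthetic palette;
  real imagery requires recalibration of the hue window and opponent cuts.
- The F∞ RIL assumption discards residual heterozygosity rather than
  modelling it.
- The renderer's hard color boundaries make segmentation easier than
  anti-aliased real images; F1 bounds reported here are upper bounds on
  what identical settings would achieve on photographs.
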