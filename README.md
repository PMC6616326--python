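# vigorscan

Image-based seedling vigor phenotyping and QTL interval mapping for rice
recombinant inbred line (RIL) populations.

Seedling vigor — early height, biomass and uniformity — predicts tillering
and yield, but manual scoring cannot keep up with the population sizes a
breeding program needs. `vigorscan` implements a camera-to-QTL pipeline for
this problem: it turns top/side-view RGB images of tray-grown seedlings into
projected plant height and pixel-area traits, summarizes them per line, and
scans a genetic map for quantitative trait loci (QTL) with genome-wide
permutation thresholds. Everything is exercisable end to end on synthetic
seedling scenes and simulated RIL populations with known ground truth, so
the whole pipeline is testable without any external data.

## The method

**Imaging.** Each RGB image is transformed into HSI (hue, saturation,
intensity; geometric definition) and CIELAB (sRGB input, D65 white). The
hue, a\* and b\* planes are rescaled onto a common 0–255 axis:

```
Y_a*  = ((a*_LAB + 100) / 200) × 255
Y_b*  = ((b*_LAB + 100) / 200) × 255
Y_H   = (H_HSI / 360) × 255
```

A plant mask is thresholded as *hue window* ∧ (*green a\** ∨ *yellow b\**),
then cleaned by a binary median (majority) filter, morphological opening,
hole filling, and small-component removal. Projected plant height is the
inclusive vertical extent of the mask (top-most to bottom-most foreground
row); pixel area is the foreground count.

**Statistics.** Per-line least-square means under the one-way line model
(equal to arithmetic line means in any replication pattern), pairwise
Pearson correlations among trait means (two-sided p from the t transform on
n−2 df), and a two-sided F test comparing the one-way residual variances of
two traits.

**QTL mapping.** Haley–Knott regression interval mapping on line means: at
each cM of the map, the expected genotype given the nearest informative
flanking markers is computed through the RIL Markov chain with Haldane
recombination fractions r = (1 − e^(−2d/100))/2 and the selfed-RIL expansion
R = 2r/(1+2r), and evidence is LOD = (n/2)·log₁₀(RSS₀/RSS₁). Genome-wide
significance comes from permuting line means (default 1000 permutations,
α = 0.05); peaks are local maxima above the threshold with 1.5-LOD support
intervals.

## Worked example

```
$ vigorscan run-all --seed 1 --out-dir demo
fixture written to demo (12 scenes, 162 lines)
24 trait records from 12 image(s); 0 failure(s)
r(FW_g, PH_mm) = 0.327  (p = 2.20e-05, n = 162)
residual variance F test: PH_mm vs FW_g
df1 = 1134, df2 = 1134, F = 0.975625, two-sided p = 0.677853
324 line means written to demo/stats
PH_mm: threshold LOD = 3.041 (1000 permutations, alpha 0.05); 1 peak(s)
  chr 1 @ 47.0 cM  LOD 14.28  support [45.0, 51.0] cM  effect +5.759
FW_g: threshold LOD = 2.946 (1000 permutations, alpha 0.05); 1 peak(s)
  chr 1 @ 48.0 cM  LOD 14.52  support [47.0, 49.0] cM  effect +2.032
run-all complete
```

What the numbers mean: the simulated fixture (162 lines × 8 replicates on a
12-chromosome map) plants a strong height QTL at 48 cM on chromosome 1 that
is shared with the biomass-like trait. Both scans recover it within 1 cM,
with LOD ≈ 14 against permutation thresholds near 3. The line-mean
correlation 0.327 is the planted genetic correlation 0.66 attenuated by the
h² = 0.5 heritability of both traits (0.66 × 0.5 ≈ 0.33). The F statistic
near 1 (p = 0.68) says the two traits' standardized residual variances are
indistinguishable — the two measurements are equally precise. The estimated
additive effects (+5.76 height units, +2.03 biomass units) sit close to the
planted values 6.0 and 2.4.

Individual stages are available as `vigorscan simulate / segment / stats /
scan`; see `vigorscan COMMAND --help`.

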