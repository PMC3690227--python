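# Methods

## Color normalization

Reinhard statistics transfer operates in the decorrelated logarithmic lαβ
space. Pixels are mapped RGB → LMS with the fixed 3×3 matrix
(0.3811, 0.5783, 0.0402; …), clamped to ε = 1/255 and logged, then rotated to
lαβ by diag(1/√3, 1/√6, 1/√2) · [[1,1,1],[1,1,−2],[1,−1,0]]. Each channel of
the source image is recentered to zero mean, scaled by σ_target/σ_source, and
shifted to the target mean; the inverse path (exact inverse of the lαβ
rotation, exponentiation, the printed LMS → RGB matrix) returns 8-bit RGB.

Numerical conventions:

* **Log base** — natural log, with the inverse exponentiated consistently.
  Only self-consistency matters: the forward/backward pair cancels whatever
  base is chosen.
* **Clamp** — LMS values are floored at 1/255 before the log so black pixels
  stay finite; this preserves ordering and bounds the dynamic range.
* **Quantization** — after inversion, values are clipped to [0, 255] and
  rounded half-up. The published RGB↔LMS matrices are a rounded inverse pair
  (their product deviates from identity by up to ≈1.4e-2 in the S row), so a
  round trip reproduces pixels only to within ±3 gray levels; statistics
  matching happens before inversion and is exact to float precision.
* **Degenerate sources** — an image with zero spread on an lαβ channel has
  no defined scale factor; the default is an error, and an explicit
  `on_zero_sd="identity"` flag skips scaling on the flat channel instead.
* **Target choice** — target images are operator-supplied (high contrast,
  dark blue nuclei is the usual criterion); the profile (six statistics plus
  the target count) serializes to YAML/JSON for reuse across runs.

## Tissue segmentation

Hue is computed with the HSI arccos formula; gray pixels (R=G=B) have no
defined hue, are flagged, and are forced into the background population.
Hue in [0, 360) is scaled linearly to integer bytes [0, 255] for
thresholding. The Otsu threshold is an exhaustive scan of k = 0…255
maximizing ω₀ω₁(μ₀−μ₁)², ties broken toward the smallest k; the
implementation returns the full class decomposition at the optimum so runs
can be audited.

The three steps: (1) Otsu on the hue histogram; the low-hue class is the
rough foreground (pink plus most purple). (2) Otsu on the G channel of the
rough background; the dark class (residual purple) is merged into the
foreground. (3) Otsu on foreground hue; at or below the cut is NORMAL, above
is ABNORMAL. Each step carries two guards:

* **Orientation guard** — if the "low" class holds more than 95 % of its
  population the classes are assumed swapped and inverted (protects against
  inverted staining conventions).
* **Separation guard** — steps 2 and 3 fire only when the two class means
  are at least 30 levels apart. Otsu always returns *some* threshold, so on
  a unimodal histogram (a background with no residual purple; an all-normal
  specimen) it would split sensor noise in half. 30 levels is well below any
  genuine pink/purple or tissue/background separation and well above noise.

The label map is smoothed once with a 9×9 majority filter (windows cropped
at borders, no padding; ties broken by the fixed priority BACKGROUND >
NORMAL > ABNORMAL, so smoothing is deterministic). Abnormal-region
boundaries for overlays are ABNORMAL pixels with a non-ABNORMAL 4-neighbor,
with the image border counting as outside.

**Known limitation** — hue is an angle but Otsu runs on the linear [0, 360)
axis, so pinks that wrap past 360° split into two clusters. Color
normalization is what keeps hue ranges stable enough for a linear cut; see
the generator notes below for how close to the wrap boundary this becomes a
real failure.

## Nuclei analysis

The R channel of the normalized image carries the strongest nucleus
contrast. The double threshold is anchored adaptively: base = mean of the
ten lowest pixel intensities (ten pixels, i.e. the lowest order statistics);
seeds are pixels ≤ base + 30; region growing (8-connected) extends seeds
into pixels ≤ base + 45. The offsets are empirical constants expressed in
8-bit intensity levels; they transfer across images *because* normalization
fixes the intensity scale first. A constant image floods entirely — nucleus
analysis presumes nuclei are present, which is why empty tiles are excluded
upstream by the operator.

Components smaller than 5 px are discarded (shape features are meaningless
below that). Features per component: area (pixel count); perimeter as the
weighted outer-contour length with diagonal steps counted √2
(scikit-image's estimator); circularity 4πA/P²; d_max and d_min as the
extreme Euclidean distances from the centroid to boundary pixel centers,
with d_min floored at half a pixel so one-pixel-wide components stay finite.
A centroid falling outside its component (strongly concave region) is
flagged but measured as stated. On rasterized shapes the circularity of a
disc of radius 15 measures ≈0.96 rather than 1.0 (chain-code bias, tolerance
0.15 documented); the classification is insensitive to this because discs
already fail the elongation test.

Classification: NORMAL rod iff circularity < 0.95 ∧ d_max/d_min > 3 ∧
area < 2000 px; otherwise abnormal — a single round nucleus below
2000 px, else a multinucleus cluster. Cluster counts divide cluster area by
the image's own mean single-round-nucleus area (per-image workflow), rounded
half-up with a floor of one; with no single round nucleus in the image each
cluster counts once and a warning is logged.

## Quantification and statistics

Parameters 1 and 2 are ratios of sums: specimen measurements are summed over
its images first (sum-then-ratio, not mean-of-ratios). Group summaries use
the sample SD (n−1). Stage cuts are midpoints of the H/M/L stage means; N
specimens are excluded from fitting and reported descriptively. A ratio
exactly at a cut goes to the more severe stage, with a 1e-12 comparison
tolerance so the decision is not made by float representation error.

`StageClassifier` defaults to `decimals=3`: ratios and stage means are
rounded half-up to three decimals before the cuts are formed. This emulates
arithmetic on values reported at fixed precision — the regime in which a
specimen can sit *exactly* on a cut — and is how tabulated results are read
back; `decimals=None` gives full-precision discrimination. Display rounding
is half-up with a 1e-9 nudge because quantities that are exact decimal
halves (e.g. a mean of 0.1225) otherwise fall just below the .5 boundary in
binary floating point.

Group comparison uses Welch's unequal-variance t-test with Satterthwaite
degrees of freedom, two-tailed, as the default. The pooled-variance Student
test is available via `equal_var=True`, but with group sizes of 6–10 and
visibly unequal spreads (L-stage SDs run ~3× the M-stage SDs) the
equal-variance assumption is not defensible and Welch is the statistically
appropriate default; the two tests disagree by an order of magnitude in p on
these data. Degenerate input (two zero-variance groups with equal means)
returns t = 0, p = 1.

## Synthetic data generator

The generator renders what the method assumes about real slides: parallel
pink collagen bands (per-band color jitter), purple elliptical metaplastic
patches covering a requested fraction of the tissue (random ellipses are
added until the realized union is within 0.5 % of target), a tinted
near-white background margin, planted non-overlapping nuclei (rod = random
elongated ellipse with semi-axes 10–16 × 1.6–2.4 px in pink tissue; round =
disc of radius 5–8 px inside purple patches), then a multiplicative
illumination ramp (default amplitude 0.05), an additive color cast (default
zero) and Gaussian noise (default σ = 2). All randomness flows through one
seeded generator; identical seeds give bitwise-identical output. Default
field size is 512×512 (library tests use 256×256 fields to keep the suite
fast; the geometry scales linearly).

Color defaults were chosen so that hue separations straddle the Otsu cuts
the way well-stained slides do, and two of them encode genuine failure modes
of the method discovered while validating end to end:

* **Pink (235, 150, 125)** — a salmon eosin with G−B = 25. Pinks with B
  close to G sit near the B>G hue-wrap boundary; statistics transfer between
  images of different composition shifts the blue-yellow axis enough to flip
  part of the pink to hue ≈350°, which a linear-axis Otsu then mislabels.
  A pink with B > G (hue ≈344°) breaks the low-hue-normal assumption
  outright.
* **Background (240, 242, 253)** — a faint bluish tint, |G−B| = 11. The hue
  of a *neutral* bright background is dominated by noise (uniformly random),
  which no hue threshold can segment — and real microscope backgrounds are
  never perfectly neutral. A tint of only ~5 levels of chroma can have its
  hue sign flipped by cross-stage normalization.

Stage simulation draws each image's abnormal fraction from H [0.24, 0.28],
M [0.18, 0.22], L [0.06, 0.16] and its round-nucleus share from H
[0.66, 0.80], M [0.58, 0.66], L [0.42, 0.58], mirroring the spread of the
reference specimens.

What the generator does *not* emulate — and hence what passing tests do not
establish about real slides: stain intensity gradients within tissue,
out-of-focus blur, overlapping or touching nuclei, chromatin texture inside
nuclei, microvasculature and other irrelevant structures, and pinks/purples
drawn from the full continuum of staining chemistry. Ground-truth recovery
on clean renders validates the algorithmic contracts (thresholds, growing,
shape rules, aggregation), not clinical accuracy.

## Problem sizes used in the checks

The bundled 29-specimen reference table drives all downstream-statistics
checks (they are exact-arithmetic reproductions, independent of image
processing). Imaging-stage checks run on rendered fields of 192–320 px per
side with 12–60 planted nuclei, where recovery is exact for nucleus counts
and within 0.03 for the area ratio; these sizes exercise every code path at
a small fraction of the cost of full 2560×1920 fields.
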