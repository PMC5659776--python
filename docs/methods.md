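# Methods

This note records the modelling choices behind `atasm`: what each stage
assumes, which parameters matter and why their defaults were chosen, what
the synthetic phantoms do and do not emulate, and the numerical corner
cases. Empirical figures quoted here are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Contours and correspondence

All structures are closed 20-point contours in pixel coordinates (x =
column, y = row increasing downward, 0-based; pixel spacing 0.075 mm carried
as metadata). Correspondence across images uses a fixed geometric rule:
the four extremal vertices (topmost, rightmost, bottommost, leftmost) are
anchors, and four points are placed at equal arc-length fractions between
each adjacent anchor pair. Contours are stored counter-clockwise (positive
shoelace area) starting at the top anchor so that inside/outside and normal
directions are unambiguous everywhere downstream. Inputs that are
degenerate (under 8 points, zero area, duplicate anchors, self-intersecting)
are rejected at read time rather than propagated.

The anchor rule assumes roughly elliptical shapes. It breaks on axis-aligned
rectangles (two extremes coincide in one vertex) — acceptable here because
tendon and sheath cross-sections are elliptical.

## Point distribution model

Generalized Procrustes alignment uses the full similarity group
(translation, rotation, isotropic scale), a 10-iteration cap and a 1e-7 RMS
convergence tolerance; the mean is normalized to centroid 0 and unit RMS
point radius. Because the mean's orientation is otherwise a free gauge
(it would inherit the arbitrary pose of the first input), the mean is
rotated so its first landmark — the top anchor — sits straight above the
centroid. This makes alignment invariant to similarity pre-transforms of
the training set.

PCA modes are retained up to 98% of total variance, capped at
`n_training − 1`; identical training shapes yield zero modes (an absolute
variance floor prevents numerical noise being promoted to a mode). Mode
weights are clamped to ±3√λᵢ — three standard deviations, the standard
active-shape-model box; a strict mode clamping at ±3λᵢ is available as a
configuration flag for comparison. Zero-variance modes clamp to exactly 0.

## Texture features

Two texture images feed the energy: the imaginary part of a 0° Gabor filter
(σ = 4 px, carrier 0.1 cycles/px, 25×25 kernel — chosen so the half-period
of the carrier, 5 px, matches the synovial band scale; all three are
configurable) and the Laws E5L5 level-edge kernel (outer product of the
edge detector (−1,−2,0,2,1)ᵀ with the averaging mask (1,4,6,4,1)). Both are
applied by convolution with reflected borders. Filters at 30°/60°/90° and
other Laws kernels can be computed for inspection but do not enter the
energy.

Texture profiles take 5 samples per control point at −4,−2,0,+2,+4 px along
the outward normal (negative = inside). The normal at point *i* is the unit
perpendicular of `c(i+1) − c(i−1)`, signed to point away from the contour
centroid — a two-neighbour stencil that is stable under landmark noise,
with the centroid resolving the sign unambiguously for star-shaped
contours. Off-grid samples are bilinear; samples outside the image take the
nearest border value and are logged.

## Energy and adaptive weights

Five terms per control point: interior angle (radians, in [0, π], with the
arccos argument clipped and coincident neighbours treated as straight),
area gradient (3×3 window means centred ±2 px along the normal), line
gradient (5-sample 1-px-spaced masks at 1..5 px along the normal), and the
two texture terms as negative squared profile differences. The texture
energies are global sums, but each point's 5-sample partial sum is kept so
the per-point weighting applies; with all weights equal to 1 the weighted
total reduces exactly to the global sums. Gradient signs are
bright-inside/dark-outside for the tendon and reversed for the sheath. No
cross-term normalization is applied: the weight-training rule absorbs scale
differences, since each weight is built from the term's own line statistics.

Weight training slides each control point ±10 px (step 1, 21 samples) along
its normal while the rest of the contour stays at the ground truth; with
`F` the term value at the truth, `F̃` the line maximum and `σ` the line
standard deviation, the weight is the training-set mean of `σ·F/F̃`.
Negative or undefined ratios contribute 0, as do cells with `F̃ = 0`. Note
the resulting weights are on the terms' native scales, so texture weights
are numerically much larger than curvature weights; this is intentional —
the ratio `F/F̃` is scale-free and `σ` carries the term's discriminative
range.

## Localization

The intensity template is the per-pixel mean of training images warped
(similarity, estimated from the 20-point correspondence) onto a reference
tendon contour, cropped to the tendon bounding box plus a 40% margin per
side (margin configurable; it should include the hypoechoic band and part
of the volar plate, which is what makes the template discriminative).
Pixels not covered by every warp use a coverage-weighted mean.

Coarse search downsamples image and template by 2×2 averaging and scans
template-sized blocks by mean absolute difference (SAD). The block stride
is **1/8** of the block size, with edge-flush rows/columns appended so the
blocks tile the whole image; ties break toward the smallest (row, column).
A coarser 1/4 stride was tried first and measurably fails: its worst-case
misalignment (half a stride) raises the true block's SAD above that of
structureless background blocks, so the search locks onto the wrong block
in roughly a third of placements. At 1/8 stride the true block always won
in our placement experiments and the returned origin stays within the
stride-quantization bound. Fine matching then minimizes full-resolution SAD
over a 4-parameter similarity transform with Powell's method (ftol 1e-4,
100 iterations), started at the coarse origin with identity scale/rotation.
A manual ROI box (outlining the tendon block at the template's proportions)
bypasses matching for scans where template search is not applicable, such
as multi-tendon fields.

## Optimization schedule

Shape search is a real-coded genetic algorithm over the clamp box:
population 50, fitness-proportional (roulette) selection on min-shifted
fitness (uniform when all fitness values tie), single-point crossover with
probability 0.5, per-chromosome mutation with probability 0.01 replacing
one uniformly redrawn gene, elitism, and convergence when the elite is
unchanged (absolute tolerance 1e-9) for 10 generations, capped at 200.
Non-finite fitness values cause resampling of the chromosome. Fixed seeds
give bit-identical trajectories.

A structural property of this operator set is worth stating: crossover only
recombines existing gene values and mutation redraws uniformly over the
whole clamp range, so the search has no local-refinement operator. On a
3-mode quadratic benchmark the elite reliably enters the central ~10% of
the box but does not concentrate to the ~2% precision a 10⁶-point random
search attains; the corresponding acceptance test is left failing rather
than altering the stated operators, and the numbers are reported by the
acceptance script (`ga_elite_hit_rate_pct`, `ga_elite_max_scaled_distance`).
In the segmentation setting this resolution limit is immaterial because the
alternating Powell pose refinement supplies the fine adjustment: up to 5
rounds of (pose refinement, GA over b), stopping when the joint energy
changes by less than 1e-4 relative; pose refinement reverts if the scale
leaves [0.5, 2]× its initial value.

## Sheath post-processing

The fitted sheath contour's lower part is unreliable (the structure fuses
with the tendon/volar-plate interface), so the lower sheath boundary is the
lower tendon arc whose direction from the tendon centroid lies strictly
within ±30° of the downward vertical. The fitted sheath contour contributes
the upper boundary after removal of a ±60° bottom wedge (wider than the
±30° arc so the bridges have room). Each side gap is closed by a parabola
`x = a·y² + b·y + c` through the two endpoints with tangent continuity at
the upper endpoint — the third constraint chosen because two endpoints
alone underdetermine a quadratic; if the closure self-intersects, straight
segments are used and the case flagged. The closed boundary always contains
the tendon centroid.

Clear/fuzzy grouping compares the means of two 15×15 windows centred 8 px
above and below the bottom tendon point (8 px so the windows abut without
overlapping); the image is "clear" iff the upper mean exceeds the lower by
strictly more than 30 intensity units. Border-clipped windows use the
clipped mean and are logged.

## Classification

The 41×21 patch is taken at the rounded tendon centroid. Wavelet features
use 2-level SWT and full 2-level wavelet-packet decompositions for haar,
db4, db6 and coif1 ("coif" without an order is read as coiflet-1), with the
patch reflect-padded to a multiple of 4; each subband contributes its mean
and standard deviation. GLCM features quantize the patch to 32 levels over
its own range and use distance-1 symmetric normalized co-occurrence
matrices in 4 directions; the 12 Haralick statistics include one
information measure of correlation (IMC1). Degenerate single-level patches
produce the analytic limits (ASM 1, contrast 0, entropy 0) with correlation
defined as 0 and logged.

Pair differences are affected − contralateral for symptomatic pairs and
right − left for asymptomatic pairs (configurable). The divergence value is
read as `(σₙ−σₐ)²(1+σₙ+σₐ)²/(σₙσₐ)` — zero at equal class spreads, growing
with spread disparity, which matches its intended behaviour; the
alternative `2σₙσₐ` denominator is available as a flag. Features with zero
spread in either class are skipped; ties keep the documented feature order.
The classifier is a standardized RBF SVM (C = 1, γ = "scale") on the top 20
features, with selection and scaling refit inside every cross-validation
fold.

Evaluation is 10 repeats of leave-one-pair-out, aggregating confusion
counts over all repeated decisions. One caveat is documented deliberately:
under a null (no class signal), leave-one-out accuracy is biased *below*
50%, because removing the held-out pair makes its class the training
minority and an uninformative SVM drifts toward the training majority.
Zero-effect phantom cohorts therefore scatter around and below 50%, and a
permutation control should be read one-sided (no spurious skill), not as a
two-sided band.

## The synthetic phantom

Each phantom renders, on a 288×224 canvas: a bright elliptical tendon
(semi-axes 42×27 px, intensity 155), a dark surrounding synovial band
(11 px, intensity 55), background tissue (90), and a bright volar plate bar
(190) beneath the sheath. Tendon shape varies through two radius modes
(cos 2θ and sin 3θ, amplitudes N(0, 0.05²) of the local radius) so the PCA
has a known 2-dimensional truth. Speckle multiplies the image by
`(1−s) + s·R` with `R` a unit-mean, σ=1-smoothed Rayleigh field and blend
amplitude s = 0.25 (≈13% intensity CV) — a standard multiplicative-speckle
surrogate, not a beam-forming simulation. "Fuzzy" phantoms brighten the
band in a ±60° wedge below the tendon to within 20 units of the tendon and
smooth a 28-row strip across the bottom boundary, putting them on the fuzzy
side of the 30-unit grouping rule; "clear" phantoms leave the full step.

Classification cohorts render one phantom pair per subject (shared ±10%
anatomy jitter); symptomatic pairs enlarge one hand's tendon area by 30%
(axes ×√1.3) and multiply its speckle amplitude by 1.5 — a surrogate for
the thickened, hypoechoic symptomatic tendon.

What the phantom does *not* emulate: attenuation and shadowing, anisotropy,
probe-pressure deformation, neighbouring tendons/bone, operator variation
in scan plane, and realistic speckle correlation. Passing phantom tests
therefore demonstrates the pipeline's internal correctness and its noise
robustness at the stated speckle level — not clinical-grade performance.

## Problem sizes and determinism

The test suite and the acceptance script train on 20 phantoms, evaluate 20
held-out speckled phantoms for segmentation, 17 placements for
localization, 20 seeded runs for the GA benchmark, and 40 pairs per
classification cohort — sizes chosen to match the scale of the original
study design while keeping a full run to a few minutes on one CPU. Every
random draw (phantom rendering, GA, cohort assembly) descends from an
explicit seed; identical seeds give bit-identical images, contours and GA
trajectories.

## Known limitations

- The anchor-based correspondence is only geometric; there is no appearance
  correspondence refinement.
- Adaptive weights inherit each term's native scale; a pathological image
  whose texture-term line maximum is near zero can inflate a weight (the
  ratio floor guards the sign, not the magnitude).
- The GA cannot refine below ~10% of the clamp-box scale on its own (see
  above); pose refinement compensates in the pipeline.
- Sheath accuracy tracks tendon accuracy, since the tendon supplies both
  the initialization and the lower boundary; phantoms whose tendon fit is
  poor (MAD ≳ 4 px) show proportionally degraded sheath boundaries.
- Leave-one-out null bias as described under Classification.
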