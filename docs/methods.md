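# Methods

This note records the scientific and numerical choices behind the
package: what each component computes, which conventions were genuinely
open, and what the synthetic phantom does and does not establish.

## Gray-level domain and quantization

All histogram methods operate on integer gray levels `0 .. L-1` with
`L = 256` by default (configurable).  Raw MRI intensities are mapped
onto that domain by a per-volume linear min-max quantization
(`volio.quantize`): one lookup for the whole volume, so relative
brightness across slices survives.  An optional robust range (e.g.
percentiles 0.5–99.5) is available because real MRI has hot pixels; it
is off by default so the mapping is exactly invertible up to rounding.
Constant volumes quantize to all-zero frames.  This normalization is a
package choice — acquisition pipelines rarely state one — and is the
single place where intensity units are decided; everything downstream is
unit-free.

Rounding convention: half-up (`floor(x + 0.5)`) everywhere a LUT value
is produced, configurable to half-even.  For the equalization core the
value `(L-1)·CDF(i)` is rational, and the rounding is performed in exact
integer arithmetic (`(2(L-1)·cum + N) // 2N` for half-up), so ties at
exactly .5 are decided by the true value rather than by floating-point
association.

Coordinates are 0-based row-major; all boxes are half-open; mask
foreground is 1.

## Equalization core and CLAHE modes

`equalize_patch` implements textbook histogram equalization of one
patch: per-level probability, cumulative distribution, output
`round((L-1)·CDF)`.  A constant patch maps to `L-1` (the CDF of its
only level is 1); an opt-in `preserve_constant` flag returns it
unchanged for users who dislike that classical artifact.

`clahe` has two modes:

* **literal** (default inside RACLAHE): the frame is tiled into
  `patch_size × patch_size` blocks, each equalized independently with
  its own histogram and pasted back.  Partial blocks at the edges keep
  their own (smaller) histograms so the whole region is covered; patch
  counts quoted for the region (e.g. 196 complete 8×8 patches at region
  side 119) refer to complete patches only.  No clipping, no
  interpolation — the aggregation of independently equalized patches.
* **standard**: classic contrast-limited CLAHE.  Per-tile histograms
  are clipped at `clip_limit × TotNum` (floor of one count), the excess
  redistributed uniformly over all levels in a single pass, and each
  pixel's output bilinearly blends the mappings of its four nearest
  tile centers (nearest tile outside the outer centers).

The standard mode was validated against scikit-image's CLAHE, which is
a different member of the same algorithm family: it uses a half-tile
shifted, reflect-padded tile grid, ~253 effective bins when asked for
256, iterative excess redistribution, and a final min-max stretch of
the output.  Per-pixel equality with it is therefore not a meaningful
target; the cross-check asserts near-perfect per-pixel correlation and
a bounded mean deviation, while exactness of this package's own
mappings is established by exact-arithmetic oracles (literal mode,
per-tile LUTs, the equalization core).

## Comparator enhancers

**AGCWD** (adaptive gamma correction with weighting distribution):
weighted pdf `pdf_w = pdf_max·((pdf − pdf_min)/(pdf_max − pdf_min))^α`,
normalized cumulative `cdf_w`, per-level gamma `γ(l) = 1 − cdf_w(l)`,
and `T(l) = round((L-1)·(l/(L-1))^γ(l))`.  The default `α = 1` makes
every exponent ≤ 1 on a base ≤ 1, so `T(l) ≥ l`: dark pixels brighten,
levels 0 and L−1 are fixed points, and the mapping is monotone (base
increases while the exponent decreases).  A flat pdf makes the
weighting transform degenerate; it is then skipped.  Constant frames
return unchanged.

**AGCCPF** blends the input histogram with a uniform histogram of equal
mass, `h' = β·h_uniform + (1−β)·h_input`, before the same gamma stage;
the color-restoration stage of the original method is the identity on
grayscale.  A consequence worth knowing: at `α = 1` the weighting
transform subtracts `pdf_min` and renormalizes, which *exactly cancels*
the uniform blend for any `β < 1` (`pdf' − pdf'_min =
(1−β)(pdf − pdf_min)`).  AGCCPF therefore coincides with AGCWD except
at `β = 1`, where the uniform histogram makes the weighting degenerate
and the gamma comes from the linear CDF.  The package keeps the blend
parameter (it matters for `α ≠ 1`) and documents the identity rather
than hiding it.

**RLBHE** splits the histogram at the Otsu threshold `t` (exhaustive
between-class-variance maximization, ties to the smallest level) and
equalizes the two sub-histograms into disjoint ranges `[X0, t]` and
`(t, XL]`.  `X0` and `XL` are found by exact search over all integer
pairs, minimizing `|mean(out) − mean(in)|` (the output mean decomposes
as `A(X0) + B(XL)`, so the search is two 1-D sweeps plus an outer sum);
ties go to the smallest pair.  This is exact rather than the closed-form
approximation sometimes used.  A structural limitation: the achievable
output class means live in `[~t/2, t]` (lower) and
`[t+1, ~(t+L)/2]` (upper), so a class whose mean lies outside its
reachable interval forces a brightness residual no choice of `X0, XL`
can remove.  On gland-against-background phantom slices the residual is
< 0.01 gray level; on adversarial bimodal frames (one blob close to an
extreme) it can be tens of levels — that is a property of range-limited
bi-histogram equalization itself.

## Region proposal and recombination

Proposed regions are forced square.  The mask-oracle proposer takes the
reference mask's bounding box, adds a 20 px margin to its larger side,
clamps the result to `[119, 149]` (134 ± 15), centers on the bounding
box and shifts — never shrinks — to fit the frame; an empty mask falls
back to the fixed, frame-centered square of side 134.  On 256×256
frames the default square covers 134²/256² ≈ 0.274 of the frame, inside
the 0.25 ± 0.12 design band.  External detectors plug in via JSON
proposals, decoupling the enhancement from any particular network.

Recombination is a hard paste: enhanced crop inside, input outside,
verified bit-exact in the tests.  Optional linear feathering over the
outermost `feather_width` pixels *inside* the region is provided for
cosmetic use but defaults off, because the recombination identity has
no blending term.

## Segmentation metrics

Overlap metrics come from the pixel confusion matrix
(`DS = 2TP/(2TP+FP+FN)`, `Sensitivity = TP/(TP+FN)`, `BA` the mean of
sensitivity and specificity).  Conventions for degenerate frames, fixed
so batch runs over phantoms with empty slices are well defined: both
masks empty → DS = 1, REI = 0, distances undefined (error, not
infinity); empty ground truth with a non-empty prediction → sensitivity
is an error.

The Rand error index is `1 −` (fraction of unordered pixel pairs on
which the two labelings agree), computed in closed form from the 2×2
contingency in O(n) and validated against an O(n²) pair enumeration.

Surface distances: a boundary pixel is a foreground pixel with at least
one background 4-neighbor, with the frame border counting as background.
Directed distances are exact Euclidean distance transforms to the other
mask's boundary (anisotropic spacing honored), both directions pooled;
HD95 is the 95th percentile of the pooled set with linear interpolation
(the common choice in medical-segmentation tooling; the alternative
max-of-directions variant is not provided) and ASD its mean.  Distances
default to pixel units; pass a physical spacing for millimetres.

## Inter-model aggregation and comparisons

For metric `m` and method `filt`, performance is the mean over models of
per-model mean scores, and variability the standard deviation across
those means with the population divisor N — the model means are the
entire population, not a sample (a sample-divisor flag exists).
Heatmap normalization first replaces distance metrics (HD, ASD) by
reciprocals (epsilon-guarded) so all columns are higher-is-better, then
min-max scales each column to best = 1 / worst = 0; lower-is-better
non-distance columns (REI) are inverted; constant columns map to 0;
variability matrices use a plain min-max with the lowest spread at 0.

Method comparisons are two-sided Wilcoxon rank-sum (Mann–Whitney) tests
on per-frame scores, exact null enumeration for tie-free samples below
8 per group and the tie-corrected normal approximation otherwise, with
significance at p ≤ 0.05 and direction-aware better-than flags
({Sensitivity, BA, DS}: higher better; {HD, ASD, REI}: lower better).
Frames are pooled rather than paired — the rank-sum test, not the
signed-rank test — matching the stated comparison protocol even though
frames are arguably paired across methods.  No multiple-testing
correction is applied, by design.

## Explainability maps

Ground-truth density is the pixel-wise sum of the binary masks over the
`Nsl` slices of a stack; saliency density sums per-frame min-max
normalized maps (normalization is a package choice so both maps share
the `[0, Nsl]` scale; constant saliency frames normalize to zero).  The
absolute difference map and its MSE quantify how far a model's salient
pixels diverge from the anatomy; identical stacks give exactly zero.
Saliency extraction itself (e.g. class-activation mapping) is out of
scope — stacks arrive as files, keeping the module model-agnostic.

## Synthetic phantom

Each patient is an axis-aligned elliptical gland (semi-axes drawn from
42–62 px, center jittered ±10 px) on a 256×256 frame, with the TZ an
inner ellipse at 0.55 of the gland axes and PZ the remaining shell;
per-slice axis jitter of ±5% emulates through-gland variation.
Intensities are region means plus Gaussian texture (SD 4), multiplied
by a single-bump Gaussian bias field and passed through Rician noise
(modulus of a complex Gaussian perturbation — the noise law of
magnitude MR images), then clipped and rounded to 8 bits.  Because
intensities are specified directly in gray levels, frames are *not*
re-stretched on quantization, so noise-free region means survive to
within rounding.

Presets:

* **low-contrast** (the hard condition): background 80, TZ 100, PZ 110
  (a 10-level zonal gap), noise σ = 8, bias amplitude 0.6 with length
  scale 40 px.  The bias parameters were chosen so the field varies
  *across* the gland region: an in-region Otsu threshold then
  misclassifies (mean baseline Dice ≈ 0.64–0.84 depending on seed),
  which is the regime local enhancement is for.
* **high-contrast**: background 30, TZ 150, PZ 180, noise σ = 4, bias
  0.1 — an easy condition the baseline segments almost perfectly.

The baseline segmenter (Otsu inside the proposed region, 3×3 binary
opening, largest connected component) is a deterministic stand-in for a
trained segmentation model, so enhancement effects on downstream
segmentation are measurable at desk scale.  The end-to-end
demonstration (`enhancement_demo`, 50 slices, seeded) therefore uses
the **standard** CLAHE mode with 64 px tiles and clip 0.02 inside the
proposed region: a threshold segmenter benefits from local equalization
only when tiles sit between the noise correlation scale and the bias
length scale; literal per-8-px equalization — aimed at texture contrast
for convolutional feature extractors — maps pure-class patches to the
full range and destroys global threshold separability (measured Dice
≈ 0.01).  The measured gain is seed-robust (+0.06 to +0.17 mean Dice
over seeds 1, 7, 42, 123).

What the phantom does *not* establish: it has no anatomy beyond nested
ellipses, no lesions, no k-space artifacts, no inter-scanner variation,
and its "model" is a threshold.  Passing results show the pipeline's
algebra and direction of effect, not clinical segmentation performance;
conclusions about trained networks on real cohorts require real data.

## Problem sizes and determinism

Test and demonstration sizes — 1000 random patches for the equalization
oracle, 200 frames for the recombination identity, 100 slices for
brightness preservation, 50 slices for the end-to-end demo — were
chosen as the smallest sizes at which the checked properties are
exercised across their input space; all stochastic tests and scripts
are seeded (hypothesis runs derandomized), and cohort generation is
bit-reproducible from (spec, seed).
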