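# Methods

This note records the models, parameter choices and numerical conventions
behind `dermoknn`, and what the synthetic validation does and does not
demonstrate.

## Synthetic lesion model

A lesion is a star-convex region around a centre, with outline

    r(θ) = R · (1 + a · Σ_{k=2,3} a_k sin(kθ + φ_k)
                  + b · Σ_{k=8..12} b_k sin(kθ + φ_k))

Per-harmonic amplitudes are drawn uniformly and L1-normalised within each
group, so `a` (asymmetry level) and `b` (border irregularity) directly
bound the fractional radial excursion of their group; `a + b < 1` keeps
the radius positive. Low harmonics (k = 2, 3) break mirror symmetry
without wrinkling the border; high harmonics (k = 8–12) wrinkle the border
without moving mass off-centre. This matches the clinical ABCD semantics:
the "A" and "B" knobs act on the asymmetry and compactness indices nearly
independently (verified by paired-lesion tests).

Colour variegation partitions the lesion into 1–4 pigment zones along a
Gaussian-smoothed random field, cut at quantiles of the mixing weights, so
zone areas follow the weights. Hairs (dark line segments, default 2 px
wide) and i.i.d. Gaussian pixel noise are overlaid *after* the
ground-truth mask is frozen, so hair-removal and segmentation quality are
measurable against exact truth.

Default class profiles (uniform ranges, 256×256 images, noise σ = 4,
0–4 hairs per image):

| parameter | normal | malignant |
|---|---|---|
| base radius (px) | 16–26 | 26–40 |
| asymmetry level | 0.02–0.12 | 0.25–0.55 |
| border irregularity | 0.02–0.10 | 0.22–0.42 |
| pigment zones | 1–2 | 2–4 |

The ranges are deliberately well separated: the generator's job is to
define a controlled two-class recovery problem, not to calibrate clinical
difficulty. **What passing tests show:** the pipeline recovers the classes
its features were designed to measure, end to end, from pixels. **What
they do not show:** performance on real dermoscopy, which adds skin
texture, illumination gradients, specular highlights, ruler/gel artifacts
and far subtler class differences. All sizes are in pixels throughout; no
pixel spacing is assumed, so no millimetre diameters are reported.

## Preprocessing

Grayscale uses the fixed luminance weights 0.299/0.587/0.114 with rounding
to the nearest integer. Hair removal is the pixel-wise maximum of
grayscale closings with line structuring elements at 8 evenly spaced
orientations, length 15 px — longer than a hair is wide, shorter than a
lesion diameter; on hair-free renders it changes the image by < 0.3 grey
levels on average, and on hairy renders it removes ≈ 90 % of the
hair-induced difference against the paired hair-free truth.

**Border rule for morphology.** At the image border the min/max windows
are restricted to in-bounds pixels (the finite-domain adjunction),
implemented with constant pads at the identity elements (0 for the max,
255 for the min). This is a deliberate choice: closing must be extensive,
increasing and idempotent, and those properties hold *exactly* only under
this rule. Stage-wise edge replication violates extensivity at border
pixels for diagonal line elements, and pad-then-crop replication violates
idempotence there; both were verified numerically before settling on the
adjunction rule.

Histogram equalization is the standard CDF remap v → round(255·CDF(v)) —
monotone, rank-preserving. PSNR (10·log₁₀(255²/MSE), +∞ sentinel at
MSE = 0) is reported between the grayscale image and the fully enhanced
output; in the feature vector the sentinel is capped at 100 dB so the
vector stays finite for distance computations.

## Segmentation

Per-pixel threshold = local mean over an odd window minus an offset;
lesions are darker than skin, so foreground is *below* threshold (the
polarity is a parameter; inverting image and polarity gives the same
mask). Defaults: window = 2⌊min(H, W)/8⌋ + 1 (65 px at 256²) — wider than
a hair, narrower than a typical lesion — and offset 10 grey levels. The
largest 8-connected component is kept (ties broken in raster order);
holes are not filled because the hole count is a feature. An empty result
raises a "no lesion detected" error carrying stage diagnostics.

**The threshold sees the dehaired raster, not the equalized one**
(config `segmentation.source`). Global equalization before a locally
adaptive threshold is counterproductive: the local-mean rule is already
invariant to monotone global remaps *in the ideal*, and in practice the
steep CDF of near-uniform skin amplifies the few-grey-level residue the
closing leaves just outside the lesion into a dark ring that the
threshold then picks up. On clean (noise-free) images this inverted the
expected noise-robustness ordering; thresholding the dehaired raster
restores it (recovery IoU ≈ 0.95 at noise σ = 4 with defaults, constant
across σ ∈ {0, 4, 8} because the orientation-max closing absorbs the
noise at the decision margin). The equalized raster remains the
"preprocessed" output used for display, intensity features and PSNR.

Lesions much smaller than the window lose a proportionally wider relative
boundary band to the closing (IoU ≈ 0.87 at radius 20); lesions whose
diameter exceeds the window hollow out, because interior windows see only
lesion. The defaults assume lesion radii of roughly 20–45 px at 256².

## Features

The 18-value vector order is frozen (`FEATURE_NAMES`) and doubles as the
CSV header. Conventions that matter:

- **Asymmetry index**: reflections are taken about both principal axes
  (eigenvectors of the second-order central moments) through the
  *centroid*; AI = (Δ₁ + Δ₂)/(2A), clamped to [0, 1]. Reflected pixel
  coordinates are rounded to the grid, which costs ≲ 0.02 on a disk. A
  half disk scores ≈ 0.185 — the long-axis reflection through the
  centroid (not the circle's diameter) overlaps the shape substantially,
  so values near 1 require far more extreme shapes than intuition
  suggests.
- **Compactness**: the perimeter comes from a Moore-neighbour boundary
  trace (unit steps axial, √2 diagonal). The walk terminates when the
  deterministic (pixel, backtrack) state repeats, which closes the
  contour correctly even on 1-px-wide limbs where "stop at the start
  pixel" fails. Rasterization inflates a disk's compactness to ≈ 1.10.
- **Diameter**: max pairwise distance between boundary pixel centres,
  computed over the convex hull (exact — the farthest pair is a hull
  pair), with an all-pairs fallback for degenerate hulls.
- **Holes**: background pixels unreachable from the border by 4-connected
  flood fill — the standard dual of 8-connected foreground.
- **Histogram statistics** use 256 integer bins and bin centres, so they
  equal the direct within-mask statistics exactly on 8-bit data; the
  whole-image mean is read off the FFT DC coefficient, identical to the
  arithmetic mean up to floating-point round-off. Both "mean" variants
  (whole-image and within-mask) are emitted, clearly named.

## Classifier

Features are z-scored with centre/scale fitted on training rows only
(population std; a constant feature gets scale 1 and a warning). Raw
features span pixel counts (~10³) down to unit-scale indices, so distances
on raw features would be dominated by area; `classifier.standardize:
false` disables scaling for strict raw-feature behaviour. Determinism
rules: neighbours are ordered by (distance, training index); odd k
precludes vote ties, and the even-k override falls back to the single
nearest neighbour. K is selected by leave-one-out accuracy over the odd
grid {1, 3, …, min(15, n−1)}, smallest k on ties, with the full curve
returned for plotting. LOO reuses the scaler fitted on the full training
set; at n = 80 the effect of not refitting per fold is negligible and the
selection stays deterministic. Models serialise to versioned JSON
(feature order, centre, scale, standardized matrix, labels, k) and
round-trip bit-exactly.

## Experiment harness and problem sizes

`run_experiment` draws the training set (default 40 + 40, echoing a small
two-class dermoscopy study) and a held-out test set (default 50 + 50)
from seed streams offset by a fixed constant, runs every image through
the full pipeline, selects k, and evaluates. Summaries are JSON with
sorted keys, so identical config + seed reproduces byte-identical output.
These sizes keep a full experiment under a minute on one CPU while giving
binomial standard errors of ~2–4 percentage points on the reported rates;
`scripts/acceptance.py` uses the same sizes, plus 20 lesions for the
segmentation IoU measurement.

## Known limitations

- No inpainting-based hair removal: very wide or dense hair mats exceed
  what closing with 15-px lines can bridge.
- Single-lesion assumption; multiple lesions are reduced to the largest
  component.
- The adaptive threshold assumes the lesion is darker than skin and
  smaller than the local window; amelanotic (light) lesions need the
  `bright_foreground` polarity, and very large lesions a larger window.
- The synthetic generator omits skin texture, illumination gradients and
  acquisition artifacts; reported accuracies characterise the pipeline's
  internal consistency, not clinical performance.
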