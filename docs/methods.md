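# Methods

This note documents the models, numerical choices and limitations behind
`histopet`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Segmentation and threshold machinery

Stain classifiers output a per-pixel probability in [0, 1].  Binarization
uses `p >= t` for positive (so a pixel exactly at the threshold is
positive), with the fixed operating points used in practice: 0.7 for
p-tau and MAO-B, 0.93 for ferric iron.  `threshold_performance` counts
the confusion matrix exhaustively per threshold; precision is marked
missing (NaN) when nothing is called positive, and such rows are excluded
from F1 maximization.  `select_operating_threshold` breaks F1 ties toward
the *larger* threshold: in burden quantification, over-calling background
is the costlier error.  The ROC area is computed exactly over the full
sweep of distinct probability values (it equals the Mann–Whitney
probability-of-correct-ranking statistic, with half credit for ties),
independent of whatever threshold grid the caller requests — a coarse
grid would otherwise bias the trapezoidal area.

The bundled pixel classifier is a regularized logistic model on raw
intensity plus a small bank of Gaussian local-mean features (sigmas 1 and
4 px by default).  It is the class of feature an interactive
random-forest/Weka segmenter uses, deliberately small: the package's
contribution is the downstream quantification, not classifier
engineering.  Training subsamples at most 50k pixels deterministically
from the labelled images.

## Burden heatmaps

`percent_positive_heatmap` assigns each pixel to the tile containing its
centre (tiles anchored at the image's top-left corner) and reports
positive/total pixels per tile.  Edge tiles with pixel coverage below
`min_coverage` (default 0.5) are flagged invalid rather than diluting the
fraction.  Positive pixels are exactly conserved over tiles, which is the
property the brute-force oracle in the tests asserts cellwise.

## Smoothness estimation and FWHM matching

For a stationary Gaussian random field smoothed by a Gaussian kernel of
width sigma, the lag-one autocorrelation along an axis with grid step h
is `exp(-h²/4σ²)`, so with s² the field variance and d² the first-
difference variance,

    FWHM = h · sqrt(−2 ln 2 / ln(1 − d²/(2 s²))).

Axes with `d² ≥ 2 s²` (white noise or rougher) are *inestimable* and
reported as NaN; the matching loop treats them as "below grid scale"
(current width 0).  Variances use only valid cells and valid neighbour
pairs.

`blur_to_fwhm` exploits that Gaussian blurs compose additively in squared
width: the cumulative kernel starts at `sqrt(target² − current²)` and is
refined by re-estimating the smoothed field — an undershoot adds the
missing squared width, an overshoot subtracts half the excess — always
re-blurring the *original* field with the cumulative kernel so overshoots
are recoverable.  Defaults: 2% relative tolerance, 25 iterations, with a
warning flag (never a silent pass) when the loop exits unconverged.
Convolutions renormalize the kernel over valid cells, so fractions stay
in [0, 1] and boundaries are not diluted.

The closed loop (smooth white noise at a known FWHM of 4–12 px on a 256²
grid, re-estimate) is part of the acceptance surface: the median estimate
over 20 seeds stays within 10% and the matched field within 2%.

## Registration

The 2D thin-plate spline minimizes bending energy subject to landmark
interpolation: an affine part plus `U(r) = r² log r` radial terms whose
weights satisfy the side conditions (zero sum, zero first moments).  The
linear system `[[K+λI, P], [Pᵀ, 0]]` is solved directly; λ = 0 (exact
interpolation) is the default because landmarks are few and hand-placed;
λ > 0 is exposed for jittered landmarks.  With exactly three landmarks
the side conditions force all radial weights to zero and the map is the
affine through the three points (asserted to 1e-8 in tests).  The
evaluate path is cross-checked against an independent thin-plate RBF
interpolator.

Images are resampled by inverse mapping of output cell centres (nearest
for masks, linear for fractional heatmaps); cells mapping outside the
source are flagged invalid.  Coordinates are continuous millimetres,
origin at the grid's top-left cell centre, arrays indexed (row=y, col=x).
A deformable refinement step could be inserted after the TPS (the hook is
the `transform` callable accepted by `apply_transform_2d`); on the
synthetic phantoms the closed-loop Dice of the TPS alone is ≥ 0.95, well
above the 0.8 QC bar used on real data, so none is shipped.

Dice of two empty masks is defined as 1.0 with an explicit `both_empty`
flag — identical emptiness — a case real data never hits but a
synthetic sweep can.

## SUVR, ROIs and the model suite

SUVR is voxel activity divided by the mean activity in a reference mask
(inferior cerebellar grey matter on real data; the phantom uses the
background compartment held at the reference activity).  The
tracer-positivity ROI keeps voxels with SUVR strictly greater than the
cutoff — a voxel exactly at 1.2 is excluded — intersected with the
anatomical mask and optionally with named structures (e.g. the lentiform
nucleus).  Cutoffs 1.2/1.3/1.4 are nested by construction and all three
are fitted in a pipeline run.

The suite m0–m6 is ordinary least squares with intercept, all models on
the identical pairwise-complete row set so AIC values are comparable.
AIC uses the least-squares form `n·ln(RSS/n) + 2k` with `k = p + 2`
(intercept and error variance count); the Gaussian constant is omitted
since it cancels in every ΔAIC.  AICc adds `2k(k+1)/(n−k−1)`; at voxel
counts in the thousands the two agree to < 0.1, and ΔAIC is reported
against the fullest available model (m0; m3 when p-tau is absent, as in
a non-tauopathy case — absent markers are recorded as missing and shrink
the suite, never imputed as zero).  VIF for each full-model predictor is
`1/(1−R²_j)` from regressing it on the others.  Betas are unstandardized
by default (burdens share the 0–1 fraction scale); `standardize=True`
z-scores outcome and predictors for cross-case comparison.  Only
fixed-effects models are implemented: no random-effects structure is
guessed, and no multiple-testing correction is applied (raw p values with
significance stars).  Spearman's ρ uses average ranks with the
t-approximation p value; the Wilcoxon rank-sum test uses the
tie-corrected normal approximation with continuity correction, matching
the conventions of the R functions a practitioner would call.  Hexbin
summaries are rectangular-bin counts: counts, not rendering, are the
contract.

## The synthetic cohort

The phantom emulates the *structure* of the problem, not its appearance:

- **Anatomy** — an ellipse/ellipsoid with an 18%-of-radius cortical
  ribbon, interior white matter, and two compact deep blobs (lentiform,
  hippocampus), jittered a few percent by the seed.
- **Marker texture** — a marker-specific continuous texture field
  (Gaussian-blob clusters at ~80/600 µm for p-tau, ~15 µm puncta for
  iron, ~400 µm diffuse noise for MAO-B), thresholded per region at the
  exact top-k quantile so empirical positive fractions equal the
  requested region densities up to pixel discretization.  Default
  densities make tau cortex/hippocampus-dominant (0.30/0.35), iron
  lentiform-dominant (0.25) and MAO-B white-matter-dominant (0.25) —
  plausible values, not calibrated to any measured case.
- **Classifier noise** — Beta-distributed probabilities for positive and
  background pixels (defaults Beta(5,2)/Beta(2,5) for the generic op).
  The pipeline's per-marker defaults are sharper — Beta(12,1)/Beta(1,12),
  and Beta(60,1)/Beta(1,60) for iron — so that recall at the fixed
  operating thresholds (0.7, 0.93) is ~0.99, emulating well-trained
  segmenters at their published operating points.  Degenerate constants
  (1.0/0.0) give the noiseless limit used in closed-loop tests.
- **Warp** — a sum of Gaussian displacement bumps rescaled to a peak
  displacement (2 mm default, capped below 10% of the field of view),
  with true landmark correspondences jittered by 0.1 mm placement noise.
  Section images are resampled under the true warp; in the pipeline,
  probability maps are warped with nearest-neighbour sampling because
  linear blending at 40 µm pitch would erase single-pixel iron puncta —
  a resampling artifact real scanned sections do not have.
- **PET** — `SUVR = β0 + Σ βm·burden_m + N(0, σ)` voxelwise, the
  generative inverse of m0, with defaults β = (1.1, 0.7, 0.4, 0.0) and
  σ = 0.1 SUVR.  The activity volume is the SUVR field scaled by a
  reference activity, with the background compartment held exactly at
  that activity so SUVR normalization is exercised and exact.

Every generator is a pure function of (parameters, seed); a master seed
spawns per-stage sub-seeds through a seed sequence, so a fixed config is
bit-reproducible and stages can re-run in isolation.

What the phantom does **not** emulate: stain colour/appearance (no DAB
rendering), tissue tearing and folding (the warp is smooth), through-plane
anatomy at histological resolution, spatially correlated PET noise, and
partial-volume cross-talk between markers.  Passing tests therefore
demonstrate the pipeline's numerics and identifiability under the stated
generative model, not robustness to every artifact of real material.

## Problem sizes and the two validation routes

The default pipeline run uses 6 coronal sections of 32×32 mm at 40 µm
pixel pitch (800² pixels per marker per section), 1 mm² tiles, 4 mm
section spacing and a 5 mm PET target FWHM — sizes chosen so a full run
is comfortable on a laptop while every stage operates far from its
degenerate limits.  Heatmaps are FWHM-matched in-plane (2D per section):
with 4 mm slab sampling a through-plane smoothness estimate is not
meaningful at this scale.

The β-recovery experiment runs at the PET grid directly (10×36×36 voxels
at 4×2×2 mm, giving ≈3 000 ROI voxels): burdens are region means plus
smooth spatial noise, PET is synthesized from them, and the suite is
refitted over 50 replicates.  Its ROI is thresholded on the *noiseless*
SUVR — thresholding the observed outcome would condition the selection on
the noise and bias the recovery check; the pipeline's own ROI builder
thresholds observed SUVR, as it must on real data.  The pixel-level
stages are validated separately by their own closed loops (quantification
exactness, threshold oracles, FWHM loop, registration loop).

In the full pixel-level run the recovered β are attenuated relative to
truth (errors-in-variables: segmentation, registration residuals and
interpolation act as measurement noise on the burden regressors).  The
report surfaces this as `ground_truth_recovery` diagnostics rather than
hiding it; in the noiseless identity-warp configuration the recovery is
exact to ≥ 6 decimals, which the tests assert.

## Known limitations

- No deformable (SyN-style) refinement after the TPS; adequate on smooth
  synthetic warps, not necessarily on torn tissue.
- The FWHM estimator assumes a stationary Gaussian random field; on
  strongly structured burden maps it is a QC heuristic, not an unbiased
  estimate of scanner resolution.
- OLS inference ignores spatial autocorrelation of voxels, as does the
  analysis convention it reproduces; standard errors on real data are
  optimistic in that sense.
- The 3D affine stage handles global alignment only; slice-to-slice
  z-registration errors are not modelled by the phantom.
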