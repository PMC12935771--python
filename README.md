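# histopet

Voxel-to-voxel comparison of quantitative histology with tau-PET.

Flortaucipir is a PET tracer for paired-helical-filament tau, but part of
its retention is *off-target*: ferric storage iron (hemosiderin, notably in
the lentiform nucleus) and monoamine-oxidase B (MAO-B, enriched in reactive
astrocytes and white matter) also bind it.  Disentangling these substrates
requires bringing post-mortem immunohistochemistry — stained at micrometre
pitch — into the millimetre voxel grid of the in-vivo PET and asking, voxel
by voxel, how much of the signal each substrate explains.

`histopet` implements that pipeline as a tested, reusable library for
image-analysis researchers working at the histology/PET interface:

1. **Segmentation** — per-pixel stain probabilities (from a CNN/Weka-style
   classifier; a regularized logistic pixel classifier is included as a
   light stand-in) are binarized at an operating threshold chosen from the
   precision–recall curve (p-tau/MAO-B at probability ≥ 0.7, ferric iron
   at 0.93 by max-F1), with full ROC/PR evaluation machinery.
2. **Quantification** — binary masks become *burden heatmaps*: the fraction
   of marker-positive pixels per 1 mm² tile.
3. **Resolution matching** — the effective smoothness of a map is estimated
   as the FWHM of the equivalent Gaussian kernel from the variance ratio of
   first differences, `FWHM = h·sqrt(−2 ln 2 / ln(1 − d²/2s²))`, and
   heatmaps are iteratively blurred to the PET's FWHM (5 mm default).
4. **Registration** — stained sections are registered to blockface
   photographs by a landmark thin-plate spline (affine + `r² log r` radial
   terms), the transform is applied to the heatmaps, sections are stacked
   into a 3D volume, and a least-squares 3D affine aligns it to MRI/PET
   space.  Registration quality is scored by Dice overlap (QC bar 0.8).
5. **Statistics** — PET activity is normalized to a reference region
   (SUVR), a tracer-positivity ROI keeps voxels with SUVR > 1.2
   (1.3/1.4 as sensitivity cutoffs), and a fixed suite of nested OLS
   models is fitted to the voxel table:

   ```
   m0: SUVR ~ ptau + iron + maob      m4: SUVR ~ ptau
   m1: SUVR ~ ptau + iron             m5: SUVR ~ iron
   m2: SUVR ~ ptau + maob             m6: SUVR ~ maob
   m3: SUVR ~ iron + maob
   ```

   compared by ΔAIC against the full model, with VIF collinearity
   screening, Spearman correlations per marker, and Wilcoxon rank-sum
   contrasts (e.g. MAO-B inside vs outside white matter).

Because the matched autopsy/PET volumes such a study uses are not public,
the package ships a first-class **synthetic cohort generator**: a geometric
anatomy phantom (cortical ribbon, white matter, lentiform nucleus,
hippocampus), marker masks with marker-specific texture (clustered p-tau
blobs, iron puncta, diffuse MAO-B) and controlled region densities, noisy
classifier probability maps, a known smooth section-to-blockface warp with
jittered landmarks, and a PET volume generated as a known linear
combination of smoothed burdens plus Gaussian noise.  Every stage therefore
has a ground-truth answer, and parameter recovery of the generative β
coefficients is the headline validation.

## Worked example

```python
from histopet.pipeline import simulate_voxel_case
from histopet.models import SuvrModelSuite

table, gt, label_map = simulate_voxel_case(42)   # truth: β0=1.1, βptau=0.7, βiron=0.4, βmaob=0
print(SuvrModelSuite(table).fit().summary())
```

```
SUVR ~ burden model suite  (n = 3204 voxels, reference m0)
----------------------------------------------------------------
Spearman correlation (rho) with SUVR
  ptau           0.486  ***
  iron           0.021   ns
  maob          -0.229  ***
Applied multilinear model: m0   R-squared 0.276
Beta coefficients
  ptau           0.699 (SE 0.024)  ***
  iron           0.403 (SE 0.026)  ***
  maob          -0.026 (SE 0.024)   ns
VIF (reference-model predictors)
  ptau           1.739
  iron           1.340
  maob           1.350
Delta AIC vs m0
  m0         0.00
  m1        -0.86 <- best
  m2       227.31
  m3       776.79
  m4       238.00
  m5      1030.26
  m6       775.33
```

The fitted coefficients recover the generative values (0.7, 0.4, 0) within
their standard errors; AIC prefers `m1`, the true generative structure
(tau + iron, no MAO-B contribution); all VIF < 2, so collinearity between
burdens is not a concern on this phantom.

The full pixel-level run — histology phantom → probability maps →
segmentation → heatmaps → warp/TPS registration → FWHM matching → SUVR
ROIs → model suite — is one call (or `histopet run-all` from the shell):

```python
from histopet.pipeline import RunConfig, run_pipeline
report = run_pipeline(RunConfig(seed=1), out_dir="scratch/run1")
```

The report records per-stage QC (segmentation AUC, per-section Dice, FWHM
flags, ROI voxel counts per cutoff) and, in synthetic mode, ground-truth
recovery diagnostics.

## Command-line interface

```
histopet run-all          full pipeline from one config + seed
histopet simulate | segment | quantify | register | analyze
                          individual stages from cached state
histopet validate-config  config sanity check
```

Common flags: `--config PATH`, `--seed INT`, `--out DIR`.

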