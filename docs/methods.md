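# Methods

## The analysis model

The pipeline treats leukoaraiosis (LKA) as the thresholded, conspicuous part
of a white-matter process and asks whether the *normal-appearing* white
matter (NAWM) around and away from it carries a diffuse FLAIR intensity
elevation that scales with lesion burden. The observation unit is the
(subject × NAWM stratum) mean normalized intensity

    NAWM_M(s, k) = mean FLAIR over stratum k of subject s / splenium mean of s,

with stratum *k* ∈ 1..5 the NAWM voxels at in-slice Chebyshev distance *k*
from LKA borders. The inferential model is a linear mixed model with the
five strata as the clustering variable:

    NAWM_M = β0 + β1·quartile + β2·age_decades + β3·hypertension
             + u0(stratum) [+ u1(stratum)·quartile] + ε

Quartile is the cohort quartile (1–4) of the total lesion volume LKA_V,
entered as a numeric regressor so β1 reads as "change per quartile
increase"; age enters in decades. Model 1 has random intercepts only,
model 2 adds random slopes on the quartile. Model choice uses AIC and a
likelihood-ratio test (2 df: slope variance + intercept–slope covariance)
on maximum-likelihood fits; reported models are REML refits.

Assumptions worth stating explicitly:

* clustering is on the five strata, not on subjects. Rows from one subject
  are treated as independent given the stratum. This mirrors the design the
  pipeline reproduces; its cost is that subject-level noise (mainly the
  splenium-reference sampling error shared by all of a subject's rows) is
  not absorbed by a random effect, so fixed-effect SEs from the image
  pipeline are somewhat optimistic. With only five clusters the
  random-effect variances are weakly identified; boundary fits are flagged
  (`boundary_fit`), never silently accepted.
* fixed-effect inference is Wald with the literal 1.96 multiplier — no
  Satterthwaite/Kenward-Roger correction — so every number is exactly
  reproducible from the estimate and SE.
* the plain χ²₂ reference for the LRT is conservative at the variance
  boundary (the slope variance cannot be negative); a non-significant
  comparison is therefore the expected outcome under slope homogeneity.

## Segmentation conventions

* All intensity thresholds are inclusive: a voxel at exactly the 6-SD
  threshold is lesion; "below the CSF maximum" excludes strictly smaller
  values. Boundary ties are measure-zero for continuous intensities.
* The splenium SD uses denominator n−1 (sample SD), the common behaviour of
  radiology workstations; the choice is configuration, not inference.
* ROI value = mean over voxels whose centres fall inside the 1-mm sphere.
  On the default 0.75 × 0.75 × 3.5 mm grid this is exactly one voxel; ROI
  centres are therefore drawn uniformly over voxel centres in the region,
  with a non-overlap constraint (pairwise ≥ 1 mm), seeded for determinism.
  Explicit world-mm centres can be supplied to reproduce rater placements.
* Morphology border convention: the grid is clipped. Dilation ignores
  out-of-grid neighbours; erosion counts them as background, so border
  voxels erode away. Erosion/dilation duality holds exactly for masks clear
  of the border. The white-matter cleanup element is the 6-connected cross —
  the most conservative 3-D choice for 3.5-mm slices; the strata use the
  in-slice 8-neighbourhood, whose recursive dilation equals in-slice
  Chebyshev distance. Distance is *defined* by dilation count; no Euclidean
  transform is involved.
* Hemispheres are defined by the sign of the world x coordinate (a supplied
  label map overrides); voxels exactly on the midline belong to neither
  hemisphere. With a unilateral infarct the contralateral hemisphere is
  analysed and LKA_V is doubled; subjects are dropped (with a logged
  reason) only when their final WM or NAWM mask is empty.
* Quartile cut-points use the nearest-rank definition with ties going low,
  computed on the analysis cohort after exclusions. Labels depend only on
  ranks.
* The "full NAWM" mean is reported descriptively but never entered as a
  sixth cluster row: it contains the strata and would double-count voxels.

## The phantom generator

The generator emulates the *statistical structure* the analysis assumes,
not brain anatomy: a supratentorial WM ellipsoid, paired ventricular CSF
ellipsoids, a posterior midline splenium block, and ellipsoidal lesions
confined to WM with a periventricular placement bias. Lesions are mirrored
about the midline (hemisphere-symmetric, as leukoaraiosis load tends to
be), which also makes the doubled single-hemisphere volume agree with the
bilateral volume. Intensities are arbitrary units; only ratios to the
splenium mean are meaningful.

Non-lesion WM voxels follow

    I = wm_base + (b_q·L + b_age·(age − 68)/10)·S + dd·(6 − d)·S·[1 ≤ d ≤ 5] + noise

with burden level L ∈ 1..4, splenium mean S, and in-slice Chebyshev
distance d to the nearest lesion. Defaults (units: splenium-normalized
unless noted):

| parameter | default | why |
| --- | --- | --- |
| grid / voxels | 80×96×16 at 0.75×0.75×3.5 mm | anisotropic clinical-FLAIR slab |
| wm_base | 102 a.u. (S = 100) | baseline NAWM_M ≈ 1.02, matching the fitted intercept scale |
| b_q (burden effect) | 0.025 per quartile | the diffuse-elevation effect size under study |
| b_age | 0.011 per decade | age effect of the same analysis |
| dd (distance decay) | 0.02 per voxel of proximity | puts the stratum-1 vs stratum-5 contrast near 0.08 and the stratum ANOVA F near 50 |
| splenium voxel SD | 8 a.u. | sets the 6-SD threshold at 1.48·S, separating lesions (2.0·S) from the most elevated NAWM (≈1.25·S) while keeping the normalization error (ROI-mean CoV ≈ 2.5%) realistic |
| noise SD | 2 a.u. | voxel noise small against the thresholding margins |
| ages | N(68, 16), clipped to [30, 100] | cohort descriptives of the emulated study |
| age–burden copula weight | 0.43 | the reported age–LKA_V correlation |
| burden volume bands (cm³) | 0.3–1.2 / 1.8–3.0 / 4.0–8.0 / 10–16 | disjoint bands around a median ≈ 3–4 cm³, so empirical quartiles reproduce the intended levels |
| infarct side | none/left/right = 0.45/0.31/0.24 | exercised hemisphere-exclusion frequencies |

Geometry+covariates and voxel noise use independent random streams, so
noise can be switched off without changing anatomy. With `noise_sd = 0`
every lesion voxel exceeds any attainable sampled threshold and no other
outlined voxel reaches it, so segmentation recovers the ground-truth mask
exactly and each stratum's NAWM_M equals the closed form above divided by
the measured splenium mean.

What the phantom does **not** emulate: real anatomy, bias fields,
registration error, partial-volume mixing across slices, scanner physics,
or rater variability in outlining. Passing tests demonstrate that the
*procedure* is implemented correctly and recovers known effects under its
own assumptions — not that those effects are estimable from any particular
clinical dataset.

A second, purely statistical generator (`simulate_stratum_table`) draws
observation tables directly from the mixed-model equation (balanced
quartiles, Gaussian stratum effects, iid residuals). The Monte Carlo
studies of the inference stage use it at 100 subjects × 5 strata with 200
replicates — large enough for stable rejection-rate estimates, small enough
to run on one CPU in minutes; the residual SD 0.068 in the
parameter-recovery study is calibrated so the fixed-effect SE is ≈ 0.003,
the regime of the analysis being mirrored.

## Numerical notes

* Mixed models are fitted with statsmodels `MixedLM`. Boundary fits
  (random-effect variance at zero) often trip a single optimizer, so the
  fit walks bfgs → lbfgs → powell → cg → nm and keeps the first converged
  result; a dataset fitted perfectly (residual variance → 0) is accepted
  and flagged, since the fixed effects are then the exact GLS solution.
  A singular random-effect covariance yields conditional modes of zero.
* AIC is computed as 2k − 2·logLik with k = fixed effects + distinct
  random-effect (co)variances + residual variance. The LRT statistic is
  clamped at zero when optimizer tolerance makes it marginally negative.
  REML log-likelihoods are never compared across models.
* Shapiro–Wilk at α = 0.05 per group decides t vs Wilcoxon and Pearson vs
  Spearman in the univariate screen; groups of fewer than 3 observations or
  constant data are treated as non-normal.
* Degenerate inputs: an empty manual outline yields an empty (valid) LKA
  mask; empty strata emit no observation row (a zero would bias the
  models); identical lesion volumes across the cohort degrade quartiles to
  a single label with a logged warning; covariates with one observed level
  are skipped in the screen.

## Limitations

* Five clusters identify random-effect variances weakly; the per-stratum
  slope estimates are conditional modes shrunk toward the fixed effect and
  should be read as patterns, not precise quantities.
* The stratum-clustered model understates subject-level correlation (see
  above); a subject-level random effect is deliberately out of scope
  because the reproduced design does not include one.
* The 2-D (in-slice) distance definition cannot see vertically adjacent
  lesion voxels on neighbouring slices; with 3.5-mm slices this is the
  intended trade-off against vertical partial-volume averaging.
* NIfTI (RAS+) is the interchange format; voxel indices are 0-based
  internally and all user-facing coordinates are world mm.
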