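# flairstrata

Quantifies subtle FLAIR signal-intensity changes in **normal-appearing white
matter (NAWM)** and relates them to the burden of **leukoaraiosis** (white
matter hyperintensities of cerebral small-vessel disease). It is written for
neuroimaging researchers who want a tested, reusable implementation of an
ROI-calibrated leukoaraiosis segmentation, distance-stratified NAWM
extraction, splenium-normalized intensity statistics and stratum-clustered
mixed-model inference — together with a phantom cohort simulator that makes
the whole analysis reproducible without patient data.

## Method

Per subject, working on co-registered atlas-space volumes:

1. **Calibration.** 8–10 ROIs of 1-mm diameter in the splenium of the corpus
   callosum give a reference mean `S` and SD `σ`; the lesion threshold is
   `S + 6σ`. 6–8 ROIs in the anterior horns of the lateral ventricles give a
   CSF maximum; voxels below it are excluded from all final masks.
2. **Segmentation.** White matter: atlas probability ≥ 0.95, restricted to
   supratentorial WM, then two erosions and one dilation (6-connected) to
   keep mostly central white matter. Leukoaraiosis (LKA): a generous manual
   outline intersected with voxels ≥ `S + 6σ`. NAWM: WM − LKA. With a
   unilateral infarct only the contralateral hemisphere is analysed, and the
   single-hemisphere lesion volume LKA_V is doubled.
3. **Distance strata.** Five recursive 2-D 8-connected dilations of the LKA
   mask; stratum *k* = (*k*-th dilation − (*k−1*)-th) ∩ NAWM, i.e. the NAWM
   voxels at in-slice Chebyshev distance *k* from lesion borders.
4. **Metrics.** NAWM_M = mean FLAIR intensity over a stratum, divided by
   `S` (dimensionless); LKA_V quartiles form an ordinal 1–4 variable.
5. **Inference.** Stratum ANOVA of NAWM_M; univariate screening
   (t/Wilcoxon, Pearson/Spearman); linear mixed models with the strata as
   the clustering variable:

   `NAWM_M = β₀ + β₁·quartile + β₂·age/10 + β₃·HTN + u₀(stratum) [+ u₁(stratum)·quartile] + ε`

   compared by AIC and a 2-df likelihood-ratio test on ML fits, with REML
   refits reported (Wald 95% CIs, estimate ± 1.96·SE).

The phantom generator builds atlas-space subjects (WM ellipsoid,
ventricular CSF, splenium block, hemisphere-symmetric hyperintense lesions)
whose NAWM intensity carries a known burden effect per quartile, a linear
proximity elevation near lesions, an age effect and Gaussian noise — so the
pipeline's recovery of the injected truth is testable end to end.

## Worked example

```sh
flairstrata run-all --n 24 --seed 5 --out demo/
# analysed 24/24 subjects; ANOVA F=13.9; quartile effect 0.0264 [0.0218, 0.0309]; LRT p=1.000
```

`demo/summary.json` then contains (abridged):

```
stratum_mean_nawm_m:  1: 1.1895  2: 1.1691  3: 1.1491  4: 1.1294  5: 1.1090
lmm_random_intercepts.fixed_effects.lka_quartile:
    estimate 0.0264, se 0.0023, ci [0.0218, 0.0310]
per_stratum_slopes:   1: 0.0265  2: 0.0264  3: 0.0264  4: 0.0263  5: 0.0262
model_comparison:     lrt_statistic 0.0, lrt_df 2, lrt_p 1.000
```

Reading: mean normalized NAWM intensity is highest adjacent to lesions and
falls with every voxel of distance (the stratum gradient drives the ANOVA
F); each lesion-volume quartile step raises NAWM_M by ≈ 0.026 normalized
units after adjusting for age and hypertension; the per-stratum random
slopes are homogeneous here, so the likelihood-ratio test finds no benefit
of the random-slopes model. In Python the same run is
`run_simulated_cohort(PhantomConfig(seed=5), 24, RunConfig(seed=5))`.

Other entry points: `flairstrata simulate` writes phantom NIfTI volumes and
a covariates CSV; `segment`, `strata` and `analyze` run individual stages
(see `--help`).

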