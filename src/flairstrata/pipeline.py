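"""End-to-end orchestration: subject-level processing and cohort analysis.

``run_subject`` composes calibration -> WM masking -> LKA thresholding ->
NAWM -> hemisphere exclusion -> distance strata -> intensity metrics for
one subject; failures exclude the subject with a structured reason instead
of aborting the run.  ``run_cohort`` processes all subjects, computes the
lesion-volume quartiles on the survivors, and runs the full statistical
analysis (stratum ANOVA, univariate screening, both mixed models and their
comparison), optionally writing per-subject NIfTI masks, CSV tables,
per-quartile voxel maps and a machine-readable JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import BinaryMask, Volume
from .metrics import assign_quartiles, normalize_to_splenium, stratum_table
from .phantom import PhantomConfig, SubjectBundle, generate_cohort
from .roi import ROIPlacementError, calibrate_thresholds
from .segmentation import (SegmentationResult, apply_hemisphere_exclusion,
                           build_nawm, segment_lka, wm_mask_from_probability)
from .stats import (ModelComparison, compare_models, strata_anova,
                    univariate_screen)
from .strata import StrataSet, build_strata

__all__ = ["RunConfig", "SubjectResult", "CohortReport", "run_subject",
           "run_cohort", "run_simulated_cohort", "build_voxel_maps",
           "load_manifest"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Options steering one pipeline run."""
    seed: int = 0
    n_splenium_rois: int = 10
    n_ventricle_rois: int = 8
    roi_diameter_mm: float = 1.0
    wm_prob_threshold: float = 0.95
    n_strata: int = 5
    normality_alpha: float = 0.05
    min_subjects: int = 8
    make_voxel_maps: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


@dataclass
class SubjectResult:
    subject_id: str
    bundle: SubjectBundle = field(repr=False)
    excluded: bool = False
    exclusion_reason: str | None = None
    seg: SegmentationResult | None = field(default=None, repr=False)
    strata: StrataSet | None = field(default=None, repr=False)
    rows: pd.DataFrame | None = field(default=None, repr=False)
    nawm_m_full: float | None = None

    def sidecar(self) -> dict:
        """JSON-serializable per-subject accounting."""
        d: dict = {"subject_id": self.subject_id, "excluded": self.excluded,
                   "exclusion_reason": self.exclusion_reason}
        if self.seg is not None:
            thr = self.seg.thresholds
            d.update({
                "thresholds": {"splenium_mean": thr.splenium_mean,
                               "splenium_sd": thr.splenium_sd,
                               "lka_threshold": thr.lka_threshold,
                               "csf_max": thr.csf_max},
                "lka_volume_cm3": self.seg.lka_volume_cm3,
                "hemisphere_excluded": self.seg.hemisphere_excluded,
                "lka_voxels": self.seg.lka_mask.count,
                "nawm_voxels": self.seg.nawm_mask.count,
            })
        if self.strata is not None:
            counts = self.strata.voxel_counts()
            d["stratum_voxels"] = counts
            d["nawm_beyond_strata_voxels"] = (
                self.strata.full_nawm.count - sum(counts))
        return d


def _derive_seed(base: int, *branch: int) -> int:
    ss = np.random.SeedSequence([base, *branch])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_subject(bundle: SubjectBundle, config: RunConfig,
                subject_index: int = 0) -> SubjectResult:
    """Process one subject; deterministic given (config.seed, subject_index)."""
    result = SubjectResult(subject_id=bundle.subject_id, bundle=bundle)
    try:
        thr = calibrate_thresholds(
            bundle.flair, bundle.splenium_mask, bundle.ventricle_mask,
            n_splenium=config.n_splenium_rois,
            n_ventricle=config.n_ventricle_rois,
            diameter_mm=config.roi_diameter_mm,
            seed=_derive_seed(config.seed, subject_index))
    except ROIPlacementError as exc:
        result.excluded = True
        result.exclusion_reason = f"roi-placement: {exc}"
        log.warning("subject %s excluded: %s", bundle.subject_id, exc)
        return result

    wm = wm_mask_from_probability(bundle.wm_probability,
                                  threshold=config.wm_prob_threshold)
    if wm.is_empty():
        result.excluded = True
        result.exclusion_reason = "empty white-matter mask"
        return result
    lka = segment_lka(bundle.flair, bundle.outline_mask, thr)
    nawm = build_nawm(wm, lka, bundle.flair, thr)
    seg = SegmentationResult(lka_mask=lka, wm_mask=wm, nawm_mask=nawm,
                             lka_volume_cm3=lka.volume_cm3,
                             hemisphere_excluded="none", thresholds=thr)
    seg = apply_hemisphere_exclusion(seg, bundle.hemisphere_map,
                                     bundle.infarct_side)
    if seg.nawm_mask.is_empty():
        result.excluded = True
        result.exclusion_reason = "empty NAWM mask after hemisphere exclusion"
        result.seg = seg
        return result

    strata = build_strata(seg.lka_mask, seg.nawm_mask, config.n_strata)
    normalized = normalize_to_splenium(bundle.flair, thr.splenium_mean)
    rows = stratum_table(bundle.subject_id, normalized, strata,
                         seg.lka_volume_cm3, bundle.age, bundle.hypertension)
    result.seg = seg
    result.strata = strata
    result.rows = rows
    full = rows[rows["stratum"] == "full"]
    result.nawm_m_full = (float(full["nawm_m"].iloc[0]) if len(full) else None)
    return result


def build_voxel_maps(lka_masks: list[BinaryMask],
                     nawm_masks: list[BinaryMask],
                     normalized_volumes: list[Volume],
                     quartiles: list[int]) -> dict[int, dict[str, Volume]]:
    """Per-quartile voxel maps across subjects in shared atlas geometry.

    For each quartile: the LKA frequency map counts, per voxel, the subjects
    whose LKA mask covers it; the NAWM intensity map is the voxelwise mean
    normalized intensity over the subjects whose NAWM mask covers it (NaN
    where no subject contributes).
    """
    ref = lka_masks[0]
    maps: dict[int, dict[str, Volume]] = {}
    for q in sorted(set(quartiles)):
        freq = np.zeros(ref.shape, dtype=float)
        ssum = np.zeros(ref.shape, dtype=float)
        cnt = np.zeros(ref.shape, dtype=float)
        for lka, nawm, vol, qi in zip(lka_masks, nawm_masks,
                                      normalized_volumes, quartiles):
            ref.check_same_geometry(lka)
            if qi != q:
                continue
            freq += lka.data
            ssum[nawm.data] += vol.data[nawm.data]
            cnt += nawm.data
        with np.errstate(invalid="ignore"):
            mean = np.where(cnt > 0, ssum / np.maximum(cnt, 1), np.nan)
        maps[q] = {"lka_frequency": Volume(freq, ref.affine),
                   "nawm_mean": Volume(mean, ref.affine)}
    return maps


@dataclass
class CohortReport:
    subject_table: pd.DataFrame
    stratum_table: pd.DataFrame
    anova: tuple[float, float]
    univariate: pd.DataFrame
    comparison: ModelComparison
    voxel_maps: dict[int, dict[str, Volume]] | None
    exclusions: list[dict]
    results: list[SubjectResult] = field(repr=False, default_factory=list)

    def summary_dict(self) -> dict:
        """Machine-readable run summary (the canonical regression surface)."""
        def lmm_dict(r):
            return {
                "method": r.method,
                "has_random_slopes": r.has_random_slopes,
                "fixed_effects": {t: dataclasses.asdict(fe)
                                  for t, fe in r.fixed_effects.items()},
                "random_effects": r.random_effects,
                "per_stratum_slopes": r.per_stratum_slopes(),
                "per_stratum_intercepts": r.per_stratum_intercepts(),
                "variance_components": r.variance_components,
                "log_likelihood": r.log_likelihood,
                "aic": r.aic,
                "boundary_fit": r.boundary_fit,
            }

        df = self.stratum_table
        numbered = df[df["stratum"] != "full"]
        stratum_means = (numbered.groupby("stratum")["nawm_m"].mean()
                         .to_dict())
        return {
            "n_subjects": int(len(self.subject_table)),
            "n_analysed": int((~self.subject_table["excluded"]).sum()),
            "exclusions": self.exclusions,
            "anova": {"F": self.anova[0], "p": self.anova[1]},
            "stratum_mean_nawm_m": stratum_means,
            "univariate": self.univariate.to_dict(orient="records"),
            "lmm_random_intercepts": lmm_dict(self.comparison.reml_intercepts),
            "lmm_random_slopes": lmm_dict(self.comparison.reml_slopes),
            "model_comparison": {
                "aic_intercepts_ml": self.comparison.aic_intercepts,
                "aic_slopes_ml": self.comparison.aic_slopes,
                "lrt_statistic": self.comparison.lrt_statistic,
                "lrt_df": self.comparison.lrt_df,
                "lrt_p": self.comparison.lrt_p,
            },
        }

    def write(self, out_dir: str | Path, save_masks: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subject_table.to_csv(out / "subject_table.csv", index=False)
        self.stratum_table.to_csv(out / "stratum_table.csv", index=False)
        self.univariate.to_csv(out / "univariate.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, sort_keys=True))
        if self.voxel_maps:
            for q, m in self.voxel_maps.items():
                m["lka_frequency"].save(out / f"lka_frequency_q{q}.nii.gz")
                m["nawm_mean"].save(out / f"nawm_mean_q{q}.nii.gz")
        if save_masks:
            for r in self.results:
                if r.seg is None:
                    continue
                sub = out / r.subject_id
                sub.mkdir(exist_ok=True)
                r.seg.lka_mask.save(sub / "lka.nii.gz")
                r.seg.wm_mask.save(sub / "wm.nii.gz")
                r.seg.nawm_mask.save(sub / "nawm.nii.gz")
                (sub / "sidecar.json").write_text(
                    json.dumps(r.sidecar(), indent=2, sort_keys=True))


def run_cohort(bundles: list[SubjectBundle], config: RunConfig,
               covariate_kinds: dict[str, str] | None = None) -> CohortReport:
    """Process a cohort end to end and run the statistical analysis."""
    results = [run_subject(b, config, subject_index=i)
               for i, b in enumerate(bundles)]
    survivors = [r for r in results if not r.excluded]
    exclusions = [{"subject_id": r.subject_id,
                   "reason": r.exclusion_reason}
                  for r in results if r.excluded]
    if len(survivors) < config.min_subjects:
        raise RuntimeError(
            f"only {len(survivors)} subjects survived exclusions "
            f"(minimum {config.min_subjects}); reasons: {exclusions}")

    volumes = [r.seg.lka_volume_cm3 for r in survivors]
    quartiles = assign_quartiles(volumes)
    qmap = {r.subject_id: int(q) for r, q in zip(survivors, quartiles)}

    tables = []
    for r in survivors:
        rows = r.rows.copy()
        rows["lka_quartile"] = qmap[r.subject_id]
        tables.append(rows)
    stratum_df = pd.concat(tables, ignore_index=True)

    subject_rows = []
    for r in results:
        subject_rows.append({
            "subject_id": r.subject_id,
            "age": r.bundle.age,
            "hypertension": int(r.bundle.hypertension),
            "infarct_side": r.bundle.infarct_side,
            "lka_volume_cm3": (r.seg.lka_volume_cm3 if r.seg else np.nan),
            "lka_quartile": qmap.get(r.subject_id, np.nan),
            "nawm_m": r.nawm_m_full,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason,
        })
    subject_df = pd.DataFrame(subject_rows)

    anova = strata_anova(stratum_df)
    kinds = covariate_kinds or {"age": "quantitative",
                                "hypertension": "binary"}
    uni = univariate_screen(subject_df[~subject_df["excluded"]], kinds,
                            outcome="nawm_m",
                            normality_alpha=config.normality_alpha)
    comparison = compare_models(stratum_df)

    maps = None
    if config.make_voxel_maps:
        maps = build_voxel_maps(
            [r.seg.lka_mask for r in survivors],
            [r.seg.nawm_mask for r in survivors],
            [normalize_to_splenium(r.bundle.flair,
                                   r.seg.thresholds.splenium_mean)
             for r in survivors],
            [qmap[r.subject_id] for r in survivors])

    return CohortReport(subject_table=subject_df, stratum_table=stratum_df,
                        anova=anova, univariate=uni, comparison=comparison,
                        voxel_maps=maps, exclusions=exclusions,
                        results=results)


def run_simulated_cohort(phantom_config: PhantomConfig, n_subjects: int,
                         config: RunConfig
                         ) -> tuple[CohortReport, list[SubjectBundle]]:
    """Generate a phantom cohort and analyse it end to end."""
    bundles, _ = generate_cohort(phantom_config, n_subjects)
    return run_cohort(bundles, config), bundles


def load_manifest(path: str | Path) -> list[SubjectBundle]:
    """Load a cohort from a manifest CSV of file paths and covariates.

    Required columns: subject_id, flair, wm_probability, splenium_mask,
    ventricle_mask, outline_mask, age, hypertension, infarct_side.
    Optional: hemisphere_map (NIfTI of +1/-1/0 labels; derived from the
    world x coordinate when absent).
    """
    base = Path(path).parent
    df = pd.read_csv(path)
    bundles = []
    for _, row in df.iterrows():
        def vol(col):
            p = Path(row[col])
            return Volume.load(p if p.is_absolute() else base / p)

        def mask(col):
            p = Path(row[col])
            return BinaryMask.load(p if p.is_absolute() else base / p)

        flair = vol("flair")
        if "hemisphere_map" in row and isinstance(row["hemisphere_map"], str):
            hemi = np.sign(vol("hemisphere_map").data).astype(np.int8)
        else:
            from .segmentation import hemisphere_labels
            hemi = hemisphere_labels(flair)
        bundles.append(SubjectBundle(
            subject_id=str(row["subject_id"]), flair=flair,
            wm_probability=vol("wm_probability"),
            splenium_mask=mask("splenium_mask"),
            ventricle_mask=mask("ventricle_mask"),
            outline_mask=mask("outline_mask"),
            hemisphere_map=hemi,
            truth_lesion_mask=BinaryMask(np.zeros(flair.shape, bool),
                                         flair.affine),
            age=float(row["age"]),
            hypertension=bool(int(row["hypertension"])),
            infarct_side=str(row["infarct_side"]),
            burden_level=0, truth_lesion_volume_cm3=float("nan")))
    return bundles
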