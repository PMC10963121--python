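"""Synthetic atlas-space phantom cohorts with known ground truth.

The phantom emulates the data structure the analysis assumes, not brain
anatomy: a supratentorial white-matter (WM) ellipsoid, paired ventricular
CSF ellipsoids near the grid centre, a posterior midline splenium block,
and random hyperintense ellipsoidal lesions confined to WM with a
configurable periventricular placement bias.  Intensities are arbitrary
units; only ratios to the splenium mean are meaningful.

Generative intensity model for a non-lesion WM voxel::

    I = wm_base + (b_q * L + b_age * (age - age_mean)/10) * S
        + dd * (E + 1 - d) * S     for proximity 1 <= d <= E
        + Gaussian noise

where ``L`` is the subject's burden level (1-4), ``S`` the splenium mean,
``d`` the in-slice Chebyshev distance to the nearest lesion, ``E`` the
proximity extent (default 5) and ``dd`` the per-voxel distance decay.  The
injected NAWM_M-vs-quartile slope therefore equals ``b_q`` by construction,
and stratum means decay linearly with distance.  Lesion voxels take a flat
intensity far above the splenium mean + 6 SD threshold, so the calibrated
segmentation recovers the ground-truth lesion mask exactly in the
noise-free case.

Two independent random streams (geometry+covariates vs voxel noise) let
noise be toggled without changing anatomy; everything is deterministic
given ``(config.seed, subject_seed)``.

A separate, purely statistical generator (:func:`simulate_stratum_table`)
draws long-format observation tables directly from the mixed-model
generative equation, for Monte Carlo studies of the inference stage where
simulating images would add nothing but runtime.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import BinaryMask, Volume, make_affine
from .morphology import CROSS_3D_6, IN_PLANE_8, dilate, erode
from .segmentation import hemisphere_labels

__all__ = ["PhantomConfig", "SubjectBundle", "PhantomError",
           "draw_covariates", "generate_subject", "generate_cohort",
           "write_cohort", "simulate_stratum_table",
           "expected_nawm_intensity"]

log = logging.getLogger(__name__)

INFARCT_SIDES = ("none", "left", "right")


class PhantomError(RuntimeError):
    """The requested phantom cannot be built under the given constraints."""


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the phantom generator (defaults are the study conditions).

    Intensity units are arbitrary; effect sizes (``burden_effect_per_quartile``,
    ``distance_decay_per_voxel``, ``age_effect_per_decade``) are expressed in
    splenium-normalized units, i.e. they multiply the splenium mean.
    """
    grid_shape: tuple[int, int, int] = (80, 96, 16)
    voxel_dims_mm: tuple[float, float, float] = (0.75, 0.75, 3.5)
    wm_base_intensity: float = 102.0
    splenium_intensity_mean: float = 100.0
    splenium_intensity_sd: float = 8.0
    csf_intensity_max: float = 60.0
    background_intensity: float = 85.0
    lesion_intensity: float = 200.0
    lesion_count_range: tuple[int, int] = (1, 60)
    lesion_radius_range_mm: tuple[float, float] = (1.5, 6.0)
    burden_effect_per_quartile: float = 0.025
    distance_decay_per_voxel: float = 0.02
    proximity_extent_vox: int = 5
    noise_sd: float = 2.0
    age_effect_per_decade: float = 0.011
    age_mean: float = 68.0
    age_sd: float = 16.0
    age_range: tuple[float, float] = (30.0, 100.0)
    age_burden_weight: float = 0.43
    hypertension_prevalence: float = 0.68
    hypertension_burden_step: float = 0.04
    infarct_side_probs: tuple[float, float, float] = (0.45, 0.31, 0.24)
    outline_margin_vox: int = 2
    periventricular_bias: float = 0.5
    mirror_lesions: bool = True
    burden_volume_bands_cm3: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.3, 1.2), 2: (1.8, 3.0),
                                 3: (4.0, 8.0), 4: (10.0, 16.0)})
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.csf_intensity_max < self.wm_base_intensity:
            raise ValueError("csf_intensity_max must be below wm_base_intensity")
        thr = (self.splenium_intensity_mean
               + 6.0 * self.splenium_intensity_sd)
        if not self.lesion_intensity > thr:
            raise ValueError(
                "lesion_intensity must exceed splenium mean + 6 SD "
                f"({self.lesion_intensity} <= {thr})")
        for lo, hi in (self.lesion_count_range, self.lesion_radius_range_mm,
                       self.age_range):
            if not lo <= hi:
                raise ValueError(f"range ({lo}, {hi}) is empty")
        if set(self.burden_volume_bands_cm3) != {1, 2, 3, 4}:
            raise ValueError("burden bands must cover levels 1-4")
        bands = [self.burden_volume_bands_cm3[i] for i in (1, 2, 3, 4)]
        for (lo, hi), (lo2, _) in zip(bands, bands[1:]):
            if not (lo < hi <= lo2):
                raise ValueError("burden bands must be non-empty, increasing "
                                 "and disjoint")
        if abs(sum(self.infarct_side_probs) - 1.0) > 1e-9:
            raise ValueError("infarct_side_probs must sum to 1")

    @property
    def affine(self) -> np.ndarray:
        cx, cy, cz = (s // 2 for s in self.grid_shape)
        return make_affine(self.voxel_dims_mm, (cx, cy, cz))

    @property
    def voxel_volume_cm3(self) -> float:
        d = self.voxel_dims_mm
        return d[0] * d[1] * d[2] / 1000.0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["burden_volume_bands_cm3"] = {
            int(k): list(v) for k, v in d["burden_volume_bands_cm3"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "voxel_dims_mm", "lesion_count_range",
                    "lesion_radius_range_mm", "age_range",
                    "infarct_side_probs"):
            if key in d:
                d[key] = tuple(d[key])
        if "burden_volume_bands_cm3" in d:
            d["burden_volume_bands_cm3"] = {
                int(k): tuple(v)
                for k, v in d["burden_volume_bands_cm3"].items()}
        return cls(**d)


@dataclass
class SubjectBundle:
    """Everything the pipeline needs for one phantom subject."""
    subject_id: str
    flair: Volume
    wm_probability: Volume
    splenium_mask: BinaryMask
    ventricle_mask: BinaryMask
    outline_mask: BinaryMask
    hemisphere_map: np.ndarray            # +1 right, -1 left, 0 midline
    truth_lesion_mask: BinaryMask
    age: float
    hypertension: bool
    infarct_side: str
    burden_level: int
    truth_lesion_volume_cm3: float

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.flair.save(out / "flair.nii.gz")
        self.wm_probability.save(out / "wm_probability.nii.gz")
        for name in ("splenium_mask", "ventricle_mask", "outline_mask",
                     "truth_lesion_mask"):
            getattr(self, name).save(out / f"{name}.nii.gz")
        Volume(self.hemisphere_map.astype(float),
               self.flair.affine).save(out / "hemisphere_map.nii.gz")


def expected_nawm_intensity(config: PhantomConfig, burden_level: int,
                            age: float, distance: int | None = None) -> float:
    """Closed-form noise-free intensity of a non-lesion WM voxel.

    ``distance`` is the in-slice Chebyshev distance to the nearest lesion
    (``None`` or > proximity extent means no proximity elevation).  The
    arithmetic mirrors the generator's voxel composition step for step, so
    the equality is exact in floating point.
    """
    sm = config.splenium_intensity_mean
    v = config.wm_base_intensity + (
        config.burden_effect_per_quartile * burden_level
        + config.age_effect_per_decade * (age - config.age_mean) / 10.0) * sm
    if distance is not None and 1 <= distance <= config.proximity_extent_vox:
        v += (config.distance_decay_per_voxel
              * (config.proximity_extent_vox + 1 - distance) * sm)
    return v


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray,
               semi_axes_vox: np.ndarray) -> np.ndarray:
    """Boolean ellipsoid rasterized over a local bounding box."""
    out = np.zeros(shape, dtype=bool)
    lo = np.maximum(np.floor(center - semi_axes_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi_axes_vox).astype(int) + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        return out
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                        indexing="ij")
    r2 = sum(((g - c) / s) ** 2
             for g, c, s in zip(grids, center, semi_axes_vox))
    out[tuple(slice(a, b) for a, b in zip(lo, hi))] = r2 <= 1.0
    return out


def _static_geometry(config: PhantomConfig) -> dict[str, np.ndarray]:
    """Anatomy shared by all subjects: WM compartment, ventricles, splenium."""
    shape = np.asarray(config.grid_shape)
    center = shape // 2
    aff = config.affine

    wm_semi = np.maximum((shape * np.array([0.38, 0.40, 0.44])), 2.0)
    wm_comp = _ellipsoid(config.grid_shape, center.astype(float), wm_semi)

    vent = np.zeros(config.grid_shape, dtype=bool)
    v_semi = np.array([4.0, 13.0, 3.0])
    for dx in (-9.0, 9.0):
        c = center.astype(float) + np.array([dx, 4.0, 0.0])
        vent |= _ellipsoid(config.grid_shape, c, v_semi)

    spl = np.zeros(config.grid_shape, dtype=bool)
    sx = slice(int(center[0]) - 3, int(center[0]) + 4)
    sy = slice(int(center[1] - wm_semi[1] * 0.72),
               int(center[1] - wm_semi[1] * 0.72) + 5)
    sz = slice(int(center[2]) - 1, int(center[2]) + 1)
    spl[sx, sy, sz] = True
    spl &= wm_comp  # keep the splenium inside the cranial compartment
    if spl.sum() < 20:
        raise PhantomError("grid too small: splenium block does not fit "
                           "inside the WM compartment")
    if (spl & vent).any():
        raise PhantomError("geometry error: splenium intersects ventricles")

    vent_margin = dilate(BinaryMask(vent, aff), CROSS_3D_6).data
    spl_margin = dilate(BinaryMask(spl, aff), CROSS_3D_6).data
    wm_clean = wm_comp & ~vent_margin & ~spl_margin
    if not wm_clean.any():
        raise PhantomError("grid too small: no WM left after carving "
                           "ventricles and splenium")
    return {"wm": wm_clean, "ventricles": vent, "splenium": spl}


def _place_lesions(config: PhantomConfig, geom: dict[str, np.ndarray],
                   rng: np.random.Generator, burden_level: int) -> np.ndarray:
    aff = config.affine
    wm = BinaryMask(geom["wm"], aff)
    core = erode(erode(wm, CROSS_3D_6), IN_PLANE_8, iterations=2).data
    candidates = np.argwhere(core)
    if len(candidates) == 0:
        raise PhantomError("grid too small: no interior WM voxels available "
                           "for lesion placement")
    pv_band = dilate(BinaryMask(geom["ventricles"], aff), IN_PLANE_8,
                     iterations=8).data & core
    pv_candidates = np.argwhere(pv_band)

    lo, hi = config.burden_volume_bands_cm3[burden_level]
    target = rng.uniform(lo, hi)
    dims = np.asarray(config.voxel_dims_mm)
    lesions = np.zeros(config.grid_shape, dtype=bool)
    count = 0
    max_count = config.lesion_count_range[1]
    while (lesions.sum() * config.voxel_volume_cm3 < target
           and count < max_count):
        pool = (pv_candidates
                if (len(pv_candidates)
                    and rng.random() < config.periventricular_bias)
                else candidates)
        c = pool[rng.integers(len(pool))].astype(float)
        r = rng.uniform(*config.lesion_radius_range_mm)
        semi_mm = np.array([r, r, 0.8 * r])
        les = _ellipsoid(config.grid_shape, c, semi_mm / dims) & geom["wm"]
        if config.mirror_lesions:
            # reflect about the midline voxel column (world x -> -x), so the
            # lesion load is hemisphere-symmetric as in small-vessel disease
            mirrored = np.zeros_like(les)
            mirrored[1:] = les[:0:-1]
            les |= mirrored & geom["wm"]
        lesions |= les
        count += 1
    vol = lesions.sum() * config.voxel_volume_cm3
    if vol < lo * 0.5 or count < config.lesion_count_range[0]:
        raise PhantomError(
            f"grid too small to place the requested lesion volume for "
            f"burden level {burden_level}: reached {vol:.2f} cm^3 of "
            f"target {target:.2f} cm^3 with {count} lesions")
    return lesions


def draw_covariates(config: PhantomConfig, burden_level: int,
                    rng: np.random.Generator) -> tuple[float, bool, str]:
    """Draw (age, hypertension, infarct_side) for one subject.

    Age is Gaussian (default 68 +/- 16 years, clipped to a plausible adult
    range) and positively correlated with the burden level through a
    Gaussian copula weight; hypertension prevalence rises mildly with
    burden; the infarct side is drawn from fixed frequencies.
    """
    z_burden = (burden_level - 2.5) / np.sqrt(1.25)
    w = config.age_burden_weight
    z = w * z_burden + np.sqrt(max(0.0, 1.0 - w * w)) * rng.standard_normal()
    age = float(np.clip(config.age_mean + config.age_sd * z,
                        *config.age_range))
    p_htn = float(np.clip(config.hypertension_prevalence
                          + config.hypertension_burden_step
                          * (burden_level - 2.5), 0.02, 0.98))
    hypertension = bool(rng.random() < p_htn)
    infarct_side = str(rng.choice(INFARCT_SIDES, p=config.infarct_side_probs))
    return age, hypertension, infarct_side


def generate_subject(config: PhantomConfig, subject_seed: int,
                     burden_level: int,
                     subject_id: str | None = None) -> SubjectBundle:
    """Generate one phantom subject, deterministic given (seed, subject_seed)."""
    if burden_level not in (1, 2, 3, 4):
        raise ValueError(f"burden_level must be 1-4, got {burden_level}")
    aff = config.affine
    geom = _static_geometry(config)
    rng_geo = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_seed, 0]))
    rng_noise = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_seed, 1]))
    rng_cov = np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_seed, 2]))

    age, hypertension, infarct_side = draw_covariates(config, burden_level,
                                                      rng_cov)

    # --- anatomy ----------------------------------------------------------
    lesions = _place_lesions(config, geom, rng_geo, burden_level)
    truth = BinaryMask(lesions, aff)
    outline = dilate(truth, IN_PLANE_8, iterations=config.outline_margin_vox)

    # --- intensities ------------------------------------------------------
    sm = config.splenium_intensity_mean
    vol = np.full(config.grid_shape, config.background_intensity, dtype=float)
    base = expected_nawm_intensity(config, burden_level, age, distance=None)
    wm_vox = geom["wm"]
    vol[wm_vox] = base
    # proximity elevation on WM voxels at in-slice Chebyshev distance d
    prev = truth
    for d in range(1, config.proximity_extent_vox + 1):
        cur = dilate(prev, IN_PLANE_8)
        ring = cur.data & ~prev.data & wm_vox
        vol[ring] += (config.distance_decay_per_voxel
                      * (config.proximity_extent_vox + 1 - d) * sm)
        prev = cur
    n_vent = int(geom["ventricles"].sum())
    vol[geom["ventricles"]] = rng_geo.uniform(
        0.3 * config.csf_intensity_max, config.csf_intensity_max, n_vent)
    n_spl = int(geom["splenium"].sum())
    vol[geom["splenium"]] = rng_geo.normal(
        sm, config.splenium_intensity_sd, n_spl)
    vol[lesions] = config.lesion_intensity
    if config.noise_sd > 0:
        vol += rng_noise.normal(0.0, config.noise_sd, config.grid_shape)

    prob = np.full(config.grid_shape, 0.02)
    shell = dilate(BinaryMask(wm_vox, aff), CROSS_3D_6).data & ~wm_vox
    prob[shell] = 0.6
    prob[wm_vox] = 0.99
    prob[geom["splenium"]] = 0.5
    prob[geom["ventricles"]] = 0.0

    flair = Volume(vol, aff)
    bundle = SubjectBundle(
        subject_id=subject_id or f"S{subject_seed:04d}",
        flair=flair,
        wm_probability=Volume(prob, aff),
        splenium_mask=BinaryMask(geom["splenium"], aff),
        ventricle_mask=BinaryMask(geom["ventricles"], aff),
        outline_mask=outline,
        hemisphere_map=hemisphere_labels(flair),
        truth_lesion_mask=truth,
        age=age, hypertension=hypertension, infarct_side=infarct_side,
        burden_level=burden_level,
        truth_lesion_volume_cm3=truth.volume_cm3)
    assert not (bundle.truth_lesion_mask.data
                & ~bundle.outline_mask.data).any()
    assert not (bundle.splenium_mask.data & bundle.ventricle_mask.data).any()
    return bundle


def generate_cohort(config: PhantomConfig, n_subjects: int
                    ) -> tuple[list[SubjectBundle], pd.DataFrame]:
    """Generate a cohort with burden levels balanced across subjects."""
    if n_subjects < 8:
        raise ValueError("need at least 8 subjects for non-degenerate "
                         f"quartiles, got {n_subjects}")
    levels = np.tile([1, 2, 3, 4], int(np.ceil(n_subjects / 4)))[:n_subjects]
    bundles, rows = [], []
    for i, level in enumerate(levels):
        b = generate_subject(config, subject_seed=i, burden_level=int(level),
                             subject_id=f"S{i:04d}")
        bundles.append(b)
        rows.append({"subject_id": b.subject_id, "age": b.age,
                     "hypertension": int(b.hypertension),
                     "infarct_side": b.infarct_side,
                     "truth_burden_level": b.burden_level,
                     "seed": config.seed})
    return bundles, pd.DataFrame(rows)


def write_cohort(bundles: list[SubjectBundle], covariates: pd.DataFrame,
                 out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        b.save(out / b.subject_id)
    covariates.to_csv(out / "covariates.csv", index=False)


def simulate_stratum_table(n_subjects: int, *,
                           intercept: float = 1.026,
                           quartile_effect: float = 0.025,
                           age_effect_per_decade: float = 0.011,
                           hypertension_effect: float = 0.006,
                           stratum_intercept_sd: float = 0.077,
                           stratum_intercepts: np.ndarray | None = None,
                           stratum_slope_sd: float = 0.0,
                           stratum_slopes: np.ndarray | None = None,
                           residual_sd: float = 0.068,
                           n_strata: int = 5,
                           age_mean: float = 68.0, age_sd: float = 16.0,
                           age_burden_weight: float = 0.43,
                           hypertension_prevalence: float = 0.68,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Draw a long-format observation table from the mixed-model equation.

    Per-stratum intercept/slope deviations are drawn Normal(0, sd) unless
    given explicitly; quartiles are balanced 1-4 across subjects; age is
    Gaussian, correlated with the quartile through ``age_burden_weight``;
    the residual is iid Gaussian per (subject, stratum) row.  Defaults place
    the fixed effects and the stratum intercept spread at the magnitudes of
    the clinical analysis this pipeline mirrors.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    q = np.tile([1, 2, 3, 4], int(np.ceil(n_subjects / 4)))[:n_subjects]
    zb = (q - 2.5) / np.sqrt(1.25)
    w = age_burden_weight
    age = age_mean + age_sd * (w * zb + np.sqrt(max(0.0, 1 - w * w))
                               * rng.standard_normal(n_subjects))
    htn = (rng.random(n_subjects) < hypertension_prevalence).astype(int)
    u0 = (np.asarray(stratum_intercepts, dtype=float)
          if stratum_intercepts is not None
          else rng.normal(0.0, stratum_intercept_sd, n_strata))
    u1 = (np.asarray(stratum_slopes, dtype=float)
          if stratum_slopes is not None
          else rng.normal(0.0, stratum_slope_sd, n_strata))
    if len(u0) != n_strata or len(u1) != n_strata:
        raise ValueError("stratum effect arrays must have length n_strata")

    qs = np.repeat(q, n_strata)
    ages = np.repeat(age, n_strata)
    htns = np.repeat(htn, n_strata)
    strat = np.tile(np.arange(1, n_strata + 1), n_subjects)
    y = (intercept + u0[strat - 1]
         + (quartile_effect + u1[strat - 1]) * qs
         + age_effect_per_decade * ages / 10.0
         + hypertension_effect * htns
         + rng.normal(0.0, residual_sd, n_subjects * n_strata))
    return pd.DataFrame({
        "subject_id": np.repeat([f"S{i:04d}" for i in range(n_subjects)],
                                n_strata),
        "stratum": strat.astype(str),
        "nawm_m": y,
        "lka_volume_cm3": qs.astype(float),
        "lka_quartile": qs,
        "age_decades": ages / 10.0,
        "hypertension": htns,
    })
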