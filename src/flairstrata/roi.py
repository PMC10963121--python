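"""Reference-structure ROI sampling and the two calibration thresholds.

The segmentation is calibrated per subject from two small-ROI samples:

* splenium of the corpus callosum (8-10 ROIs of 1-mm diameter): the lesion
  threshold is ``mean + 6*SD`` of the ROI values, and the mean also serves
  as the normalization reference for all intensity metrics;
* anterior horns of the lateral ventricles (6-8 ROIs): the maximum ROI value
  is the CSF exclusion floor -- voxels below it are removed from the lesion
  and normal-appearing white matter masks so that residual CSF cannot
  contaminate them.

An ROI value is the mean intensity over the voxels whose centres fall inside
the 1-mm world-space sphere.  On the default anisotropic grid
(0.75 x 0.75 x 3.5 mm) the sphere contains exactly the single voxel at its
centre; this degenerate but faithful behaviour is accepted and tested.
ROI centres are drawn uniformly (seeded) over voxel centres within the
region, subject to a non-overlap constraint (pairwise centre distance >=
diameter); a manual mode accepts explicit world-mm centres instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import BinaryMask, Volume

__all__ = ["ROISample", "CalibrationThresholds", "ROIPlacementError",
           "sample_rois", "lka_threshold", "csf_exclusion_threshold",
           "calibrate_thresholds", "N_ROI_RANGE"]

log = logging.getLogger(__name__)

#: admissible ROI counts per reference structure
N_ROI_RANGE = {"splenium": (8, 10), "ventricle": (6, 8)}


class ROIPlacementError(RuntimeError):
    """The region cannot host the requested number of non-overlapping ROIs."""


@dataclass
class ROISample:
    """Intensity values sampled from small spherical ROIs."""
    values: np.ndarray
    n_rois: int
    roi_diameter_mm: float
    source: str | None = None
    centers_mm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("ROI sample is empty")
        if self.values.size != self.n_rois:
            raise ValueError("n_rois does not match number of values")
        if self.source in N_ROI_RANGE:
            lo, hi = N_ROI_RANGE[self.source]
            if not lo <= self.n_rois <= hi:
                raise ValueError(
                    f"{self.source} sample must have {lo}-{hi} ROIs, "
                    f"got {self.n_rois}")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (denominator n-1)."""
        return float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0

    @property
    def max(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class CalibrationThresholds:
    """Per-subject intensity calibration derived from the ROI samples."""
    splenium_mean: float
    splenium_sd: float
    lka_threshold: float   # splenium_mean + 6 * splenium_sd
    csf_max: float         # maximum of the ventricle sample

    def __post_init__(self) -> None:
        expected = self.splenium_mean + 6.0 * self.splenium_sd
        if abs(self.lka_threshold - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("lka_threshold must equal splenium_mean + 6*SD")


def _roi_value(volume: Volume, center_mm: np.ndarray, radius_mm: float,
               inv_affine: np.ndarray) -> float:
    """Mean over voxels whose centres lie within the world-space sphere."""
    cvox = (inv_affine @ np.append(center_mm, 1.0))[:3]
    dims = np.asarray(volume.voxel_dims_mm)
    reach = np.ceil(radius_mm / dims).astype(int) + 1
    lo = np.maximum(np.floor(cvox).astype(int) - reach, 0)
    hi = np.minimum(np.ceil(cvox).astype(int) + reach + 1,
                    np.asarray(volume.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    idx = np.stack(np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = idx @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    inside = np.linalg.norm(world - center_mm, axis=1) <= radius_mm + 1e-9
    if not inside.any():
        raise ROIPlacementError(
            f"ROI at {center_mm} mm covers no voxel centre")
    vals = volume.data[sl].reshape(-1)[inside]
    return float(vals.mean())


def sample_rois(volume: Volume, region_mask: BinaryMask, n_rois: int,
                diameter_mm: float = 1.0, seed: int | None = None,
                source: str | None = None,
                centers_mm: np.ndarray | None = None) -> ROISample:
    """Sample ``n_rois`` non-overlapping spherical ROIs within a region.

    Parameters
    ----------
    centers_mm
        Optional explicit (n, 3) world-mm ROI centres (manual mode,
        reproducing rater placements).  When omitted, centres are drawn
        uniformly over voxel centres inside ``region_mask`` with a seeded
        generator, rejecting placements closer than ``diameter_mm``.
    """
    volume.check_same_geometry(region_mask)
    if region_mask.is_empty():
        raise ROIPlacementError(
            f"region {source or '<unnamed>'} is empty; cannot place ROIs")
    inv = np.linalg.inv(volume.affine)
    radius = diameter_mm / 2.0

    if centers_mm is None:
        voxels = np.argwhere(region_mask.data)
        world = voxels @ volume.affine[:3, :3].T + volume.affine[:3, 3]
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(world))
        chosen: list[np.ndarray] = []
        for i in order:
            c = world[i]
            if all(np.linalg.norm(c - p) >= diameter_mm for p in chosen):
                chosen.append(c)
                if len(chosen) == n_rois:
                    break
        if len(chosen) < n_rois:
            raise ROIPlacementError(
                f"region {source or '<unnamed>'} too small to place "
                f"{n_rois} non-overlapping ROIs of {diameter_mm} mm "
                f"(placed {len(chosen)})")
        centers_mm = np.asarray(chosen)
    else:
        centers_mm = np.asarray(centers_mm, dtype=float).reshape(-1, 3)
        if len(centers_mm) != n_rois:
            raise ValueError("number of centres does not match n_rois")

    values = np.array([_roi_value(volume, c, radius, inv)
                       for c in centers_mm])
    return ROISample(values=values, n_rois=n_rois,
                     roi_diameter_mm=diameter_mm, source=source,
                     centers_mm=centers_mm)


def lka_threshold(splenium: ROISample) -> float:
    """Lesion threshold: 6 sample SDs above the splenium ROI mean."""
    if splenium.values.size < 2:
        raise ValueError("need at least 2 splenium ROI values to estimate SD")
    return splenium.mean + 6.0 * splenium.sd


def csf_exclusion_threshold(ventricle: ROISample) -> float:
    """CSF exclusion floor: maximum of the ventricle ROI values."""
    return ventricle.max


def calibrate_thresholds(flair: Volume, splenium_mask: BinaryMask,
                         ventricle_mask: BinaryMask,
                         n_splenium: int = 10, n_ventricle: int = 8,
                         diameter_mm: float = 1.0,
                         seed: int | None = None) -> CalibrationThresholds:
    """Derive both calibration thresholds for one subject's FLAIR volume."""
    spl = sample_rois(flair, splenium_mask, n_splenium, diameter_mm,
                      seed=seed, source="splenium")
    seed2 = None if seed is None else seed + 1
    vent = sample_rois(flair, ventricle_mask, n_ventricle, diameter_mm,
                       seed=seed2, source="ventricle")
    thr = CalibrationThresholds(
        splenium_mean=spl.mean, splenium_sd=spl.sd,
        lka_threshold=lka_threshold(spl),
        csf_max=csf_exclusion_threshold(vent))
    log.debug("calibration: splenium %.4f +/- %.4f -> lka thr %.4f, "
              "csf max %.4f", thr.splenium_mean, thr.splenium_sd,
              thr.lka_threshold, thr.csf_max)
    return thr
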