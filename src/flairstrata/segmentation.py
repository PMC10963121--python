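"""Leukoaraiosis / white-matter / NAWM segmentation for one subject.

The per-subject masks are produced in four steps:

1. white matter: atlas probability map thresholded at ``>= 0.95`` inside the
   supratentorial mask, then two erosions and one dilation (6-connected)
   keeping mostly central white matter;
2. leukoaraiosis (LKA): intersection of the generous manual/supplied outline
   with voxels at or above the calibrated ``mean + 6*SD`` splenium threshold;
3. NAWM: white matter minus LKA; for both LKA and NAWM, voxels below the
   ventricular-CSF maximum are excluded;
4. optional hemisphere exclusion: when the subject has a visible unilateral
   infarct, only the contralateral hemisphere is analysed and the remaining
   LKA volume is doubled.

All intensity thresholds are inclusive (``>=`` keeps a voxel; "below ...
excluded" is read as strict ``<``), a stated convention the tests pin down.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .grids import BinaryMask, Volume
from .morphology import CROSS_3D_6, StructuringElement, dilate, erode, mask_algebra
from .roi import CalibrationThresholds

__all__ = ["SegmentationResult", "wm_mask_from_probability", "segment_lka",
           "build_nawm", "apply_hemisphere_exclusion", "hemisphere_labels",
           "dice"]

log = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    """Final per-subject masks plus the calibration that produced them.

    ``lka_volume_cm3`` is voxel count x voxel volume, doubled when only a
    single hemisphere was analysed.
    """
    lka_mask: BinaryMask
    wm_mask: BinaryMask
    nawm_mask: BinaryMask
    lka_volume_cm3: float
    hemisphere_excluded: str  # none / left / right (the *excluded* side)
    thresholds: CalibrationThresholds


def wm_mask_from_probability(prob: Volume,
                             supratentorial_mask: BinaryMask | None = None,
                             threshold: float = 0.95,
                             elem: StructuringElement = CROSS_3D_6) -> BinaryMask:
    """White-matter mask: probability >= threshold, two erosions, one dilation."""
    if prob.data.min() < -1e-9 or prob.data.max() > 1 + 1e-9:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = BinaryMask(prob.data >= threshold, prob.affine)
    if supratentorial_mask is not None:
        mask = mask_algebra(mask, supratentorial_mask, "intersection")
    mask = dilate(erode(mask, elem, iterations=2), elem, iterations=1)
    if mask.is_empty():
        warnings.warn("white-matter mask is empty after thresholding and "
                      "morphology; subject should be excluded", stacklevel=2)
        log.warning("empty white-matter mask produced")
    return mask


def segment_lka(flair: Volume, outline: BinaryMask,
                thresholds: CalibrationThresholds) -> BinaryMask:
    """LKA mask: outlined voxels at/above the 6-SD splenium threshold.

    Voxels below the CSF maximum are excluded.  An empty outline is valid
    (subjects may have no visible lesions) and yields an empty mask.
    """
    flair.check_same_geometry(outline)
    keep = (outline.data
            & (flair.data >= thresholds.lka_threshold)
            & (flair.data >= thresholds.csf_max))
    return BinaryMask(keep, flair.affine)


def build_nawm(wm: BinaryMask, lka: BinaryMask, flair: Volume,
               thresholds: CalibrationThresholds) -> BinaryMask:
    """NAWM mask: (WM - LKA) with sub-CSF voxels removed."""
    wm.check_same_geometry(lka)
    wm.check_same_geometry(flair)
    nawm = mask_algebra(wm, lka, "difference")
    keep = nawm.data & (flair.data >= thresholds.csf_max)
    return BinaryMask(keep, wm.affine)


def hemisphere_labels(grid: Volume | BinaryMask) -> np.ndarray:
    """+1 where the voxel-centre world x > 0 (right), -1 where < 0 (left),
    0 exactly on the midline (excluded from both hemispheres)."""
    x = grid.world_coordinates()[..., 0]
    return np.sign(x).astype(np.int8)


def apply_hemisphere_exclusion(seg: SegmentationResult,
                               hemisphere_map: np.ndarray | None,
                               infarct_side: str) -> SegmentationResult:
    """Restrict the analysis to the hemisphere contralateral to an infarct.

    With ``infarct_side`` of ``left`` or ``right`` the LKA and NAWM masks are
    intersected with the contralateral hemisphere and the LKA volume is
    doubled; with ``none`` the masks are untouched and the volume is the
    plain bilateral volume.
    """
    if infarct_side not in ("none", "left", "right"):
        raise ValueError(f"unknown infarct side {infarct_side!r}; "
                         "expected none/left/right")
    if infarct_side == "none":
        return replace(seg, lka_volume_cm3=seg.lka_mask.volume_cm3,
                       hemisphere_excluded="none")
    if hemisphere_map is None:
        hemisphere_map = hemisphere_labels(seg.lka_mask)
    keep_label = -1 if infarct_side == "right" else 1  # contralateral side
    keep = hemisphere_map == keep_label
    lka = BinaryMask(seg.lka_mask.data & keep, seg.lka_mask.affine)
    nawm = BinaryMask(seg.nawm_mask.data & keep, seg.nawm_mask.affine)
    return replace(seg, lka_mask=lka, nawm_mask=nawm,
                   lka_volume_cm3=2.0 * lka.volume_cm3,
                   hemisphere_excluded=infarct_side)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap between two masks (1.0 when both are empty)."""
    a.check_same_geometry(b)
    na, nb = a.count, b.count
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
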