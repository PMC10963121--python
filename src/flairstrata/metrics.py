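"""Splenium-normalized intensity metrics and lesion-volume quartiles.

NAWM_M is the mean FLAIR intensity over an NAWM region divided by the
subject's splenium ROI mean; it is dimensionless and invariant under global
intensity scaling of the raw volume.  LKA_V (total leukoaraiosis volume,
cm^3, doubled for single-hemisphere subjects) enters the statistical models
as cohort quartiles, an ordinal 1-4 variable; quartile cut-points use the
nearest-rank percentile definition with ties going to the lower quartile.
Age enters as decades (years / 10) so its coefficient reads as the change
per 10-year increase.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import BinaryMask, Volume
from .strata import StrataSet

__all__ = ["EmptyMaskError", "normalize_to_splenium", "mean_masked_intensity",
           "assign_quartiles", "stratum_table"]

log = logging.getLogger(__name__)

#: column order of the long-format analysis table
TABLE_COLUMNS = ["subject_id", "stratum", "nawm_m", "lka_volume_cm3",
                 "lka_quartile", "age_decades", "hypertension"]


class EmptyMaskError(ValueError):
    """A mean was requested over an empty mask (no observation row)."""


def normalize_to_splenium(flair: Volume, splenium_mean: float) -> Volume:
    """Divide every voxel by the splenium ROI mean intensity."""
    if not splenium_mean > 0:
        raise ValueError(f"splenium mean must be positive, got {splenium_mean}")
    return Volume(flair.data / splenium_mean, flair.affine)


def mean_masked_intensity(volume: Volume, mask: BinaryMask) -> float:
    """Arithmetic mean of the volume over the masked voxels."""
    volume.check_same_geometry(mask)
    if mask.is_empty():
        raise EmptyMaskError("mask is empty; no mean intensity defined")
    return float(volume.data[mask.data].mean())


def assign_quartiles(volumes) -> np.ndarray:
    """Quartile labels 1-4 from nearest-rank 25/50/75th percentile cut-points.

    Values <= Q1 map to 1, <= Q2 to 2, <= Q3 to 3, else 4; ties go low.
    Labels depend only on ranks, so any monotone transform of the volumes
    yields identical labels.
    """
    v = np.asarray(volumes, dtype=float)
    if v.ndim != 1 or v.size < 4:
        raise ValueError("need at least 4 volumes to form quartiles")
    srt = np.sort(v)
    n = v.size
    # nearest-rank percentile: smallest value with cumulative rank >= p*n
    cuts = [srt[int(np.ceil(p * n)) - 1] for p in (0.25, 0.50, 0.75)]
    labels = np.full(n, 4, dtype=int)
    for q, cut in zip((3, 2, 1), reversed(cuts)):
        labels[v <= cut] = q
    if np.all(v == v[0]):
        log.warning("all lesion volumes identical; quartiles degenerate "
                    "(every subject labelled 1)")
    return labels


def stratum_table(subject_id: str, normalized_flair: Volume,
                  strata: StrataSet, lka_volume_cm3: float,
                  age_years: float, hypertension: bool) -> pd.DataFrame:
    """Long-format observation rows for one subject.

    One row per non-empty stratum (stratum column ``1..n``) plus one
    descriptive ``full`` row for the whole NAWM; empty strata emit no row
    (a zero would bias the models).  The cohort-level quartile column is
    filled in later, once all surviving subjects' volumes are known.
    """
    rows = []
    for k, mask in enumerate(strata.strata, start=1):
        if mask.is_empty():
            log.info("subject %s: stratum %d empty, no row emitted",
                     subject_id, k)
            continue
        rows.append({"subject_id": subject_id, "stratum": str(k),
                     "nawm_m": mean_masked_intensity(normalized_flair, mask)})
    if not strata.full_nawm.is_empty():
        rows.append({"subject_id": subject_id, "stratum": "full",
                     "nawm_m": mean_masked_intensity(normalized_flair,
                                                     strata.full_nawm)})
    df = pd.DataFrame(rows)
    df["lka_volume_cm3"] = lka_volume_cm3
    df["lka_quartile"] = np.nan
    df["age_decades"] = age_years / 10.0
    df["hypertension"] = int(hypertension)
    return df[TABLE_COLUMNS]
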