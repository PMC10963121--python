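"""NAWM distance strata around leukoaraiosis borders.

With ``D0`` the LKA mask and ``Dk`` its k-th recursive 2-D 8-connected
dilation, stratum ``k`` is ``(Dk - D(k-1))`` intersected with the NAWM mask:
the NAWM voxels at in-slice Chebyshev distance exactly ``k`` from the
nearest LKA voxel in the same slice.  Dilations never cross slices, which
avoids vertical partial-volume contamination from thick slices.  Strata are
pairwise disjoint by construction; empty strata are retained as empty masks
(downstream metrics emit no observation row for them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask
from .morphology import IN_PLANE_8, dilate, mask_algebra

__all__ = ["StrataSet", "build_strata"]


@dataclass
class StrataSet:
    """Ordered NAWM strata at voxel distances 1..n from LKA borders."""
    strata: list[BinaryMask]
    full_nawm: BinaryMask

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def voxel_counts(self) -> list[int]:
        return [s.count for s in self.strata]

    def label_volume(self) -> np.ndarray:
        """Integer label grid: 0 outside, k = stratum index (1-based)."""
        labels = np.zeros(self.full_nawm.shape, dtype=np.uint8)
        for k, s in enumerate(self.strata, start=1):
            labels[s.data] = k
        return labels


def build_strata(lka: BinaryMask, nawm: BinaryMask,
                 n_strata: int = 5) -> StrataSet:
    """Build the NAWM voxel-distance strata by recursive in-plane dilation."""
    lka.check_same_geometry(nawm)
    if (lka.data & nawm.data).any():
        raise ValueError("LKA and NAWM masks overlap; they must be disjoint")
    strata: list[BinaryMask] = []
    prev = lka
    for _ in range(n_strata):
        cur = dilate(prev, IN_PLANE_8)
        ring = mask_algebra(cur, prev, "difference")
        strata.append(mask_algebra(ring, nawm, "intersection"))
        prev = cur
    return StrataSet(strata=strata, full_nawm=nawm)
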