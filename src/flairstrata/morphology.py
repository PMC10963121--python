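"""Binary-mask morphology with explicit connectivity and border conventions.

Two structuring elements are used by the pipeline:

``in_plane_8``
    the 8 in-slice neighbours (chessboard/Chebyshev connectivity with no
    slice-to-slice component).  Recursive dilation with this element defines
    the voxel-distance strata: n dilations reach exactly the voxels whose
    in-slice Chebyshev distance to the mask is <= n.
``cross_3d_6``
    the 6 face neighbours, used for the conservative white-matter mask
    erosion/dilation.

Border convention: the grid is clipped, never wrapped.  For dilation,
neighbours outside the grid are ignored; for erosion they count as False, so
border voxels always erode away.  This is scipy's ``border_value=0``
behaviour for both operations, and the brute-force oracle in the test suite
shares it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import BinaryMask

__all__ = ["StructuringElement", "IN_PLANE_8", "CROSS_3D_6", "element",
           "dilate", "erode", "mask_algebra"]


@dataclass(frozen=True)
class StructuringElement:
    kind: str
    structure: np.ndarray = field(repr=False, hash=False, compare=False)

    @property
    def offsets(self) -> list[tuple[int, int, int]]:
        """Neighbour offsets excluding the centre voxel."""
        out = []
        for idx in np.argwhere(self.structure):
            off = tuple(int(v) - 1 for v in idx)
            if off != (0, 0, 0):
                out.append(off)
        return out


def _in_plane_8_structure() -> np.ndarray:
    s = np.zeros((3, 3, 3), dtype=bool)
    s[:, :, 1] = True  # full 3x3 within the slice (axis 2 = slices)
    return s


IN_PLANE_8 = StructuringElement("in_plane_8", _in_plane_8_structure())
CROSS_3D_6 = StructuringElement("cross_3d_6",
                                ndimage.generate_binary_structure(3, 1))

_ELEMENTS = {e.kind: e for e in (IN_PLANE_8, CROSS_3D_6)}


def element(kind: str) -> StructuringElement:
    try:
        return _ELEMENTS[kind]
    except KeyError:
        raise ValueError(
            f"unknown structuring element {kind!r}; "
            f"choose from {sorted(_ELEMENTS)}") from None


def dilate(mask: BinaryMask, elem: StructuringElement = IN_PLANE_8,
           iterations: int = 1) -> BinaryMask:
    """Morphological dilation; out-of-grid neighbours are ignored."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    data = mask.data
    if iterations > 0 and data.any():
        data = ndimage.binary_dilation(data, structure=elem.structure,
                                       iterations=iterations)
    return BinaryMask(np.array(data, dtype=bool, copy=True), mask.affine)


def erode(mask: BinaryMask, elem: StructuringElement = CROSS_3D_6,
          iterations: int = 1) -> BinaryMask:
    """Morphological erosion; voxels beyond the border count as False."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    data = mask.data
    if iterations > 0 and data.any():
        data = ndimage.binary_erosion(data, structure=elem.structure,
                                      iterations=iterations, border_value=0)
    return BinaryMask(np.array(data, dtype=bool, copy=True), mask.affine)


def mask_algebra(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Voxelwise set operation between two masks with identical geometry.

    ``op`` is one of ``difference`` (a minus b), ``intersection``, ``union``.
    """
    a.check_same_geometry(b)
    if op == "difference":
        data = a.data & ~b.data
    elif op == "intersection":
        data = a.data & b.data
    elif op == "union":
        data = a.data | b.data
    else:
        raise ValueError(f"unknown op {op!r}; use difference/intersection/union")
    return BinaryMask(data, a.affine)
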