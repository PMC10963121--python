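"""Volumetric containers shared by every stage of the pipeline.

A :class:`Volume` is a dense 3-D scalar grid (FLAIR-like intensities, tissue
probabilities) carrying a 4x4 voxel-to-world affine; a :class:`BinaryMask` is
a boolean grid with identical geometry.  Grids are indexed ``(i, j, k)`` with
``k`` the slice axis; world coordinates are in mm (RAS+).  All masks and
volumes belonging to one subject must share shape and affine, and every
operation that combines two grids checks this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "BinaryMask", "GeometryError", "make_affine"]


class GeometryError(ValueError):
    """Two grids that must share geometry do not."""


def make_affine(voxel_dims_mm: tuple[float, float, float],
                center_index: tuple[float, float, float]) -> np.ndarray:
    """Diagonal RAS+ affine placing world (0,0,0) at ``center_index``."""
    affine = np.eye(4)
    for ax, d in enumerate(voxel_dims_mm):
        affine[ax, ax] = d
        affine[ax, 3] = -d * center_index[ax]
    return affine


def _check_same_geometry(a: "_Grid", b: "_Grid") -> None:
    if a.data.shape != b.data.shape:
        raise GeometryError(
            f"grid shapes differ: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise GeometryError(
            f"affines differ:\n{a.affine}\nvs\n{b.affine}")


@dataclass
class _Grid:
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims_mm(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other: "_Grid") -> bool:
        try:
            _check_same_geometry(self, other)
        except GeometryError:
            return False
        return True

    def check_same_geometry(self, other: "_Grid") -> None:
        _check_same_geometry(self, other)

    def world_coordinates(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre world coordinates in mm."""
        idx = np.indices(self.shape).astype(float)
        hom = np.stack([idx[0], idx[1], idx[2], np.ones(self.shape)], axis=-1)
        return hom @ self.affine.T[:, :3]


@dataclass
class Volume(_Grid):
    """3-D scalar grid with world geometry (intensities in arbitrary units)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(float, copy=False)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine),
                 str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)


@dataclass
class BinaryMask(_Grid):
    """3-D boolean grid sharing a Volume's geometry."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool, copy=False)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        """Mask volume as voxel count x voxel volume (never via meshing)."""
        return self.count * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not self.data.any()

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine),
                 str(path))

    @classmethod
    def load(cls, path: str | Path) -> "BinaryMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0, img.affine)
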