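"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: morphology
is checked against a per-voxel neighbour scan, strata against an in-slice
Chebyshev distance computation, and masked means against explicit loops.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from flairstrata import BinaryMask, PhantomConfig


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Down-scaled phantom for fast unit tests (same structure, smaller grid)."""
    return PhantomConfig(
        grid_shape=(48, 56, 10),
        lesion_radius_range_mm=(1.5, 3.0),
        burden_volume_bands_cm3={1: (0.05, 0.15), 2: (0.25, 0.45),
                                 3: (0.6, 0.9), 4: (1.1, 1.5)},
        seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_mask(rng: np.random.Generator, shape=(16, 16, 8),
                p: float = 0.2) -> BinaryMask:
    return BinaryMask(rng.random(shape) < p)


# --- brute-force morphology oracle (per-voxel neighbour scan) -------------

def bf_dilate(data: np.ndarray, offsets) -> np.ndarray:
    """Per-voxel scan: true if the voxel or any in-grid neighbour is true."""
    out = np.array(data, dtype=bool, copy=True)
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if out[i, j, k]:
                    continue
                for di, dj, dk in offsets:
                    a, b, c = i + di, j + dj, k + dk
                    if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz \
                            and data[a, b, c]:
                        out[i, j, k] = True
                        break
    return out


def bf_erode(data: np.ndarray, offsets) -> np.ndarray:
    """Per-voxel scan: true iff the voxel and all neighbours are true,
    with out-of-grid neighbours counting as false."""
    out = np.zeros_like(data, dtype=bool)
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not data[i, j, k]:
                    continue
                keep = True
                for di, dj, dk in offsets:
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) \
                            or not data[a, b, c]:
                        keep = False
                        break
                out[i, j, k] = keep
    return out


# --- in-slice Chebyshev distance oracle for the strata --------------------

def chebyshev_strata(lka: np.ndarray, nawm: np.ndarray,
                     n_strata: int = 5) -> list[np.ndarray]:
    """Stratum k = NAWM voxels whose minimal in-slice Chebyshev distance to
    an LKA voxel in the same slice equals k."""
    out = [np.zeros_like(nawm, dtype=bool) for _ in range(n_strata)]
    for z in range(lka.shape[2]):
        lk = np.argwhere(lka[:, :, z])
        if len(lk) == 0:
            continue
        nw = np.argwhere(nawm[:, :, z])
        for (i, j) in nw:
            d = np.max(np.abs(lk - np.array([i, j])), axis=1).min()
            if 1 <= d <= n_strata:
                out[d - 1][i, j, z] = True
    return out


def noise_free(config: PhantomConfig, **overrides) -> PhantomConfig:
    """Noise-free variant of a phantom config (anatomy unchanged)."""
    return dataclasses.replace(config, noise_sd=0.0, **overrides)
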