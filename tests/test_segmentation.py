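"""Segmentation: WM masking, LKA thresholding, NAWM, hemisphere exclusion."""

import dataclasses

import numpy as np
import pytest

from flairstrata import (CROSS_3D_6, BinaryMask, CalibrationThresholds,
                         RunConfig, Volume, apply_hemisphere_exclusion,
                         build_nawm, dice, generate_subject,
                         hemisphere_labels, run_subject, segment_lka,
                         wm_mask_from_probability)
from flairstrata.grids import make_affine
from flairstrata.segmentation import SegmentationResult

from conftest import bf_dilate, bf_erode, noise_free


def _thr(mean=100.0, sd=5.0, csf=60.0):
    return CalibrationThresholds(splenium_mean=mean, splenium_sd=sd,
                                 lka_threshold=mean + 6 * sd, csf_max=csf)


def test_wm_probability_threshold_is_inclusive():
    data = np.zeros((3, 1, 1))
    data[:, 0, 0] = [0.94, 0.95, 0.96]
    mask = Volume(data).data >= 0.95
    assert mask.tolist() == [[[False]], [[True]], [[True]]]


def test_wm_morphology_cube_erode_twice_dilate_once():
    """7^3 probability-1 cube: two 6-connected erosions leave a 3^3 cube;
    the single dilation grows each face but not the corners, so the result
    sits strictly between the 3^3 and 5^3 cubes (81 voxels) and matches the
    brute-force per-voxel oracle exactly."""
    prob = np.zeros((11, 11, 11))
    prob[2:9, 2:9, 2:9] = 1.0
    wm = wm_mask_from_probability(Volume(prob))
    offs = CROSS_3D_6.offsets
    bf = bf_dilate(bf_erode(bf_erode(prob >= 0.95, offs), offs), offs)
    assert np.array_equal(wm.data, bf)
    inner = np.zeros((11, 11, 11), dtype=bool)
    inner[4:7, 4:7, 4:7] = True
    outer = np.zeros((11, 11, 11), dtype=bool)
    outer[3:8, 3:8, 3:8] = True
    assert (inner <= wm.data).all() and (wm.data <= outer).all()
    assert wm.count == 27 + 6 * 9


def test_empty_probability_map_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="empty"):
        wm = wm_mask_from_probability(Volume(np.zeros((6, 6, 4))))
    assert wm.is_empty()


def test_probability_values_validated():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        wm_mask_from_probability(Volume(np.full((3, 3, 3), 1.5)))


def test_segment_lka_brute_force_filter():
    flair = Volume(np.array([[[10.0], [120.0], [135.0], [50.0]],
                             [[130.0], [129.9], [140.0], [200.0]],
                             [[131.0], [60.0], [130.0], [135.0]],
                             [[0.0], [250.0], [131.0], [129.0]]]))
    outline = BinaryMask(np.ones((4, 4, 1), dtype=bool))
    outline.data[3, 1, 0] = False  # the 250 voxel is outside the outline
    thr = _thr(100, 5, 60)  # lka threshold 130
    lka = segment_lka(flair, outline, thr)
    expected = np.zeros((4, 4, 1), dtype=bool)
    for i in range(4):
        for j in range(4):
            expected[i, j, 0] = (outline.data[i, j, 0]
                                 and flair.data[i, j, 0] >= 130.0
                                 and flair.data[i, j, 0] >= 60.0)
    assert np.array_equal(lka.data, expected)
    assert lka.data[1, 0, 0] and lka.data[0, 2, 0]       # 130/135 inclusive
    assert not lka.data[1, 1, 0] and not lka.data[3, 1, 0]


def test_segment_lka_empty_outline_is_valid():
    flair = Volume(np.full((4, 4, 2), 500.0))
    empty = BinaryMask(np.zeros((4, 4, 2), dtype=bool))
    assert segment_lka(flair, empty, _thr()).is_empty()


def test_build_nawm_set_algebra(rng):
    shape = (10, 10, 4)
    flair = Volume(rng.uniform(0, 200, shape))
    wm = BinaryMask(rng.random(shape) < 0.5)
    lka = BinaryMask(rng.random(shape) < 0.2)
    thr = _thr(100, 5, 60)
    nawm = build_nawm(wm, lka, flair, thr)
    expected = wm.data & ~lka.data & (flair.data >= 60.0)
    assert np.array_equal(nawm.data, expected)
    # degenerate cases
    empty = BinaryMask(np.zeros(shape, dtype=bool))
    assert np.array_equal(build_nawm(wm, empty, flair, thr).data,
                          wm.data & (flair.data >= 60.0))
    assert build_nawm(wm, wm, flair, thr).is_empty()


def _seg_with_lka(lka_data, affine):
    lka = BinaryMask(lka_data, affine)
    empty = BinaryMask(np.zeros_like(lka_data, dtype=bool), affine)
    return SegmentationResult(lka_mask=lka, wm_mask=empty, nawm_mask=empty,
                              lka_volume_cm3=0.0, hemisphere_excluded="none",
                              thresholds=_thr())


def test_volume_without_hemisphere_exclusion():
    affine = make_affine((0.75, 0.75, 3.5), (10, 10, 2))
    data = np.zeros((20, 20, 4), dtype=bool)
    data.reshape(-1)[:1000] = True
    seg = apply_hemisphere_exclusion(_seg_with_lka(data, affine), None, "none")
    assert seg.lka_volume_cm3 == pytest.approx(1000 * 0.75 * 0.75 * 3.5 / 1000)


def test_volume_doubling_with_right_infarct():
    affine = make_affine((0.75, 0.75, 3.5), (10, 10, 2))
    data = np.zeros((20, 20, 4), dtype=bool)
    data[:10, :, :] = False
    data[0:5, 0:10, 0:2] = True          # 100 voxels, x<0 (left hemisphere)
    assert data.sum() == 100
    seg = apply_hemisphere_exclusion(_seg_with_lka(data, affine), None,
                                     "right")
    assert seg.hemisphere_excluded == "right"
    assert seg.lka_volume_cm3 == pytest.approx(
        2 * 100 * 0.75 * 0.75 * 3.5 / 1000)
    assert seg.lka_mask.count == 100


def test_mirrored_lesions_double_to_bilateral_volume():
    """For hemisphere-symmetric lesions, doubling the single-hemisphere
    volume recovers the bilateral volume up to the midline column."""
    affine = make_affine((0.75, 0.75, 3.5), (10, 10, 2))
    data = np.zeros((20, 20, 4), dtype=bool)
    data[6:9, 5:9, 1:3] = True
    mirrored = np.zeros_like(data)
    mirrored[1:] = data[:0:-1]
    both = data | mirrored
    bilateral = apply_hemisphere_exclusion(
        _seg_with_lka(both, affine), None, "none").lka_volume_cm3
    single = apply_hemisphere_exclusion(
        _seg_with_lka(both, affine), None, "left").lka_volume_cm3
    voxel_cm3 = 0.75 * 0.75 * 3.5 / 1000
    assert abs(single - bilateral) <= voxel_cm3 + 1e-12


def test_unknown_infarct_side_rejected():
    affine = make_affine((0.75, 0.75, 3.5), (2, 2, 1))
    seg = _seg_with_lka(np.zeros((4, 4, 2), dtype=bool), affine)
    with pytest.raises(ValueError, match="unknown infarct side"):
        apply_hemisphere_exclusion(seg, None, "both")


def test_hemisphere_labels_midline_excluded():
    affine = make_affine((0.75, 0.75, 3.5), (2, 0, 0))
    vol = Volume(np.zeros((5, 2, 2)), affine)
    labels = hemisphere_labels(vol)
    assert (labels[0:2] == -1).all() and (labels[3:5] == 1).all()
    assert (labels[2] == 0).all()  # exact midline belongs to neither side


def test_pipeline_invariants_on_phantom(small_config):
    cfg = dataclasses.replace(small_config, seed=5)
    for seed, level in [(0, 2), (1, 4)]:
        b = generate_subject(cfg, seed, level)
        r = run_subject(b, RunConfig(seed=3), seed)
        assert not r.excluded
        seg = r.seg
        assert not (seg.lka_mask.data & seg.nawm_mask.data).any()
        assert (seg.nawm_mask.data <= seg.wm_mask.data).all()
        for m in (seg.lka_mask, seg.nawm_mask):
            assert (b.flair.data[m.data] >= seg.thresholds.csf_max).all()
        if seg.hemisphere_excluded != "none":
            label = 1 if seg.hemisphere_excluded == "right" else -1
            side = b.hemisphere_map == label
            assert not (seg.lka_mask.data & side).any()
            assert not (seg.nawm_mask.data & side).any()


def test_noise_free_recovery_small_phantom(small_config):
    cfg = noise_free(small_config, infarct_side_probs=(1.0, 0.0, 0.0))
    b = generate_subject(cfg, 2, 3)
    r = run_subject(b, RunConfig(seed=1), 2)
    assert dice(r.seg.lka_mask, b.truth_lesion_mask) == 1.0


def test_scale_invariance_of_masks(small_config):
    """Multiplying the FLAIR volume by c > 0 leaves every mask unchanged
    because all thresholds are derived from the same image."""
    b = generate_subject(small_config, 4, 3)
    r1 = run_subject(b, RunConfig(seed=9), 4)
    for c in (0.5, 3.7):
        b2 = dataclasses.replace(b, flair=Volume(b.flair.data * c,
                                                 b.flair.affine))
        r2 = run_subject(b2, RunConfig(seed=9), 4)
        assert np.array_equal(r1.seg.lka_mask.data, r2.seg.lka_mask.data)
        assert np.array_equal(r1.seg.nawm_mask.data, r2.seg.nawm_mask.data)
        assert r2.seg.thresholds.lka_threshold == pytest.approx(
            c * r1.seg.thresholds.lka_threshold, rel=1e-9)
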