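"""Landmark affine solve, resampling, ROI transfer, intensity registration."""

from __future__ import annotations

import numpy as np
import pytest

from radpathcorr import registration as reg
from radpathcorr.types import AffineTransform2D, LandmarkSet, MRVolume, ROISpec


def _random_affine(rng, scale=1.0):
    A = np.eye(2) * scale + rng.normal(0, 0.1, size=(2, 2))
    t = rng.normal(0, 10, size=2)
    return AffineTransform2D(A, t)


# ---------------------------------------------------------------------------
# landmark affine
# ---------------------------------------------------------------------------

def test_exact_four_point_recovery(rng):
    for _ in range(20):
        truth = _random_affine(rng, scale=30.0)
        src = LandmarkSet(rng.uniform(0, 80, size=(4, 2)))
        dst = LandmarkSet(truth.apply(src.points))
        res = reg.fit_landmark_affine(src, dst)
        np.testing.assert_allclose(res.transform.matrix, truth.matrix,
                                   atol=1e-9)
        np.testing.assert_allclose(res.transform.translation,
                                   truth.translation, atol=1e-9)
        assert np.all(res.residuals < 1e-9)


def test_three_noncollinear_pairs_zero_residual(rng):
    src = LandmarkSet([[0.0, 0.0], [10.0, 2.0], [3.0, 12.0]])
    dst = LandmarkSet(rng.uniform(0, 50, size=(3, 2)))
    res = reg.fit_landmark_affine(src, dst)
    assert np.all(res.residuals < 1e-9)
    np.testing.assert_allclose(res.transform.apply(src.points), dst.points,
                               atol=1e-9)


def test_matches_normal_equations_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(4, 9))
        src = LandmarkSet(rng.uniform(0, 100, size=(n, 2)))
        dst = LandmarkSet(rng.uniform(0, 100, size=(n, 2)))
        res = reg.fit_landmark_affine(src, dst)
        M = np.column_stack([src.points, np.ones(n)])
        coef = np.linalg.solve(M.T @ M, M.T @ dst.points)
        np.testing.assert_allclose(res.transform.matrix, coef[:2].T,
                                   atol=1e-8)
        np.testing.assert_allclose(res.transform.translation, coef[2],
                                   atol=1e-8)


def test_consistent_extra_landmark_changes_nothing(rng):
    truth = _random_affine(rng)
    pts = rng.uniform(0, 50, size=(4, 2))
    res4 = reg.fit_landmark_affine(LandmarkSet(pts),
                                   LandmarkSet(truth.apply(pts)))
    pts5 = np.vstack([pts, rng.uniform(0, 50, size=(1, 2))])
    res5 = reg.fit_landmark_affine(LandmarkSet(pts5),
                                   LandmarkSet(truth.apply(pts5)))
    np.testing.assert_allclose(res5.transform.matrix, res4.transform.matrix,
                               atol=1e-9)
    np.testing.assert_allclose(res5.transform.translation,
                               res4.transform.translation, atol=1e-9)


def test_collinear_sources_rejected():
    src = LandmarkSet([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    dst = LandmarkSet([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
    with pytest.raises(ValueError, match="collinear"):
        reg.fit_landmark_affine(src, dst)


def test_unpaired_sets_rejected():
    with pytest.raises(ValueError, match="differ in length"):
        reg.fit_landmark_affine(LandmarkSet(np.zeros((4, 2))),
                                LandmarkSet(np.zeros((3, 2))))


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        reg.fit_landmark_affine(LandmarkSet([[0.0, 0], [1, 1]]),
                                LandmarkSet([[0.0, 0], [1, 1]]))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_apply_transform_identity(rng):
    img = rng.normal(size=(20, 25))
    out = reg.apply_transform(img, AffineTransform2D.identity(), img.shape)
    np.testing.assert_allclose(out, img, atol=1e-12)


def test_apply_transform_integer_shift(rng):
    img = rng.normal(size=(20, 20))
    t = AffineTransform2D(np.eye(2), [3.0, -2.0])  # src -> target
    out = reg.apply_transform(img, t, (20, 20))
    # target pixel (i, j) samples source (i - 3, j + 2)
    np.testing.assert_allclose(out[3:, :18], img[:17, 2:], atol=1e-12)
    assert np.all(np.isnan(out[:3, :]))  # out-of-domain rows


def test_apply_transform_rejects_unknown_interpolation():
    with pytest.raises(ValueError, match="interpolation"):
        reg.apply_transform(np.zeros((4, 4)), AffineTransform2D.identity(),
                            (4, 4), interpolation="cubic")


def test_affine_index_to_physical_pure_scaling():
    t = AffineTransform2D.scaling(40.0)  # e.g. MD px -> hist px at 40x
    phys = reg.affine_index_to_physical(t, src_pixel_size=200.0,
                                        dst_pixel_size=5.0)
    np.testing.assert_allclose(phys.matrix, np.eye(2), atol=1e-12)
    # centre-of-pixel convention: index i at (i + 0.5) * pixel size
    src_pt = np.array([[2.0, 3.0]])
    expected = (t.apply(src_pt) + 0.5) * 5.0
    got = phys.apply((src_pt + 0.5) * 200.0)
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_crop_to_tissue_offset_and_nan():
    values = np.arange(36, dtype=float).reshape(6, 6)
    mask = np.zeros((6, 6), dtype=bool)
    mask[2:5, 1:4] = True
    mask[3, 2] = False
    cropped, offset = reg.crop_to_tissue(values, mask)
    assert offset == (2, 1)
    assert cropped.shape == (3, 3)
    assert np.isnan(cropped[1, 1])
    assert cropped[0, 0] == values[2, 1]


def test_crop_to_tissue_empty_mask():
    with pytest.raises(ValueError, match="empty"):
        reg.crop_to_tissue(np.zeros((4, 4)), np.zeros((4, 4), bool))


def test_transfer_roi_area_scales_with_determinant():
    roi = ROISpec(anchor=(100.0, 200.0), height=50.0, width=80.0, label="#1")
    t = AffineTransform2D([[2.0, 0.0], [0.0, 3.0]], [10.0, -5.0])
    out = reg.transfer_roi(roi, t)
    assert out.area == pytest.approx(roi.area * abs(np.linalg.det(t.matrix)))
    assert out.label == "#1"


def test_transfer_roi_fully_outside_rejected():
    roi = ROISpec(anchor=(0.0, 0.0), height=10.0, width=10.0, label="x")
    t = AffineTransform2D(np.eye(2), [-1000.0, -1000.0])
    with pytest.raises(ValueError, match="outside"):
        reg.transfer_roi(roi, t, target_bounds=(500.0, 500.0))


# ---------------------------------------------------------------------------
# intensity-driven affine registration (phantom volumes)
# ---------------------------------------------------------------------------

def test_self_registration_is_near_identity(weighted0):
    t2w = weighted0["T2w"]
    res = reg.register_affine_intensity(t2w, t2w)
    assert res.success
    A = np.asarray(res.transform["matrix"])
    t = np.asarray(res.transform["translation"])
    # in-plane part is identity to high accuracy; the through-plane scale is
    # not identifiable from a 3-slice slab and is deliberately not asserted
    np.testing.assert_allclose(A[:2, :2], np.eye(2), atol=0.01)
    # 0.05 px at 0.1 mm pixels = 5 um
    assert np.all(np.abs(t[:2]) < 0.05 * t2w.spacing[0])


def test_cross_contrast_shift_recovered(weighted0):
    """T1w shifted by (3, 2, 0) voxels re-aligns to within 0.2 voxel."""
    from scipy import ndimage

    t1w, t2w = weighted0["T1w"], weighted0["T2w"]
    shifted = MRVolume(
        ndimage.shift(t1w.voxels, (3.0, 2.0, 0.0), order=1, mode="nearest"),
        t1w.spacing, contrast_label="T1w",
    )
    res = reg.register_affine_intensity(shifted, t2w)
    assert res.success
    # the recovered fixed->moving map should displace by ~ +(3, 2, 0) voxels
    t = np.asarray(res.transform["translation"])
    shift_vox = t / np.asarray(t1w.spacing)
    np.testing.assert_allclose(shift_vox[:2], [3.0, 2.0], atol=0.2)
    # and the resampled volume should match the unshifted T1w interior
    core = (slice(15, -15), slice(15, -15), slice(None))
    r = np.corrcoef(res.resampled.voxels[core].ravel(),
                    t1w.voxels[core].ravel())[0, 1]
    assert r > 0.95


def test_disjoint_fov_returns_identity_failure(weighted0):
    t2w = weighted0["T2w"]
    far = MRVolume(t2w.voxels, t2w.spacing, origin=(1000.0, 1000.0, 0.0),
                   contrast_label="T1w")
    res = reg.register_affine_intensity(far, t2w)
    assert not res.success
    np.testing.assert_array_equal(res.transform["matrix"], np.eye(3))


def test_unknown_metric_rejected(weighted0):
    t2w = weighted0["T2w"]
    with pytest.raises(ValueError, match="metric"):
        reg.register_affine_intensity(t2w, t2w, metric="ncc")
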