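"""Spatial alignment: contrast-to-contrast, MD-map-to-histology, ROI transfer.

The weighted contrasts (T1w, T2*w) are aligned to the T2w reference by an
intensity-driven affine registration with a mutual-information criterion
(contrasts differ, so a cross-modal metric is needed).  The MD map is mapped
onto the digital histology template by a landmark-based 2-D affine solved in
closed form from paired fiducial points (least squares on the Euclidean
distances).  Transforms can then be applied to maps and rectangular ROIs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .types import (
    AffineTransform2D,
    LandmarkSet,
    MRVolume,
    RegistrationResult,
    ROISpec,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# intensity-driven 3-D affine registration (cross-contrast)
# ---------------------------------------------------------------------------

def _to_sitk(vol: MRVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(vol.voxels, (2, 1, 0)), dtype=np.float64)
    )
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(vol.origin, vol.spacing)))
    return img


def _overlapping_fov(moving: MRVolume, fixed: MRVolume) -> bool:
    mb, fb = moving.physical_extent(), fixed.physical_extent()
    return bool(np.all(mb[0] < fb[1]) and np.all(fb[0] < mb[1]))


def register_affine_intensity(
    moving: MRVolume,
    fixed: MRVolume,
    metric: str = "mattes",
    n_bins: int = 32,
) -> RegistrationResult:
    """Affine registration of one contrast onto another.

    Uses Mattes mutual information (default) or mean squares, dense sampling
    for determinism, and gradient-descent optimisation.  On failure (or
    disjoint fields of view) the identity is returned with ``success=False``.
    The resampled moving image on the fixed grid is attached to the result.
    """
    if moving.voxels.ndim != fixed.voxels.ndim:
        raise ValueError("moving and fixed volumes must share dimensionality")
    if not _overlapping_fov(moving, fixed):
        return RegistrationResult(
            transform={"matrix": np.eye(3).tolist(),
                       "translation": [0.0, 0.0, 0.0]},
            success=False,
            resampled=moving,
        )
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    if metric == "mattes":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=n_bins)
    elif metric == "meansquares":
        reg.SetMetricAsMeanSquares()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    reg.SetInterpolator(sitk.sitkLinear)
    # central differences instead of the recursive Gaussian gradient filter,
    # which needs >= 4 samples along every axis (thin slabs have 3 slices)
    reg.MetricUseFixedImageGradientFilterOff()
    reg.MetricUseMovingImageGradientFilterOff()
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(initial, inPlace=False)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.5, minStep=1e-7, numberOfIterations=300,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    try:
        final = reg.Execute(f_img, m_img)
        metric_value = float(reg.GetMetricValue())
        iters = int(reg.GetOptimizerIteration())
    except RuntimeError as exc:
        logger.warning("affine registration diverged: %s", exc)
        return RegistrationResult(
            transform={"matrix": np.eye(3).tolist(),
                       "translation": [0.0, 0.0, 0.0]},
            success=False,
            resampled=moving,
        )
    resampled = sitk.Resample(
        m_img, f_img, final, sitk.sitkLinear, 0.0, sitk.sitkFloat64
    )
    arr = np.transpose(sitk.GetArrayFromImage(resampled), (2, 1, 0))
    aff = sitk.AffineTransform(sitk.CompositeTransform(final).GetNthTransform(0))
    A = np.asarray(aff.GetMatrix()).reshape(3, 3)
    c = np.asarray(aff.GetCenter())
    t = np.asarray(aff.GetTranslation())
    t_eff = t + c - A @ c  # fixed -> moving physical map, centre folded in
    return RegistrationResult(
        transform={"matrix": A.tolist(), "translation": t_eff.tolist(),
                   "direction": "fixed_to_moving_physical"},
        similarity=metric_value,
        iterations=iters,
        success=True,
        resampled=MRVolume(
            voxels=arr, spacing=fixed.spacing, origin=fixed.origin,
            contrast_label=moving.contrast_label,
        ),
    )


# ---------------------------------------------------------------------------
# landmark-based 2-D affine
# ---------------------------------------------------------------------------

def fit_landmark_affine(src: LandmarkSet, dst: LandmarkSet) -> RegistrationResult:
    """Closed-form least-squares 2-D affine from paired fiducial points.

    Minimises the sum of squared Euclidean distances between the transformed
    source landmarks and the destination landmarks (6 unknowns).  With three
    non-collinear pairs the system is exactly determined and residuals are
    zero; four or more pairs give the least-squares solution with
    per-landmark residual distances reported.
    """
    if len(src) != len(dst):
        raise ValueError(
            f"landmark sets differ in length ({len(src)} vs {len(dst)})"
        )
    if len(src) < 3:
        raise ValueError("at least 3 landmark pairs are needed for an affine")
    P = src.points
    Q = dst.points
    centered = P - P.mean(axis=0)
    # collinear sources leave the 6-unknown system rank-deficient
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(P).max())) < 2:
        raise ValueError("source landmarks are collinear; affine is singular")
    M = np.column_stack([P, np.ones(len(src))])  # n x 3
    coef, *_ = np.linalg.lstsq(M, Q, rcond=None)  # 3 x 2
    A = coef[:2].T
    t = coef[2]
    transform = AffineTransform2D(A, t)
    residuals = np.linalg.norm(transform.apply(P) - Q, axis=1)
    return RegistrationResult(
        transform=transform,
        similarity=float(np.sum(residuals**2)),
        residuals=residuals,
        iterations=0,
        success=True,
    )


# ---------------------------------------------------------------------------
# resampling and cropping
# ---------------------------------------------------------------------------

def apply_transform(
    image: np.ndarray,
    t: AffineTransform2D,
    output_shape: tuple[int, int],
    interpolation: str = "linear",
) -> np.ndarray:
    """Resample a 2-D map through an affine onto a target grid.

    ``t`` maps source pixel coordinates to target pixel coordinates; the
    output is sampled via the inverse mapping.  Out-of-domain pixels carry
    NaN.  ``nearest`` interpolation never invents values at missing-data
    boundaries; ``linear`` is for intensity images.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    image = np.asarray(image, dtype=float)
    inv = t.inverse()  # raises if singular
    r, c = np.meshgrid(
        np.arange(output_shape[0], dtype=float),
        np.arange(output_shape[1], dtype=float),
        indexing="ij",
    )
    # pixel coordinates are array-index coordinates (centre of pixel i at i)
    pts = inv.apply(np.column_stack([r.ravel(), c.ravel()]))
    coords = pts.T.reshape(2, *output_shape)
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        image, coords, order=order, mode="constant", cval=np.nan
    )
    return out


def affine_index_to_physical(
    t: AffineTransform2D, src_pixel_size: float, dst_pixel_size: float
) -> AffineTransform2D:
    """Convert a pixel-index affine into physical (micrometre) units.

    Index coordinate i corresponds to the physical position of the pixel
    centre, (i + 0.5) * pixel_size, in the corner-origin physical frame.
    """
    A, tr = t.matrix, t.translation
    half = np.array([0.5, 0.5])
    matrix = (dst_pixel_size / src_pixel_size) * A
    translation = dst_pixel_size * (tr + half - A @ half)
    return AffineTransform2D(matrix, translation)


def crop_to_tissue(values: np.ndarray, mask: np.ndarray
                   ) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop a map to the bounding box of a tissue mask.

    Values outside the mask become NaN; the returned offset is the bounding
    box's low corner, so coordinates remain convertible to the uncropped
    frame (uncropped index = cropped index + offset).
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape must match the map")
    if not mask.any():
        raise ValueError("tissue mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    cropped = np.where(mask, values, np.nan)[r0:r1, c0:c1]
    return cropped, (int(r0), int(c0))


def transfer_roi(roi: ROISpec, t: AffineTransform2D,
                 target_bounds: tuple[float, float] | None = None,
                 target_frame: str = "") -> ROISpec:
    """Map a rectangular ROI into another image frame.

    The four corners are pushed through the affine and the transferred ROI
    is their axis-aligned bounding box (recorded as such via the frame
    label); for axis-aligned transforms the area change equals
    ``|det(linear part)|`` exactly.  ``target_bounds`` (physical units of the
    target frame) enables the fully-outside check.
    """
    mapped = t.apply(roi.corners())
    lo = mapped.min(axis=0)
    hi = mapped.max(axis=0)
    if target_bounds is not None:
        if hi[0] <= 0 or hi[1] <= 0 or lo[0] >= target_bounds[0] \
                or lo[1] >= target_bounds[1]:
            raise ValueError(
                f"ROI {roi.label!r} falls fully outside the target frame"
            )
    return ROISpec(
        anchor=(lo[0], lo[1]),
        height=hi[0] - lo[0],
        width=hi[1] - lo[1],
        label=roi.label,
        image_frame=target_frame or f"{roi.image_frame}->transferred",
    )
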