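"""End-to-end orchestration: simulate -> register -> fit -> correlate.

Each stage reads and writes a conventional workspace layout so the CLI
subcommands can be run individually or all at once; a fixed seed makes the
whole run reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage

from . import cellularity as cell
from . import dti, io, registration
from . import phantom as ph
from . import roistats as rs
from .types import AffineTransform2D, LandmarkSet, MRVolume, ROISpec

logger = logging.getLogger(__name__)

CONTRASTS = ("T1w", "T2w", "T2star")

# landmark objects: one fiducial per tissue piece and per marker
LANDMARK_OBJECTS = (
    ("tissueA", ("tissueA_rim", "tissueA_core")),
    ("tissueB", ("tissueB", "tissueB_hemosiderin")),
    ("marker1", ("marker1",)),
    ("marker2", ("marker2",)),
)


def make_spec(seed: int, config: dict | None = None) -> ph.PhantomSpec:
    """Phantom spec at the default study conditions, with optional overrides."""
    kwargs = dict(config or {})
    kwargs["seed"] = int(seed)
    return ph.PhantomSpec(**kwargs)


def default_rois() -> list[ROISpec]:
    """The study's ROI layout on the phantom, in weighted-image um coords.

    #1 rim of tissue A, #2 calcified core, #3 straddling the rim/core
    boundary (mixed), #4 tissue B, BV blood vessel, CTRL agarose reference,
    #4a / #4b low- and high-hemosiderin sub-regions of tissue B.
    """

    def centered(label: str, c0_mm: float, c1_mm: float, size_mm: float
                 ) -> ROISpec:
        h = size_mm * 1000.0
        return ROISpec(
            anchor=(c0_mm * 1000.0 - h / 2, c1_mm * 1000.0 - h / 2),
            height=h, width=h, label=label, image_frame="T2w",
        )

    return [
        centered("#1", 5.2, 7.2, 0.5),
        centered("#2", 5.2, 5.2, 0.5),
        centered("#3", 5.2, 3.8, 0.5),
        centered("#4", 10.4, 9.0, 1.6),
        centered("BV", 11.4, 4.6, 0.5),
        centered("CTRL", 8.0, 2.2, 1.0),
        centered("#4a", 11.0, 8.4, 0.4),
        centered("#4b", 9.6, 8.2, 0.4),
    ]


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------

def _object_centroid(label_img: np.ndarray, indices: list[int]) -> np.ndarray:
    mask = np.isin(label_img, indices)
    if not mask.any():
        raise ValueError("landmark object absent from label image")
    return np.asarray(ndimage.center_of_mass(mask))


def landmarks_from_labels(spec: ph.PhantomSpec, label_fine: np.ndarray,
                          label_hist: np.ndarray
                          ) -> tuple[LandmarkSet, LandmarkSet]:
    """Fiducial centroids of the two tissues and two markers on both frames.

    The point within each object is its centroid (a convention; any
    reproducible interior point works for the affine solve).  Source
    centroids are measured on the fine weighted-image grid - where fiducials
    are actually legible - and expressed in MD-map pixel coordinates through
    the shared physical frame; the coarse MD raster aliases the letter
    marker by up to a pixel.
    """
    s_fine = spec.spacing_weighted[0]
    s_md = spec.spacing_dwi[0]
    src_pts, dst_pts = [], []
    for _, labels in LANDMARK_OBJECTS:
        idx = [spec.label_index(lab) for lab in labels]
        c_fine = _object_centroid(label_fine, idx)
        src_pts.append((c_fine + 0.5) * s_fine / s_md - 0.5)
        dst_pts.append(_object_centroid(label_hist, idx))
    return (
        LandmarkSet(np.asarray(src_pts), frame="MD"),
        LandmarkSet(np.asarray(dst_pts), frame="histology"),
    )


def stage_simulate(out_dir: Path, spec: ph.PhantomSpec) -> dict:
    """Generate and write the complete synthetic fixture directory."""
    fx = Path(out_dir) / "fixture"
    fx.mkdir(parents=True, exist_ok=True)

    gt = ph.build_phantom(spec)
    weighted = ph.render_weighted_images(gt)
    table = ph.default_gradient_table(spec.bval)
    frames = ph.simulate_dwi(gt, table)
    images, true_counts, hist_labels = ph.render_histology(gt)

    for contrast, vol in weighted.items():
        io.write_mr_volume(vol, fx / f"{contrast.lower()}.nii")
    for i, frame in enumerate(frames):
        io.write_mr_volume(frame, fx / f"dwi_{i:02d}.nii")
    io.write_gradient_table(table, fx / "gradients.txt")
    for img in images:
        io.write_histology_image(img, fx / f"histology_level_{img.level_index:02d}.tiff")

    mid = spec.shape_dwi[2] // 2
    label_md = gt.label_dwi[:, :, mid]
    label_fine = gt.label_weighted[:, :, spec.shape_weighted[2] // 2]
    src, dst = landmarks_from_labels(spec, label_fine, hist_labels)
    io.write_landmarks(src, dst, fx / "landmarks.json")

    tissue_idx = [spec.label_index(l) for l in ph.TISSUE_LABELS]
    b_idx = [spec.label_index(l) for l in ("tissueB", "tissueB_hemosiderin")]
    iio.imwrite(fx / "hist_tissueB_mask.png",
                (np.isin(hist_labels, b_idx) * 255).astype(np.uint8))
    iio.imwrite(fx / "md_tissue_mask.png",
                (np.isin(label_md, tissue_idx) * 255).astype(np.uint8))

    gt_doc = {
        "shrinkage": spec.shrinkage,
        "hist_pixel_size_um": spec.hist_pixel_size_um,
        "hist_levels": list(spec.hist_levels),
        "n_intervals": spec.n_intervals,
        "affine_md_px_to_hist_px": {
            "matrix": gt.affine_md_px_to_hist_px.matrix.tolist(),
            "translation": gt.affine_md_px_to_hist_px.translation.tolist(),
        },
        "compartments": [
            {
                "label": c.label,
                "true_md_mm2_s": c.true_md(),
                "nucleus_density_per_tile": (
                    c.nucleus_density
                    if c.nucleus_density is not None
                    else float(spec.expected_density(c.true_md()))
                ),
            }
            for c in spec.compartments
        ],
        "true_tile_counts_per_level": true_counts.sum(axis=(1, 2)).tolist(),
    }
    with open(fx / "ground_truth.json", "w") as fh:
        json.dump(gt_doc, fh, indent=1)
    return {
        "gt": gt, "weighted": weighted, "table": table, "frames": frames,
        "hist_images": images, "hist_labels": hist_labels,
        "true_counts": true_counts, "landmarks": (src, dst), "dir": fx,
    }


# ---------------------------------------------------------------------------
# stage: contrast registration
# ---------------------------------------------------------------------------

def stage_register_contrasts(out_dir: Path, weighted: dict[str, MRVolume]
                             ) -> dict[str, MRVolume]:
    """Align T1w and T2*w onto the T2w reference; write resampled volumes."""
    reg_dir = Path(out_dir) / "registered"
    reg_dir.mkdir(parents=True, exist_ok=True)
    fixed = weighted["T2w"]
    io.write_mr_volume(fixed, reg_dir / "t2w.nii")
    aligned = {"T2w": fixed}
    transforms = {}
    for contrast in ("T1w", "T2star"):
        res = registration.register_affine_intensity(weighted[contrast], fixed)
        aligned[contrast] = res.resampled
        transforms[contrast] = {
            "transform": res.transform,
            "similarity": res.similarity,
            "iterations": res.iterations,
            "success": res.success,
        }
        io.write_mr_volume(res.resampled,
                           reg_dir / f"{contrast.lower()}_on_t2w.nii")
    with open(reg_dir / "transforms.json", "w") as fh:
        json.dump(transforms, fh, indent=1)
    return aligned


# ---------------------------------------------------------------------------
# stage: DTI fit
# ---------------------------------------------------------------------------

def background_corner_mask(shape: tuple[int, int, int],
                           margin: int = 10) -> np.ndarray:
    """Corner boxes of the FOV, used as the signal-free background region."""
    m = np.zeros(shape, dtype=bool)
    m[:margin, :margin, :] = True
    m[:margin, -margin:, :] = True
    m[-margin:, :margin, :] = True
    m[-margin:, -margin:, :] = True
    return m


def stage_fit_dti(out_dir: Path, frames: list[MRVolume],
                  table: ph.GradientTable) -> dti.ScalarMap:
    """Rigid-align the series, estimate sigma, fit tensors, derive MD."""
    dti_dir = Path(out_dir) / "dti"
    dti_dir.mkdir(parents=True, exist_ok=True)

    aligned, rigid_results = dti.register_dwi_to_b0(frames, table)
    b0 = aligned[int(np.flatnonzero(table.bvals == 0)[0])]
    # the FOV corners lie outside the specimen container (air), so the b0
    # magnitude there is pure Rician noise floor -> Rayleigh-corrected sigma
    corners = background_corner_mask(b0.voxels.shape)
    sigma = dti.estimate_noise_sigma(b0.voxels, corners)
    fit_mask = b0.voxels > 4.0 * sigma
    tmap = dti.fit_tensor_map(aligned, table, sigma, mask=fit_mask)
    tmap = dti.enforce_positive_definite_map(tmap, aligned, table, sigma)
    md = dti.compute_md(tmap)

    spacing = frames[0].spacing
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(tmap.tensors, affine), dti_dir / "tensors.nii")
    nib.save(nib.Nifti1Image(tmap.flags.astype(np.int16), affine),
             dti_dir / "fit_flags.nii")
    io.write_mr_volume(
        MRVolume(np.nan_to_num(md.values, nan=-1.0), spacing,
                 contrast_label="MD"),
        dti_dir / "md.nii",
    )
    io.write_rigid_3d([r.transform for r in rigid_results],
                      dti_dir / "rigid_transforms.json")
    with open(dti_dir / "noise.json", "w") as fh:
        json.dump({"sigma": sigma,
                   "registration_success": [bool(r.success)
                                            for r in rigid_results]}, fh,
                  indent=1)
    return md


# ---------------------------------------------------------------------------
# stage: histology registration
# ---------------------------------------------------------------------------

def stage_register_histology(out_dir: Path, src: LandmarkSet,
                             dst: LandmarkSet) -> AffineTransform2D:
    """Landmark affine from MD-map pixels to histology pixels."""
    hist_dir = Path(out_dir) / "histreg"
    hist_dir.mkdir(parents=True, exist_ok=True)
    res = registration.fit_landmark_affine(src, dst)
    io.write_affine_2d(
        res.transform, hist_dir / "md_to_hist_affine.json",
        extra={"residuals_px": res.residuals.tolist(),
               "singular_values": np.linalg.svd(
                   res.transform.matrix, compute_uv=False).tolist()},
    )
    return res.transform


# ---------------------------------------------------------------------------
# stage: ROI statistics
# ---------------------------------------------------------------------------

def stage_roi_stats(out_dir: Path, aligned: dict[str, MRVolume],
                    rois: list[ROISpec] | None = None) -> list[dict]:
    """ROI means/SDs, normalisation to CTRL, pairwise t-test table."""
    stats_dir = Path(out_dir) / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    rois = rois or default_rois()
    mid = aligned["T2w"].shape[2] // 2
    spacing_um = tuple(s * 1000.0 for s in aligned["T2w"].spacing[:2])

    stat_rows: list[dict] = []
    roi_values: dict[str, dict[str, np.ndarray]] = {}
    for contrast in CONTRASTS:
        image = aligned[contrast].voxels[:, :, mid]
        by_roi = {}
        stats_list = {}
        for roi in rois:
            vals = rs.roi_voxel_values(image, spacing_um, roi)
            by_roi[roi.label] = vals
            stats_list[roi.label] = rs.roi_statistics(
                image, spacing_um, roi, contrast_label=contrast
            )
        control = stats_list["CTRL"]
        for roi in rois:
            st = rs.normalize_to_control(stats_list[roi.label], control)
            stat_rows.append(
                {
                    "roi": st.roi_label,
                    "contrast": st.contrast_label,
                    "n_voxels": st.n,
                    "mean": st.mean,
                    "sd": st.sd,
                    "relative_mean": st.relative_mean,
                }
            )
        roi_values[contrast] = by_roi
    io.write_stats_table(stat_rows, stats_dir / "roi_stats.csv")

    records = rs.pairwise_comparison_table(roi_values, pairs=rs.STUDY_PAIRS)
    rows = rs.comparison_records_to_rows(records,
                                         n_comparisons=len(rs.STUDY_PAIRS))
    io.write_stats_table(rows, stats_dir / "comparisons.csv")
    return rows


# ---------------------------------------------------------------------------
# stage: cellularity + correlation
# ---------------------------------------------------------------------------

def stage_cellularity(out_dir: Path, hist_images, tissueB_mask: np.ndarray,
                      n_intervals: int) -> tuple[cell.CellularityGrid, list]:
    cel_dir = Path(out_dir) / "cellularity"
    cel_dir.mkdir(parents=True, exist_ok=True)
    detections = [cell.detect_nuclei(img) for img in hist_images]
    grid = cell.grid_cellularity_map(
        hist_images, tissueB_mask, detections=detections,
        n_intervals=n_intervals,
    )
    rgb = cell.colorize_cellularity(grid)
    iio.imwrite(cel_dir / "cellularity_map.png", rgb)
    rows = []
    est = grid.estimate
    for (r, c), raw in np.ndenumerate(grid.raw_mean):
        if np.isfinite(raw):
            rows.append(
                {"tile_row": r, "tile_col": c, "raw_mean": raw,
                 "estimate": est[r, c], "bin": int(grid.bins[r, c])}
            )
    io.write_stats_table(rows, cel_dir / "cellularity_grid.csv")
    return grid, detections


def select_md_pixels(md_slice: np.ndarray, tissue_mask: np.ndarray,
                     n_pixels: int, rng: np.random.Generator) -> np.ndarray:
    """Pick pixels with variable MD: one random pixel per MD quantile band."""
    idx = np.argwhere(tissue_mask & np.isfinite(md_slice))
    if idx.shape[0] < n_pixels:
        raise ValueError("tissue region smaller than the requested sample")
    order = np.argsort(md_slice[idx[:, 0], idx[:, 1]], kind="stable")
    chunks = np.array_split(idx[order], n_pixels)
    return np.asarray([chunk[rng.integers(len(chunk))] for chunk in chunks])


def stage_correlate(out_dir: Path, md: dti.ScalarMap, tissue_mask_md: np.ndarray,
                    affine_md_to_hist: AffineTransform2D,
                    detections: list[np.ndarray], hist_pixel_size: float,
                    n_intervals: int, seed: int, n_pixels: int = 15,
                    roi_um: float = 200.0) -> dict:
    """Pixel-level MD vs estimated cell count, through the landmark affine."""
    cor_dir = Path(out_dir) / "correlation"
    cor_dir.mkdir(parents=True, exist_ok=True)
    mid = md.values.shape[2] // 2 if md.values.ndim == 3 else None
    md_slice = md.values[:, :, mid] if mid is not None else md.values
    rng = np.random.default_rng([int(seed), 400])
    pixels = select_md_pixels(md_slice, tissue_mask_md, n_pixels, rng)

    md_vals, counts = [], []
    pairs = []
    for p in pixels:
        md_val = md_slice[p[0], p[1]]
        centre_hist_px = affine_md_to_hist.apply(p.astype(float))[0]
        centre_um = (centre_hist_px + 0.5) * hist_pixel_size
        roi = ROISpec(
            anchor=(centre_um[0] - roi_um / 2, centre_um[1] - roi_um / 2),
            height=roi_um, width=roi_um, label="px", image_frame="histology",
        )
        per_level = [cell.count_in_roi(d, roi) for d in detections]
        est = cell.estimate_section_count(per_level, n_intervals)
        md_vals.append(md_val)
        counts.append(est)
        pairs.append({"pixel": p.tolist(), "md_mm2_s": float(md_val),
                      "estimated_cells": est})
    r, n = cell.correlate_md_cellularity(md_vals, counts)
    report = {
        "pearson_r": r,
        "magnitude": abs(r),
        "sign": "negative" if r < 0 else "positive",
        "n_pixels": n,
        "roi_um": roi_um,
        "pairs": pairs,
    }
    with open(cor_dir / "md_cellularity_correlation.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(out_dir: str | Path, seed: int = 0,
            config: dict | None = None) -> dict:
    """Full pipeline on the default phantom; returns a summary dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = make_spec(seed, config)

    sim = stage_simulate(out_dir, spec)
    gt, weighted = sim["gt"], sim["weighted"]
    aligned = stage_register_contrasts(out_dir, weighted)
    md = stage_fit_dti(out_dir, sim["frames"], sim["table"])
    src, dst = sim["landmarks"]
    affine = stage_register_histology(out_dir, src, dst)
    comparisons = stage_roi_stats(out_dir, aligned)

    b_idx = [spec.label_index(l) for l in ("tissueB", "tissueB_hemosiderin")]
    tissueB_mask = np.isin(sim["hist_labels"], b_idx)
    grid, detections = stage_cellularity(
        out_dir, sim["hist_images"], tissueB_mask, spec.n_intervals
    )

    mid = spec.shape_dwi[2] // 2
    tissue_idx = [spec.label_index(l) for l in ph.TISSUE_LABELS]
    tissue_mask_md = np.isin(gt.label_dwi[:, :, mid], tissue_idx)
    report = stage_correlate(
        out_dir, md, tissue_mask_md, affine, detections,
        spec.hist_pixel_size_um, spec.n_intervals, seed,
    )

    summary = {
        "seed": int(seed),
        "n_comparisons": len(comparisons),
        "pearson_r": report["pearson_r"],
        "n_pixels": report["n_pixels"],
        "recovered_singular_values": np.linalg.svd(
            affine.matrix, compute_uv=False).tolist(),
        "true_shrinkage": spec.shrinkage,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
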