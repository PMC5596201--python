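"""Readers and writers for every on-disk format the pipeline touches.

Formats: NIfTI-1 for MR volumes and scalar maps, whitespace text for the
gradient table (one ``b gx gy gz`` row per frame), JSON for landmarks / ROI
specifications / transforms, CSV for statistics tables, TIFF or PNG for
histology and rendered maps.  Every reader/writer pair round-trips its own
output bit-exactly.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .types import (
    MIN_DWI_FRAMES,
    AffineTransform2D,
    GradientTable,
    HistologyImage,
    LandmarkSet,
    MRVolume,
    RigidTransform3D,
    ROISpec,
)

__all__ = [
    "read_mr_volume",
    "write_mr_volume",
    "read_gradient_table",
    "write_gradient_table",
    "read_landmarks",
    "write_landmarks",
    "read_roi_specs",
    "write_roi_specs",
    "read_histology_image",
    "write_histology_image",
    "write_stats_table",
    "read_stats_table",
    "read_affine_2d",
    "write_affine_2d",
    "write_rigid_3d",
    "read_rigid_3d",
]


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_mr_volume(path: str | os.PathLike, contrast_label: str = "T2w") -> MRVolume:
    """Load a 3-D NIfTI-1 volume.

    Spacing comes from the header zooms (mm) and the origin from the affine
    translation.  Non-3-D data are rejected with a message naming the axis
    count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3-D volume, file has {data.ndim} axes: {path.name}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return MRVolume(
        voxels=data.astype(np.float64),
        spacing=spacing,
        origin=origin,
        contrast_label=contrast_label,
    )


def write_mr_volume(vol: MRVolume, path: str | os.PathLike) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Gradient table
# ---------------------------------------------------------------------------

def read_gradient_table(path: str | os.PathLike) -> GradientTable:
    """Parse a plain-text gradient table, one ``b gx gy gz`` line per frame.

    Directions within 1e-3 of unit length are renormalised; anything further
    off is rejected.  The table must contain a b=0 reference and at least six
    weighted frames so that a tensor fit is possible downstream.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'b gx gy gz', got {line!r}"
                )
            rows.append([float(p) for p in parts])
    if len(rows) < MIN_DWI_FRAMES:
        raise ValueError(
            f"gradient table has {len(rows)} frames; a tensor fit needs at "
            f"least {MIN_DWI_FRAMES} (one b=0 and six weighted)"
        )
    arr = np.asarray(rows, dtype=float)
    bvals, bvecs = arr[:, 0], arr[:, 1:4]
    if not np.any(bvals == 0):
        raise ValueError("no reference frame: gradient table has no b=0 entry")
    weighted = bvals > 0
    norms = np.linalg.norm(bvecs[weighted], axis=1)
    off = np.abs(norms - 1.0)
    if np.any(off > 1e-3):
        bad = np.flatnonzero(weighted)[np.argmax(off)]
        raise ValueError(
            f"gradient direction on line for frame {bad} is not a unit vector "
            f"(|g| = {norms[np.argmax(off)]:.4g}, tolerance 1e-3)"
        )
    bvecs = bvecs.copy()
    # renormalise only genuinely off-unit rows; touching already-unit rows
    # would perturb the last ULP and break bit-exact round-trips
    fix = off > 1e-12
    if np.any(fix):
        rows = np.flatnonzero(weighted)[fix]
        bvecs[rows] /= norms[fix, None]
    table = GradientTable(bvals=bvals, bvecs=bvecs)
    table.validate_for_tensor_fit()
    return table


def write_gradient_table(table: GradientTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for b, g in zip(table.bvals, table.bvecs):
            # builtin-float repr round-trips at full precision
            fh.write(f"{float(b)!r} {float(g[0])!r} "
                     f"{float(g[1])!r} {float(g[2])!r}\n")


# ---------------------------------------------------------------------------
# Landmarks and ROIs (JSON)
# ---------------------------------------------------------------------------

def read_landmarks(path: str | os.PathLike) -> tuple[LandmarkSet, LandmarkSet]:
    """Load a paired landmark file: source (MD map) and destination sets.

    The JSON layout is ``{"source": {"frame": ..., "points": [[p0, p1], ...]},
    "destination": {...}}`` with index-paired, equally long point lists.
    """
    with open(path) as fh:
        doc = json.load(fh)
    try:
        src_doc, dst_doc = doc["source"], doc["destination"]
    except KeyError as exc:
        raise ValueError(f"landmark file missing section {exc}") from exc
    src = LandmarkSet(np.asarray(src_doc["points"], dtype=float),
                      frame=str(src_doc.get("frame", "")))
    dst = LandmarkSet(np.asarray(dst_doc["points"], dtype=float),
                      frame=str(dst_doc.get("frame", "")))
    if len(src) != len(dst):
        raise ValueError(
            f"landmark sets are index-paired but differ in length "
            f"({len(src)} vs {len(dst)})"
        )
    if len(src) < 3:
        raise ValueError(
            f"an affine solve needs at least 3 landmark pairs, got {len(src)}"
        )
    return src, dst


def write_landmarks(src: LandmarkSet, dst: LandmarkSet,
                    path: str | os.PathLike) -> None:
    if len(src) != len(dst):
        raise ValueError("source and destination sets must pair by index")
    doc = {
        "source": {"frame": src.frame, "points": src.points.tolist()},
        "destination": {"frame": dst.frame, "points": dst.points.tolist()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_roi_specs(rois: list[ROISpec], path: str | os.PathLike) -> None:
    doc = [
        {
            "label": r.label,
            "image_frame": r.image_frame,
            "anchor_um": list(r.anchor),
            "height_um": r.height,
            "width_um": r.width,
        }
        for r in rois
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_roi_specs(path: str | os.PathLike) -> list[ROISpec]:
    with open(path) as fh:
        doc = json.load(fh)
    return [
        ROISpec(
            anchor=tuple(d["anchor_um"]),
            height=d["height_um"],
            width=d["width_um"],
            label=d.get("label", ""),
            image_frame=d.get("image_frame", ""),
        )
        for d in doc
    ]


# ---------------------------------------------------------------------------
# Histology images
# ---------------------------------------------------------------------------

def write_histology_image(img: HistologyImage, path: str | os.PathLike) -> None:
    """Write TIFF (with pixel size and level in the description tag) or PNG."""
    path = Path(path)
    pixels = np.asarray(img.pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        meta = json.dumps({"pixel_size_um": img.pixel_size,
                           "level_index": img.level_index})
        tifffile.imwrite(str(path), pixels, description=meta)
    else:
        iio.imwrite(str(path), pixels)


def read_histology_image(path: str | os.PathLike, pixel_size: float | None = None,
                         level_index: int | None = None) -> HistologyImage:
    """Read a histology TIFF/PNG.

    For TIFFs written by :func:`write_histology_image` the pixel size and
    level are recovered from the description tag; for other files they must
    be supplied by the caller.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            pixels = tf.asarray()
            desc = tf.pages[0].tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                    pixel_size = pixel_size or meta.get("pixel_size_um")
                    level_index = level_index or meta.get("level_index")
                except (json.JSONDecodeError, TypeError):
                    pass
    else:
        pixels = iio.imread(str(path))
    if pixel_size is None:
        raise ValueError(f"pixel size unknown for {path.name}; pass pixel_size=")
    return HistologyImage(pixels=pixels, pixel_size=pixel_size,
                          level_index=level_index or 1)


# ---------------------------------------------------------------------------
# Statistics tables (CSV)
# ---------------------------------------------------------------------------

def write_stats_table(rows: list[dict], path: str | os.PathLike,
                      columns: list[str] | None = None) -> None:
    """Write records to CSV with a header; floats keep full repr precision.

    An empty record list yields a header-only file (columns required then).
    """
    if rows:
        keys = list(rows[0].keys())
        for r in rows[1:]:
            if list(r.keys()) != keys:
                raise ValueError("stats rows must share one column schema")
        df = pd.DataFrame(rows, columns=keys)
    else:
        df = pd.DataFrame(columns=columns or [])
    df.to_csv(path, index=False)


def read_stats_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Transforms (JSON)
# ---------------------------------------------------------------------------

def write_affine_2d(t: AffineTransform2D, path: str | os.PathLike,
                    extra: dict | None = None) -> None:
    doc = {"matrix": t.matrix.tolist(), "translation": t.translation.tolist()}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_affine_2d(path: str | os.PathLike) -> AffineTransform2D:
    with open(path) as fh:
        doc = json.load(fh)
    return AffineTransform2D(np.asarray(doc["matrix"]),
                             np.asarray(doc["translation"]))


def write_rigid_3d(transforms: list[RigidTransform3D],
                   path: str | os.PathLike) -> None:
    doc = [
        {"rotation": t.rotation.tolist(), "translation": t.translation.tolist()}
        for t in transforms
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_rigid_3d(path: str | os.PathLike) -> list[RigidTransform3D]:
    with open(path) as fh:
        doc = json.load(fh)
    return [
        RigidTransform3D(np.asarray(d["rotation"]), np.asarray(d["translation"]))
        for d in doc
    ]
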