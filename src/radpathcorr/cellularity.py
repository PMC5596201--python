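"""Nucleus counting, section-interval scaling, cellularity grids, correlation.

Cellularity is defined as the nucleus count in a region of interest.  Counts
from several section levels are averaged and multiplied by the number of
interval sections (default 35) to estimate the cells contained in the full
MR slice thickness.  A tiled grid of such estimates over the tissue is
colour-coded with an 11-bin palette spanning 0 to 2500 cells, and the
per-pixel mean diffusivity is correlated (Pearson) against matched estimated
counts.

The nucleus detector is a deliberately simple, documented stand-in for
proprietary slide-analysis software: global dark-object thresholding,
watershed splitting of touching nuclei (distance-transform peaks as
markers), and an area filter, with an optional manual-correction list
(additions/removals by coordinate) replacing interactive editing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import feature, measure, segmentation

from .types import HistologyImage, ROISpec

N_INTERVAL_SECTIONS = 35  # serial 6-um sections represented by one level
DEFAULT_TILE_UM = 100.0

# 11 colour bins: white (0), then 250-cell-wide bins up to 2500.  The bin
# boundaries as printed overlap ("1 to 250", "250 to 500"); the recorded
# convention is that bin 0 holds exactly 0 and interior boundaries belong to
# the lower bin (half-open (low, high] after zero).
BIN_EDGES = np.arange(0.0, 2501.0, 250.0)  # 0, 250, ..., 2500
BIN_COLORS = np.array(
    [
        (255, 255, 255),  # white: 0
        (255, 255, 180),  # light yellow: (0, 250]
        (255, 238, 90),   # yellow: (250, 500]
        (205, 160, 110),  # light brown: (500, 750]
        (255, 190, 120),  # light orange: (750, 1000]
        (255, 150, 40),   # orange: (1000, 1250]
        (255, 110, 110),  # light red: (1250, 1500]
        (230, 30, 30),    # red: (1500, 1750]
        (160, 10, 10),    # dark red: (1750, 2000]
        (140, 85, 40),    # brown: (2000, 2250]
        (80, 45, 20),     # dark brown: (2250, 2500]
    ],
    dtype=np.uint8,
)


@dataclass
class NucleusDetectionParams:
    """Tunables of the threshold + connected-components nucleus detector."""

    threshold: float = 0.5        # fraction of the image intensity range
    min_area_um2: float = 20.0
    max_area_um2: float = 2000.0
    min_separation_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if not 0.0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("need 0 < min area < max area")
        if self.min_separation_um < 0:
            raise ValueError("minimum separation cannot be negative")


@dataclass
class CellularityGrid:
    """Tiled nucleus-count estimates over a histology image.

    ``estimate = raw_mean * n_intervals`` holds exactly on every tile;
    estimates stay real-valued internally (rounding is display-only).
    Tiles outside the tissue mask carry NaN.
    """

    tile_um: float
    origin_px: tuple[int, int]
    pixel_size_um: float
    raw_mean: np.ndarray
    n_intervals: int
    bins: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.raw_mean = np.asarray(self.raw_mean, dtype=float)
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if np.nanmin(self.raw_mean, initial=0.0) < 0:
            raise ValueError("counts cannot be negative")
        if self.bins is None:
            self.bins = colorize_bins(self.estimate)

    @property
    def estimate(self) -> np.ndarray:
        return self.raw_mean * self.n_intervals


# ---------------------------------------------------------------------------
# detection and counting
# ---------------------------------------------------------------------------

def _to_gray(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 3:
        return np.asarray(pixels[..., :3], dtype=float).mean(axis=-1)
    return np.asarray(pixels, dtype=float)


def detect_nuclei(image: HistologyImage,
                  params: NucleusDetectionParams | None = None) -> np.ndarray:
    """Centroids (um, image frame) of dark blobs passing the area filter.

    Deterministic: global threshold at ``min + threshold * range``, then
    watershed segmentation seeded at distance-transform peaks so touching
    nuclei are split rather than counted as one clump, then an area filter
    in um^2 with one centroid per segment.  A blank image yields an empty
    list, not an error.  When a minimum centroid separation is set,
    centroids closer than it are merged greedily in decreasing-area order.
    """
    params = params or NucleusDetectionParams()
    gray = _to_gray(image.pixels)
    lo, hi = float(gray.min()), float(gray.max())
    if hi == lo:
        return np.empty((0, 2))
    cut = lo + params.threshold * (hi - lo)
    mask = gray < cut
    components = measure.label(mask, connectivity=2)
    distance = ndimage.distance_transform_edt(mask)
    peaks = feature.peak_local_max(
        distance, min_distance=1, labels=components, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labeled = segmentation.watershed(-distance, markers, mask=mask)
    px_area = image.pixel_size**2
    cents, areas = [], []
    for region in measure.regionprops(labeled):
        area = region.area * px_area
        if params.min_area_um2 <= area <= params.max_area_um2:
            cents.append(region.centroid)
            areas.append(area)
    if not cents:
        return np.empty((0, 2))
    # pixel-centre physical position: (index + 0.5) * pixel size
    cent_um = (np.asarray(cents) + 0.5) * image.pixel_size
    if params.min_separation_um > 0 and len(cent_um) > 1:
        order = np.argsort(areas)[::-1]
        kept: list[np.ndarray] = []
        for idx in order:
            p = cent_um[idx]
            if all(np.linalg.norm(p - q) >= params.min_separation_um
                   for q in kept):
                kept.append(p)
        cent_um = np.asarray(kept)
    return cent_um


def apply_corrections(centroids: np.ndarray, corrections: dict,
                      tolerance_um: float = 5.0) -> np.ndarray:
    """Apply a manual-correction record to detected centroids.

    ``corrections`` holds ``"add"`` (list of [p0, p1] um positions) and
    ``"remove"`` (positions matched to the nearest detection within
    ``tolerance_um``).
    """
    pts = list(np.asarray(centroids, dtype=float).reshape(-1, 2))
    for rm in corrections.get("remove", []):
        if not pts:
            break
        d = [np.linalg.norm(p - np.asarray(rm, dtype=float)) for p in pts]
        k = int(np.argmin(d))
        if d[k] <= tolerance_um:
            pts.pop(k)
    for add in corrections.get("add", []):
        pts.append(np.asarray(add, dtype=float))
    return np.asarray(pts).reshape(-1, 2)


def count_in_roi(centroids: np.ndarray, roi: ROISpec) -> int:
    """Number of centroids inside the half-open ROI rectangle.

    Points exactly on the high edge are excluded (half-open convention).
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        return 0
    a0, a1 = roi.anchor
    inside = (
        (pts[:, 0] >= a0) & (pts[:, 0] < a0 + roi.height)
        & (pts[:, 1] >= a1) & (pts[:, 1] < a1 + roi.width)
    )
    return int(inside.sum())


def estimate_section_count(per_level_counts, n_intervals: int = N_INTERVAL_SECTIONS
                           ) -> float:
    """Mean count across section levels, scaled by the interval count.

    The returned estimate is real-valued; rounding happens only at display.
    """
    counts = np.asarray(per_level_counts, dtype=float).ravel()
    if counts.size == 0:
        raise ValueError("at least one section level is required")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    return float(counts.mean() * n_intervals)


# ---------------------------------------------------------------------------
# gridded cellularity map
# ---------------------------------------------------------------------------

def grid_cellularity_map(
    images: list[HistologyImage],
    tissue_mask: np.ndarray,
    tile_um: float = DEFAULT_TILE_UM,
    params: NucleusDetectionParams | None = None,
    n_intervals: int = N_INTERVAL_SECTIONS,
    detections: list[np.ndarray] | None = None,
) -> CellularityGrid:
    """Sequential square tiles over the tissue mask, counts averaged by level.

    Tiles are laid row-major from the mask bounding box origin; tiles whose
    centre lies outside the mask carry NaN.  ``detections`` can supply
    precomputed centroid lists (um) to avoid re-running the detector.
    """
    if tile_um <= 0:
        raise ValueError("tile size must be positive")
    if not images:
        raise ValueError("at least one section level is required")
    mask = np.asarray(tissue_mask, dtype=bool)
    if not mask.any():
        raise ValueError("tissue mask is empty")
    px = images[0].pixel_size
    if any(img.pixel_size != px or img.shape_2d != images[0].shape_2d
           for img in images):
        raise ValueError("all section levels must share geometry")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, c0 = int(rows[0]), int(cols[0])
    tile_px = tile_um / px
    n0 = int(np.ceil((rows[-1] + 1 - r0) / tile_px))
    n1 = int(np.ceil((cols[-1] + 1 - c0) / tile_px))

    if detections is None:
        detections = [detect_nuclei(img, params) for img in images]

    counts = np.zeros((len(images), n0, n1))
    origin_um = np.array([r0, c0]) * px
    for li, cents in enumerate(detections):
        if len(cents) == 0:
            continue
        rel = (cents - origin_um) / tile_um
        t0 = np.floor(rel[:, 0]).astype(int)
        t1 = np.floor(rel[:, 1]).astype(int)
        ok = (t0 >= 0) & (t0 < n0) & (t1 >= 0) & (t1 < n1)
        np.add.at(counts[li], (t0[ok], t1[ok]), 1)

    raw_mean = counts.mean(axis=0)
    # mask out tiles whose centre is not tissue
    tc0 = np.clip((r0 + (np.arange(n0) + 0.5) * tile_px).astype(int), 0,
                  mask.shape[0] - 1)
    tc1 = np.clip((c0 + (np.arange(n1) + 0.5) * tile_px).astype(int), 0,
                  mask.shape[1] - 1)
    in_tissue = mask[np.ix_(tc0, tc1)]
    raw_mean = np.where(in_tissue, raw_mean, np.nan)
    return CellularityGrid(
        tile_um=tile_um,
        origin_px=(r0, c0),
        pixel_size_um=px,
        raw_mean=raw_mean,
        n_intervals=n_intervals,
    )


# ---------------------------------------------------------------------------
# colour coding
# ---------------------------------------------------------------------------

def colorize_bins(estimates: np.ndarray) -> np.ndarray:
    """Bin index (0-10) per estimate; NaN maps to -1.

    Bin 0 is exactly 0; bin k (k >= 1) is (250*(k-1), 250*k]; estimates
    above 2500 clamp to the top bin with a warning.
    """
    est = np.asarray(estimates, dtype=float)
    if np.nanmin(est, initial=0.0) < 0:
        raise ValueError("cellularity estimates cannot be negative")
    finite = np.isfinite(est)
    bins = np.full(est.shape, -1, dtype=int)
    vals = est[finite]
    idx = np.ceil(vals / 250.0).astype(int)  # 0 -> 0, (0,250] -> 1, ...
    if np.any(idx > 10):
        warnings.warn(
            "cellularity estimates above 2500 clamped to the top colour bin",
            RuntimeWarning,
            stacklevel=2,
        )
        idx = np.minimum(idx, 10)
    bins[finite] = idx
    return bins


def colorize_cellularity(grid: CellularityGrid,
                         background=(0, 0, 0)) -> np.ndarray:
    """RGB image of the grid's colour bins (one pixel per tile)."""
    bins = colorize_bins(grid.estimate)
    out = np.zeros(bins.shape + (3,), dtype=np.uint8)
    out[...] = np.asarray(background, dtype=np.uint8)
    valid = bins >= 0
    out[valid] = BIN_COLORS[bins[valid]]
    return out


# ---------------------------------------------------------------------------
# MD-cellularity correlation
# ---------------------------------------------------------------------------

def correlate_md_cellularity(md_values: np.ndarray, counts: np.ndarray
                             ) -> tuple[float, int]:
    """Pearson correlation between matched MD values and estimated counts.

    The signed coefficient is returned together with n; report the magnitude
    separately when an unsigned convention is wanted.
    """
    md = np.asarray(md_values, dtype=float).ravel()
    ct = np.asarray(counts, dtype=float).ravel()
    if md.size != ct.size:
        raise ValueError("MD values and counts must be matched pairs")
    keep = np.isfinite(md) & np.isfinite(ct)
    md, ct = md[keep], ct[keep]
    if md.size < 3:
        raise ValueError("at least 3 matched pairs are required")
    if md.std() == 0 or ct.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r = stats.pearsonr(md, ct).statistic
    return float(r), int(md.size)
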