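"""Nucleus detection, interval scaling, colour bins, grid and correlation."""

from __future__ import annotations

import numpy as np
import pytest

from radpathcorr import cellularity as cell
from radpathcorr.types import HistologyImage, ROISpec


def _disk_image(centers_px, radius_px=3, shape=(200, 200), pixel_size=5.0,
                background=230, foreground=40):
    img = np.full(shape, background, dtype=np.uint8)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    for r0, c0 in centers_px:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2] = foreground
    return HistologyImage(pixels=img, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_hundred_nontouching_disks_detected_exactly():
    centers = [(10 + 18 * i, 10 + 18 * j) for i in range(10) for j in range(10)]
    img = _disk_image(centers, radius_px=2, shape=(200, 200))
    cents = cell.detect_nuclei(img)
    assert cents.shape == (100, 2)
    # centroids land within one pixel of the drawn disk centres
    drawn = (np.asarray(centers, dtype=float) + 0.5) * img.pixel_size
    d = np.sort(np.linalg.norm(cents[:, None] - drawn[None], axis=2).min(axis=1))
    assert d.max() < img.pixel_size


def test_blank_image_yields_no_detections():
    img = HistologyImage(pixels=np.full((50, 50), 200, dtype=np.uint8),
                         pixel_size=5.0)
    assert cell.detect_nuclei(img).shape == (0, 2)


def test_area_filter_removes_specks_and_blobs():
    # 1-px speck (25 um^2 at 5 um/px is in range; use min_area to cut it)
    img = _disk_image([(30, 30)], radius_px=1, shape=(100, 100))
    params = cell.NucleusDetectionParams(min_area_um2=200.0,
                                         max_area_um2=2000.0)
    assert cell.detect_nuclei(img, params).shape[0] == 0
    # giant blob above max area is rejected too
    img = _disk_image([(50, 50)], radius_px=20, shape=(100, 100))
    assert cell.detect_nuclei(img, params).shape[0] == 0


def test_touching_nuclei_are_declumped():
    # two disks whose masks touch form one connected component
    img = _disk_image([(50, 50), (50, 57)], radius_px=4, shape=(100, 100))
    from skimage import measure

    mask = np.asarray(img.pixels) < 135
    assert measure.label(mask).max() == 1  # a single clump
    cents = cell.detect_nuclei(img)
    assert cents.shape[0] == 2


def test_detection_params_validation():
    with pytest.raises(ValueError, match="threshold"):
        cell.NucleusDetectionParams(threshold=1.5)
    with pytest.raises(ValueError, match="area"):
        cell.NucleusDetectionParams(min_area_um2=100.0, max_area_um2=50.0)


def test_apply_corrections_add_and_remove():
    cents = np.array([[100.0, 100.0], [200.0, 200.0]])
    out = cell.apply_corrections(
        cents,
        {"remove": [[101.0, 99.0]], "add": [[300.0, 300.0]]},
        tolerance_um=5.0,
    )
    assert out.shape == (2, 2)
    assert [300.0, 300.0] in out.tolist()
    assert [100.0, 100.0] not in out.tolist()
    # removals farther than the tolerance are ignored
    out = cell.apply_corrections(cents, {"remove": [[150.0, 150.0]]})
    assert out.shape == (2, 2)


# ---------------------------------------------------------------------------
# counting and scaling
# ---------------------------------------------------------------------------

def test_count_in_roi_half_open_edges():
    pts = np.array([[0.0, 0.0], [100.0, 50.0], [50.0, 100.0], [99.9, 99.9]])
    roi = ROISpec(anchor=(0.0, 0.0), height=100.0, width=100.0)
    # low edges included, high edges excluded
    assert cell.count_in_roi(pts, roi) == 2


def test_worked_example_455():
    assert cell.estimate_section_count([10, 12, 14, 16], 35) == 455.0
    assert cell.estimate_section_count([7], 1) == 7.0
    assert cell.N_INTERVAL_SECTIONS == 35


def test_estimate_errors():
    with pytest.raises(ValueError, match="at least one"):
        cell.estimate_section_count([])
    with pytest.raises(ValueError, match="n_intervals"):
        cell.estimate_section_count([1.0], 0)


# ---------------------------------------------------------------------------
# colour bins
# ---------------------------------------------------------------------------

def test_bins_partition_zero_to_2500():
    # bin 0 holds exactly 0; interior boundaries belong to the lower bin
    assert cell.colorize_bins(np.array([0.0]))[0] == 0
    assert cell.colorize_bins(np.array([100.0]))[0] == 1
    assert cell.colorize_bins(np.array([250.0]))[0] == 1
    assert cell.colorize_bins(np.array([250.0001]))[0] == 2
    assert cell.colorize_bins(np.array([2500.0]))[0] == 10
    # every boundary maps to exactly one bin
    edges = cell.BIN_EDGES
    bins = cell.colorize_bins(edges)
    assert bins.tolist() == list(range(11))
    assert len(cell.BIN_COLORS) == 11


def test_bins_clamp_above_2500_with_warning():
    with pytest.warns(RuntimeWarning, match="clamped"):
        bins = cell.colorize_bins(np.array([3000.0]))
    assert bins[0] == 10


def test_bins_reject_negative_and_propagate_nan():
    with pytest.raises(ValueError, match="negative"):
        cell.colorize_bins(np.array([-1.0]))
    assert cell.colorize_bins(np.array([np.nan]))[0] == -1


def test_doubling_counts_doubles_estimates_never_lowers_bins(rng):
    raw = rng.uniform(0, 30, size=(5, 5))
    g1 = cell.CellularityGrid(tile_um=100.0, origin_px=(0, 0),
                              pixel_size_um=5.0, raw_mean=raw, n_intervals=35)
    g2 = cell.CellularityGrid(tile_um=100.0, origin_px=(0, 0),
                              pixel_size_um=5.0, raw_mean=2 * raw,
                              n_intervals=35)
    np.testing.assert_allclose(g2.estimate, 2 * g1.estimate, rtol=1e-12)
    with np.errstate(invalid="ignore"):
        assert np.all(g2.bins >= g1.bins)


def test_estimate_is_mean_times_intervals_exactly(rng):
    raw = rng.uniform(0, 40, size=(4, 6))
    g = cell.CellularityGrid(tile_um=100.0, origin_px=(0, 0),
                             pixel_size_um=5.0, raw_mean=raw, n_intervals=35)
    np.testing.assert_array_equal(g.estimate, raw * 35)


# ---------------------------------------------------------------------------
# gridded map
# ---------------------------------------------------------------------------

def test_grid_shape_and_mask_sentinels():
    # 1 x 1 mm mask at 5 um/px -> 200 x 200 px -> 10 x 10 grid of 100 um tiles
    mask = np.zeros((260, 260), dtype=bool)
    mask[30:230, 30:230] = True
    img = HistologyImage(pixels=np.full((260, 260), 200, np.uint8),
                         pixel_size=5.0)
    grid = cell.grid_cellularity_map([img], mask, tile_um=100.0)
    assert grid.raw_mean.shape == (10, 10)
    assert grid.origin_px == (30, 30)
    assert np.all(np.isfinite(grid.raw_mean))  # all tile centres in tissue


def test_grid_tiling_conservation():
    # sum of per-tile counts equals the number of detections in the region
    centers = [(15 + 20 * i, 15 + 20 * j) for i in range(9) for j in range(9)]
    img = _disk_image(centers, radius_px=2, shape=(200, 200))
    cents = cell.detect_nuclei(img)
    mask = np.ones((200, 200), dtype=bool)
    grid = cell.grid_cellularity_map([img], mask, tile_um=100.0,
                                     detections=[cents])
    total_in_tiles = np.nansum(grid.raw_mean)
    assert total_in_tiles == len(cents) == len(centers)
    # equivalently through count_in_roi over the disjoint tiling
    n0, n1 = grid.raw_mean.shape
    s = 0
    for i in range(n0):
        for j in range(n1):
            roi = ROISpec(anchor=(i * 100.0, j * 100.0), height=100.0,
                          width=100.0)
            s += cell.count_in_roi(cents, roi)
    assert s == len(cents)


def test_grid_rejects_empty_mask_and_geometry_mismatch():
    img = HistologyImage(pixels=np.full((50, 50), 200, np.uint8),
                         pixel_size=5.0)
    with pytest.raises(ValueError, match="empty"):
        cell.grid_cellularity_map([img], np.zeros((50, 50), bool))
    other = HistologyImage(pixels=np.full((60, 60), 200, np.uint8),
                           pixel_size=5.0)
    with pytest.raises(ValueError, match="geometry"):
        cell.grid_cellularity_map([img, other], np.ones((50, 50), bool))


def test_colorize_cellularity_rgb():
    raw = np.array([[0.0, np.nan], [10.0, 60.0]])
    g = cell.CellularityGrid(tile_um=100.0, origin_px=(0, 0),
                             pixel_size_um=5.0, raw_mean=raw, n_intervals=35)
    rgb = cell.colorize_cellularity(g)
    assert rgb.shape == (2, 2, 3)
    assert tuple(rgb[0, 0]) == (255, 255, 255)  # estimate 0 -> white
    assert tuple(rgb[0, 1]) == (0, 0, 0)        # NaN -> background


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_perfect_linear_coupling_gives_minus_one():
    md = np.linspace(0.3e-3, 1.0e-3, 15)
    counts = 75.0 - 7.0e4 * md
    r, n = cell.correlate_md_cellularity(md, counts)
    assert n == 15
    assert r == pytest.approx(-1.0, abs=1e-12)


def test_null_coupling_small_correlation(rng):
    md = rng.uniform(0.3e-3, 1.0e-3, size=1000)
    counts = rng.poisson(30.0, size=1000).astype(float)
    r, n = cell.correlate_md_cellularity(md, counts)
    assert abs(r) < 0.1


def test_correlation_input_validation():
    with pytest.raises(ValueError, match="matched pairs"):
        cell.correlate_md_cellularity(np.ones(3), np.ones(4))
    with pytest.raises(ValueError, match="at least 3"):
        cell.correlate_md_cellularity(np.ones(2), np.ones(2))
    with pytest.raises(ValueError, match="zero variance"):
        cell.correlate_md_cellularity(np.ones(5), np.arange(5.0))
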