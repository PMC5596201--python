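"""ROI intensity statistics, control normalisation and pairwise t-tests.

Mirrors the semiquantitative signal analysis: average and sample standard
deviation of voxel intensities per ROI on the co-registered weighted images,
normalisation to a control ROI placed in the agarose gel, and a pairwise
unpaired (pooled-variance Student) t-test table across ROI pairs and
contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ROISpec

DEFAULT_ALPHA = 0.05


@dataclass
class ROIStats:
    """Summary statistics of one ROI on one contrast."""

    roi_label: str
    contrast_label: str
    n: int
    mean: float
    sd: float
    relative_mean: float = float("nan")

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD cannot be negative")


@dataclass
class ComparisonRecord:
    """One pairwise unpaired t-test between two ROIs on one contrast."""

    roi_a: str
    roi_b: str
    contrast_label: str
    t: float
    p: float
    significant: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p value outside [0, 1]")


def roi_voxel_values(image: np.ndarray, spacing_um: tuple[float, float],
                     roi: ROISpec) -> np.ndarray:
    """Values of voxels whose centres fall in the half-open ROI rectangle.

    The centre of pixel (i, j) sits at physical ((i+0.5)*s0, (j+0.5)*s1) um;
    missing-value (NaN) voxels are excluded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("ROI statistics operate on a 2-D slice or map")
    s0, s1 = spacing_um
    a0, a1 = roi.anchor
    i0 = int(np.ceil(a0 / s0 - 0.5))
    i1 = int(np.ceil((a0 + roi.height) / s0 - 0.5))
    j0 = int(np.ceil(a1 / s1 - 0.5))
    j1 = int(np.ceil((a1 + roi.width) / s1 - 0.5))
    i0c, j0c = max(i0, 0), max(j0, 0)
    i1c, j1c = min(i1, image.shape[0]), min(j1, image.shape[1])
    if i0c >= i1c or j0c >= j1c:
        raise ValueError(f"ROI {roi.label!r} does not intersect the image")
    block = image[i0c:i1c, j0c:j1c]
    return block[np.isfinite(block)]


def roi_statistics(image: np.ndarray, spacing_um: tuple[float, float],
                   roi: ROISpec, contrast_label: str = "") -> ROIStats:
    """Mean and sample SD (n-1 denominator) of the ROI's included voxels."""
    vals = roi_voxel_values(image, spacing_um, roi)
    if vals.size < 2:
        raise ValueError(
            f"ROI {roi.label!r} covers {vals.size} usable voxels; "
            "at least 2 are required"
        )
    return ROIStats(
        roi_label=roi.label,
        contrast_label=contrast_label,
        n=int(vals.size),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
    )


def normalize_to_control(stats_in: ROIStats, control: ROIStats) -> ROIStats:
    """Express an ROI mean relative to the control (agarose) ROI mean."""
    if stats_in.contrast_label != control.contrast_label:
        raise ValueError(
            "normalisation requires matching contrasts "
            f"({stats_in.contrast_label!r} vs {control.contrast_label!r})"
        )
    if control.mean == 0:
        raise ValueError("control ROI mean is zero; cannot normalise")
    rel = 1.0 if stats_in is control else stats_in.mean / control.mean
    return ROIStats(
        roi_label=stats_in.roi_label,
        contrast_label=stats_in.contrast_label,
        n=stats_in.n,
        mean=stats_in.mean,
        sd=stats_in.sd,
        relative_mean=rel,
    )


def unpaired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Student t-test with pooled variance, two-tailed p.

    Degenerate cases (both groups with zero variance) follow the recorded
    conventions: equal means give p = 1, unequal means give p = 0 with a
    warning; both are flagged by :func:`compare_rois`.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs n >= 2 (got {na} and {nb})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn(
            "both groups have zero variance with unequal means; "
            "p = 0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf"), 0.0
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def compare_rois(a: np.ndarray, b: np.ndarray, labels: tuple[str, str],
                 contrast_label: str, alpha: float = DEFAULT_ALPHA
                 ) -> ComparisonRecord:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
    t, p = unpaired_t_test(a, b)
    return ComparisonRecord(
        roi_a=labels[0],
        roi_b=labels[1],
        contrast_label=contrast_label,
        t=t,
        p=p,
        significant=bool(p < alpha),
        degenerate=degenerate,
    )


# The study's comparison design: pairs among the four tissue ROIs, the
# blood-vessel ROI, and the two sub-ROIs of tissue B, on every contrast.
STUDY_PAIRS = (
    ("#1", "#2"), ("#1", "#3"), ("#1", "#4"),
    ("#2", "#3"), ("#2", "#4"), ("#3", "#4"),
    ("#1", "BV"), ("#2", "BV"), ("#3", "BV"), ("#4", "BV"),
    ("#4a", "#1"), ("#4b", "#1"),
    ("#4a", "BV"), ("#4b", "BV"),
    ("#4a", "#4b"),
)


def pairwise_comparison_table(
    roi_values: dict[str, dict[str, np.ndarray]],
    pairs: tuple[tuple[str, str], ...] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[ComparisonRecord]:
    """Pairwise unpaired t-tests for requested ROI pairs on each contrast.

    ``roi_values`` maps contrast -> {roi label -> voxel values}.  Output
    ordering is deterministic (input order); duplicate pair requests are
    deduplicated with a warning.  Significance is flagged at ``alpha``
    without multiple-testing correction, matching the study design; a
    Bonferroni-corrected flag is available downstream as supplementary
    output.
    """
    records: list[ComparisonRecord] = []
    for contrast, by_roi in roi_values.items():
        if len(by_roi) < 2:
            raise ValueError(
                f"contrast {contrast!r} has fewer than 2 ROIs to compare"
            )
        use_pairs = pairs
        if use_pairs is None:
            labels = list(by_roi)
            use_pairs = tuple(
                (labels[i], labels[j])
                for i in range(len(labels))
                for j in range(i + 1, len(labels))
            )
        seen: set[frozenset[str]] = set()
        for pa, pb in use_pairs:
            for lab in (pa, pb):
                if lab not in by_roi:
                    raise KeyError(
                        f"unknown ROI label {lab!r} for contrast {contrast!r}"
                    )
            key = frozenset((pa, pb))
            if key in seen:
                warnings.warn(
                    f"duplicate comparison {pa} vs {pb} requested; skipping",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            seen.add(key)
            records.append(
                compare_rois(by_roi[pa], by_roi[pb], (pa, pb), contrast, alpha)
            )
    return records


def comparison_records_to_rows(records: list[ComparisonRecord],
                               n_comparisons: int | None = None,
                               alpha: float = DEFAULT_ALPHA) -> list[dict]:
    """CSV-ready rows; includes a supplementary Bonferroni column."""
    m = n_comparisons or max(len(records), 1)
    return [
        {
            "pair": f"{r.roi_a} versus {r.roi_b}",
            "contrast": r.contrast_label,
            "t": r.t,
            "p": r.p,
            "significant": r.significant,
            "significant_bonferroni": bool(r.p < alpha / m),
            "degenerate": r.degenerate,
        }
        for r in records
    ]
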