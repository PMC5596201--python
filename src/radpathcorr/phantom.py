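"""Synthetic multi-compartment specimen phantom.

The phantom stands in for a small formalin-fixed surgical specimen embedded
in agarose gel: tissue A is a hyperintense rim around a signal-void calcified
core, tissue B is a melanin-like blob (T1-hyperintense / T2-hypointense) with
T2*-dark hemosiderin sub-regions, a small blood-vessel profile sits in the
gel, and two pasta fiducial markers (a round rod cross-section and a letter
glyph) allow orientation.  The module produces

* piecewise-constant weighted contrasts (T1w / T2w / T2*w) plus Gaussian noise,
* a DWI series simulated from per-compartment ground-truth diffusion tensors
  under Rician noise (magnitude MR data),
* digital histology sections at several levels whose nucleus density is
  negatively coupled to the true mean diffusivity, related to MR space by a
  known affine that includes paraffin-processing shrinkage (up to 20%).

All randomness is reproducible from the spec seed; the zero-noise limits are
exactly piecewise constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AffineTransform2D, GradientTable, HistologyImage, MRVolume

LABELS = (
    "air",
    "agarose",
    "marker1",
    "marker2",
    "tissueA_rim",
    "tissueA_core",
    "tissueB",
    "tissueB_hemosiderin",
    "vessel",
)
SPECIMEN_LABELS = LABELS[1:]  # everything inside the container
TISSUE_LABELS = ("tissueA_rim", "tissueA_core", "tissueB", "tissueB_hemosiderin")

# 7x7 bitmap of the letter glyph used as the orientation marker (a "G").
_LETTER_G = np.array(
    [
        [1, 1, 1, 1, 1, 1, 0],
        [1, 0, 0, 0, 0, 0, 0],
        [1, 0, 0, 0, 0, 0, 0],
        [1, 0, 0, 1, 1, 1, 0],
        [1, 0, 0, 0, 0, 1, 0],
        [1, 0, 0, 0, 0, 1, 0],
        [1, 1, 1, 1, 1, 1, 0],
    ],
    dtype=bool,
)


def tetrahedral_directions() -> np.ndarray:
    """Six unit directions of the tetrahedron-derived encoding scheme.

    Normalised (±1, ±1, 0)-type edge vectors; together with one b=0 frame
    this is the default 7-frame acquisition.
    """
    dirs = np.array(
        [
            [1, 1, 0],
            [1, -1, 0],
            [1, 0, 1],
            [1, 0, -1],
            [0, 1, 1],
            [0, 1, -1],
        ],
        dtype=float,
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def default_gradient_table(bval: float = 1000.0) -> GradientTable:
    """One b=0 reference plus six tetrahedral directions at `bval` s/mm^2."""
    bvals = np.concatenate([[0.0], np.full(6, float(bval))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], tetrahedral_directions()])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def _iso(d: float) -> tuple[float, ...]:
    return (d, d, d, 0.0, 0.0, 0.0)


@dataclass
class Compartment:
    """One phantom compartment: geometry, MR appearance, true tensor, cells.

    ``s0_scale`` scales the non-diffusion-weighted signal (proton density);
    0 makes the compartment a signal void (air, dense calcification).
    """

    label: str
    geometry: dict
    intensities: dict[str, float]
    tensor: tuple[float, float, float, float, float, float]
    nucleus_density: float | None = None  # cells/tile; None -> coupled to MD
    s0_scale: float = 1.0

    def tensor_matrix(self) -> np.ndarray:
        dxx, dyy, dzz, dxy, dxz, dyz = self.tensor
        return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])

    def true_md(self) -> float:
        return float(sum(self.tensor[:3]) / 3.0)


def _default_compartments() -> list[Compartment]:
    return [
        Compartment(
            "air",
            {"type": "background"},
            {"T1w": 0.0, "T2w": 0.0, "T2star": 0.0},
            _iso(0.0),
            nucleus_density=0.0,
            s0_scale=0.0,
        ),
        Compartment(
            "agarose",  # 2% w/v gel filling the specimen container
            {"type": "disk", "center": (8.0, 8.0), "radius": 7.8},
            {"T1w": 200.0, "T2w": 900.0, "T2star": 700.0},
            _iso(2.0e-3),
            nucleus_density=0.0,
        ),
        Compartment(
            "tissueA_rim",
            {"type": "annulus", "center": (5.2, 5.2), "r_in": 1.4, "r_out": 2.6},
            {"T1w": 700.0, "T2w": 260.0, "T2star": 320.0},
            (0.9e-3, 0.65e-3, 0.55e-3, 0.0, 0.0, 0.0),
        ),
        Compartment(
            "tissueA_core",
            {"type": "disk", "center": (5.2, 5.2), "radius": 1.4},
            {"T1w": 4.0, "T2w": 4.0, "T2star": 4.0},
            _iso(0.25e-3),
            nucleus_density=0.0,  # dense calcification, acellular
            s0_scale=0.05,
        ),
        Compartment(
            "tissueB",
            {"type": "ellipse", "center": (10.4, 9.0), "radii": (2.4, 1.9),
             "angle_deg": 25.0},
            {"T1w": 760.0, "T2w": 240.0, "T2star": 330.0},
            (1.05e-3, 0.8e-3, 0.7e-3, 0.0, 0.0, 0.0),
        ),
        Compartment(
            "tissueB_hemosiderin",
            {"type": "disks", "centers": ((9.6, 8.2), (11.2, 9.8)),
             "radii": (0.5, 0.5)},
            {"T1w": 700.0, "T2w": 220.0, "T2star": 80.0},
            (0.7e-3, 0.55e-3, 0.55e-3, 0.0, 0.0, 0.0),
        ),
        Compartment(
            "vessel",
            {"type": "disk", "center": (11.4, 4.6), "radius": 0.5},
            {"T1w": 650.0, "T2w": 820.0, "T2star": 520.0},
            _iso(1.3e-3),
            nucleus_density=0.0,
        ),
        Compartment(
            "marker1",  # round pasta rod cross-section
            {"type": "disk", "center": (4.6, 11.6), "radius": 1.2},
            {"T1w": 400.0, "T2w": 350.0, "T2star": 380.0},
            _iso(1.0e-3),
            nucleus_density=0.0,
        ),
        Compartment(
            "marker2",  # letter-glyph pasta for slice orientation
            {"type": "letter", "center": (12.3, 12.5), "height": 2.0},
            {"T1w": 400.0, "T2w": 350.0, "T2star": 380.0},
            _iso(1.0e-3),
            nucleus_density=0.0,
        ),
    ]


@dataclass
class PhantomSpec:
    """Complete description of the simulated specimen and its acquisitions.

    Default geometry follows the ex vivo protocol: 100 um in-plane / 300 um
    slices for the weighted contrasts and 200 um in-plane for the DWI, over a
    16 mm field of view covering the specimen container (3 representative
    slices around the analysed one).
    """

    shape_weighted: tuple[int, int, int] = (160, 160, 3)
    spacing_weighted: tuple[float, float, float] = (0.1, 0.1, 0.3)
    shape_dwi: tuple[int, int, int] = (80, 80, 3)
    spacing_dwi: tuple[float, float, float] = (0.2, 0.2, 0.3)
    compartments: list[Compartment] = field(default_factory=_default_compartments)
    noise_sd_weighted: float = 15.0
    rician_sigma_dwi: float = 25.0
    s0: float = 1000.0
    bval: float = 1000.0
    # cellularity coupling: density per tile = c0 - c1 * MD + eps
    coupling_intercept: float = 75.0       # c0, cells per 100x100 um tile
    coupling_slope: float = 7.0e4          # c1, cells per tile per (mm^2/s)
    coupling_eps_sd: float = 4.0           # sd of the extra Gaussian jitter
    shrinkage: float = 0.8                 # paraffin shrinkage (linear factor)
    hist_pixel_size_um: float = 5.0
    hist_rotation_deg: float = 0.0
    hist_levels: tuple[int, ...] = (1, 11, 25, 35)
    n_intervals: int = 35
    tile_um: float = 100.0
    nucleus_radius_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.7 <= self.shrinkage <= 1.0):
            raise ValueError(
                f"shrinkage {self.shrinkage} outside the supported band "
                "[0.7, 1.0] (processing shrinks tissue by up to 20-30%)"
            )
        if self.rician_sigma_dwi < 0 or self.noise_sd_weighted < 0:
            raise ValueError("noise levels cannot be negative")
        if self.coupling_slope < 0:
            raise ValueError("coupling slope c1 must be >= 0")
        if self.coupling_intercept < 0:
            raise ValueError("coupling intercept c0 must be >= 0")
        for comp in self.compartments:
            evals = np.linalg.eigvalsh(comp.tensor_matrix())
            if np.any(evals < 0):
                raise ValueError(
                    f"compartment {comp.label!r} tensor has negative eigenvalue"
                )
            if comp.nucleus_density is not None and comp.nucleus_density < 0:
                raise ValueError("nucleus densities must be >= 0")

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (
            self.shape_weighted[0] * self.spacing_weighted[0],
            self.shape_weighted[1] * self.spacing_weighted[1],
        )

    def label_index(self, label: str) -> int:
        return LABELS.index(label)

    def compartment(self, label: str) -> Compartment:
        for comp in self.compartments:
            if comp.label == label:
                return comp
        raise KeyError(label)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def expected_density(self, md: np.ndarray | float) -> np.ndarray:
        """Mean nucleus count per tile implied by the linear MD coupling."""
        return np.maximum(
            self.coupling_intercept - self.coupling_slope * np.asarray(md), 0.0
        )


# ---------------------------------------------------------------------------
# geometry rasterisation (physical mm coordinates, in-plane)
# ---------------------------------------------------------------------------

def _geometry_mask(geom: dict, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    kind = geom["type"]
    if kind == "background":
        return np.ones_like(p0, dtype=bool)
    if kind == "disk":
        c = geom["center"]
        r = float(geom["radius"])
        if r <= 0:
            raise ValueError("degenerate geometry: non-positive disk radius")
        return (p0 - c[0]) ** 2 + (p1 - c[1]) ** 2 <= r**2
    if kind == "disks":
        mask = np.zeros_like(p0, dtype=bool)
        for c, r in zip(geom["centers"], geom["radii"]):
            if r <= 0:
                raise ValueError("degenerate geometry: non-positive disk radius")
            mask |= (p0 - c[0]) ** 2 + (p1 - c[1]) ** 2 <= float(r) ** 2
        return mask
    if kind == "annulus":
        c = geom["center"]
        r_in, r_out = float(geom["r_in"]), float(geom["r_out"])
        if not 0 <= r_in < r_out:
            raise ValueError("degenerate geometry: annulus needs 0 <= r_in < r_out")
        d2 = (p0 - c[0]) ** 2 + (p1 - c[1]) ** 2
        return (d2 >= r_in**2) & (d2 <= r_out**2)
    if kind == "ellipse":
        c = geom["center"]
        a, b = (float(r) for r in geom["radii"])
        if a <= 0 or b <= 0:
            raise ValueError("degenerate geometry: non-positive ellipse radius")
        th = np.deg2rad(float(geom.get("angle_deg", 0.0)))
        d0, d1 = p0 - c[0], p1 - c[1]
        u = np.cos(th) * d0 + np.sin(th) * d1
        v = -np.sin(th) * d0 + np.cos(th) * d1
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if kind == "letter":
        c = geom["center"]
        h = float(geom["height"])
        if h <= 0:
            raise ValueError("degenerate geometry: non-positive letter height")
        n = _LETTER_G.shape[0]
        cell = h / n
        i = np.floor((p0 - (c[0] - h / 2)) / cell).astype(int)
        j = np.floor((p1 - (c[1] - h / 2)) / cell).astype(int)
        inside = (i >= 0) & (i < n) & (j >= 0) & (j < n)
        mask = np.zeros_like(p0, dtype=bool)
        ii, jj = i[inside], j[inside]
        mask[inside] = _LETTER_G[ii, jj]
        return mask
    raise ValueError(f"unknown geometry primitive {kind!r}")


def _geometry_bounds(geom: dict) -> tuple[float, float, float, float] | None:
    """Conservative (lo0, hi0, lo1, hi1) bounding box in mm, None = unbounded."""
    kind = geom["type"]
    if kind == "background":
        return None
    if kind == "disk":
        c, r = geom["center"], float(geom["radius"])
        return (c[0] - r, c[0] + r, c[1] - r, c[1] + r)
    if kind == "disks":
        boxes = [
            (c[0] - r, c[0] + r, c[1] - r, c[1] + r)
            for c, r in zip(geom["centers"], geom["radii"])
        ]
        los0, his0, los1, his1 = zip(*boxes)
        return (min(los0), max(his0), min(los1), max(his1))
    if kind == "annulus":
        c, r = geom["center"], float(geom["r_out"])
        return (c[0] - r, c[0] + r, c[1] - r, c[1] + r)
    if kind == "ellipse":
        c = geom["center"]
        r = max(float(x) for x in geom["radii"])
        return (c[0] - r, c[0] + r, c[1] - r, c[1] + r)
    if kind == "letter":
        c, h = geom["center"], float(geom["height"])
        return (c[0] - h / 2, c[0] + h / 2, c[1] - h / 2, c[1] + h / 2)
    raise ValueError(f"unknown geometry primitive {kind!r}")


def label_at_points(spec: PhantomSpec, p0: np.ndarray,
                    p1: np.ndarray) -> np.ndarray:
    """Compartment index at physical in-plane positions (mm).

    Compartments are painted in spec order with later entries overwriting
    earlier ones, except that markers are painted last so they remain
    visible fiducials.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    labels = np.zeros(p0.shape, dtype=np.int8)
    ordered = sorted(
        spec.compartments,
        key=lambda c: 1 if c.label.startswith("marker") else 0,
    )
    for comp in ordered:
        mask = _geometry_mask(comp.geometry, p0, p1)
        labels[mask] = spec.label_index(comp.label)
    return labels


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Oracle outputs of the generator: label maps, true tensors/MD, affine."""

    spec: PhantomSpec
    label_weighted: np.ndarray
    label_dwi: np.ndarray
    tensor_dwi: np.ndarray      # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    md_dwi: np.ndarray
    affine_mr_mm_to_hist_px: AffineTransform2D
    affine_md_px_to_hist_px: AffineTransform2D

    @property
    def hist_shape(self) -> tuple[int, int]:
        fov = self.spec.fov_mm
        px = self.spec.hist_pixel_size_um / 1000.0
        return (int(round(fov[0] / px)), int(round(fov[1] / px)))

    def tissue_mask_dwi(self) -> np.ndarray:
        idx = [self.spec.label_index(lab) for lab in TISSUE_LABELS]
        return np.isin(self.label_dwi, idx)

    def background_mask_dwi(self) -> np.ndarray:
        return self.label_dwi == self.spec.label_index("agarose")


def _hist_affines(spec: PhantomSpec) -> tuple[AffineTransform2D, AffineTransform2D]:
    """Ground-truth mappings MR (mm) -> histology (px), MD px -> histology px.

    Pixel coordinates are array-index coordinates (pixel i centred at i);
    the physical position of index i is (i + 0.5) * pixel_size from the
    image corner.  The shrunken specimen is centred in the histology
    template.
    """
    s = spec.shrinkage
    th = np.deg2rad(spec.hist_rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    px_mm = spec.hist_pixel_size_um / 1000.0
    fov = np.asarray(spec.fov_mm)
    hist_shape = np.round(fov / px_mm)
    lin = s * rot / px_mm
    trans = hist_shape / 2.0 - lin @ (fov / 2.0) - 0.5
    mr_mm_to_hist = AffineTransform2D(lin, trans)
    # MD pixel index -> mm: p_mm = (p_idx + 0.5) * spacing (in plane)
    sp = np.diag(spec.spacing_dwi[:2])
    md_px_to_hist = AffineTransform2D(
        lin @ sp, lin @ sp @ np.array([0.5, 0.5]) + trans
    )
    return mr_mm_to_hist, md_px_to_hist


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterise the compartment geometry and assemble the ground truth.

    Deterministic: geometry carries no randomness.  Raises if a compartment
    does not fit in the field of view or the two fiducial markers overlap.
    """
    fov = spec.fov_mm
    for comp in spec.compartments:
        box = _geometry_bounds(comp.geometry)
        if box is None:
            continue
        lo0, hi0, lo1, hi1 = box
        if lo0 < 0 or lo1 < 0 or hi0 > fov[0] or hi1 > fov[1]:
            raise ValueError(
                f"compartment {comp.label!r} extends outside the "
                f"{fov[0]:g}x{fov[1]:g} mm field of view"
            )

    def grid_centers(shape, spacing):
        c0 = (np.arange(shape[0]) + 0.5) * spacing[0]
        c1 = (np.arange(shape[1]) + 0.5) * spacing[1]
        return np.meshgrid(c0, c1, indexing="ij")

    p0w, p1w = grid_centers(spec.shape_weighted, spec.spacing_weighted)
    slice_w = label_at_points(spec, p0w, p1w)
    label_weighted = np.repeat(slice_w[:, :, None], spec.shape_weighted[2], axis=2)

    # marker overlap check on the fine grid
    m1 = spec.label_index("marker1")
    m2 = spec.label_index("marker2")
    g1 = _geometry_mask(spec.compartment("marker1").geometry, p0w, p1w)
    g2 = _geometry_mask(spec.compartment("marker2").geometry, p0w, p1w)
    if np.any(g1 & g2):
        raise ValueError("the two fiducial markers overlap")

    p0d, p1d = grid_centers(spec.shape_dwi, spec.spacing_dwi)
    slice_d = label_at_points(spec, p0d, p1d)
    label_dwi = np.repeat(slice_d[:, :, None], spec.shape_dwi[2], axis=2)

    tensor_lut = np.zeros((len(LABELS), 6))
    for comp in spec.compartments:
        tensor_lut[spec.label_index(comp.label)] = comp.tensor
    tensor_dwi = tensor_lut[label_dwi]
    md_dwi = tensor_dwi[..., :3].sum(axis=-1) / 3.0

    aff_mm, aff_md = _hist_affines(spec)
    return GroundTruth(
        spec=spec,
        label_weighted=label_weighted,
        label_dwi=label_dwi,
        tensor_dwi=tensor_dwi,
        md_dwi=md_dwi,
        affine_mr_mm_to_hist_px=aff_mm,
        affine_md_px_to_hist_px=aff_md,
    )


# ---------------------------------------------------------------------------
# weighted contrasts
# ---------------------------------------------------------------------------

def render_weighted_images(
    gt: GroundTruth, spec: PhantomSpec | None = None
) -> dict[str, MRVolume]:
    """Piecewise-constant T1w/T2w/T2*w volumes plus seeded Gaussian noise."""
    spec = spec or gt.spec
    out: dict[str, MRVolume] = {}
    present = np.unique(gt.label_weighted)
    for k, contrast in enumerate(("T1w", "T2w", "T2star")):
        lut = np.zeros(len(LABELS))
        defined = set()
        for comp in spec.compartments:
            if contrast not in comp.intensities:
                raise ValueError(
                    f"compartment {comp.label!r} has no intensity entry for "
                    f"contrast {contrast}"
                )
            lut[spec.label_index(comp.label)] = comp.intensities[contrast]
            defined.add(spec.label_index(comp.label))
        missing = [int(i) for i in present if int(i) not in defined]
        if missing:
            raise ValueError(
                f"labels {missing} present in phantom but not specified"
            )
        vox = lut[gt.label_weighted].astype(float)
        if spec.noise_sd_weighted > 0:
            rng = spec.rng(100 + k)
            vox = vox + rng.normal(0.0, spec.noise_sd_weighted, size=vox.shape)
        out[contrast] = MRVolume(
            voxels=vox,
            spacing=spec.spacing_weighted,
            contrast_label=contrast,
        )
    return out


# ---------------------------------------------------------------------------
# DWI simulation
# ---------------------------------------------------------------------------

def tensor_design_vector(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows q_i with  g'Dg * b = q_i . d6  for d6 = (Dxx,Dyy,Dzz,Dxy,Dxz,Dyz)."""
    b = np.asarray(bvals, dtype=float)[:, None]
    g = np.asarray(bvecs, dtype=float)
    return b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex signal with Gaussian noise on both channels."""
    if sigma < 0:
        raise ValueError("Rician sigma must be >= 0")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    n1 = rng.normal(0.0, sigma, size=np.shape(signal))
    n2 = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_dwi(
    gt: GroundTruth,
    table: GradientTable,
    s0: float | None = None,
    sigma: float | None = None,
    seed: int | None = None,
) -> list[MRVolume]:
    """Simulate the DWI series: S_i = S0 exp(-b_i g_i' D g_i) + Rician noise.

    One volume per gradient-table entry, in table order.  ``sigma = 0`` gives
    the exact noiseless signals.
    """
    spec = gt.spec
    s0 = spec.s0 if s0 is None else float(s0)
    sigma = spec.rician_sigma_dwi if sigma is None else float(sigma)
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    if sigma < 0:
        raise ValueError("Rician sigma must be >= 0")
    evals = np.linalg.eigvalsh(_d6_to_mat(gt.tensor_dwi))
    if np.any(evals < -1e-15):
        raise ValueError("ground-truth tensors must be positive semi-definite")
    q = tensor_design_vector(table.bvals, table.bvecs)  # (F, 6)
    rng = (
        np.random.default_rng([int(seed), 200])
        if seed is not None
        else spec.rng(200)
    )
    scale_lut = np.zeros(len(LABELS))
    for comp in spec.compartments:
        scale_lut[spec.label_index(comp.label)] = comp.s0_scale
    s0_map = s0 * scale_lut[gt.label_dwi]
    frames: list[MRVolume] = []
    for i in range(len(table)):
        atten = np.einsum("...k,k->...", gt.tensor_dwi, q[i])
        signal = s0_map * np.exp(-atten)
        noisy = add_rician_noise(signal, sigma, rng)
        frames.append(
            MRVolume(
                voxels=noisy,
                spacing=spec.spacing_dwi,
                contrast_label="b0" if table.bvals[i] == 0 else "DWI",
            )
        )
    return frames


def _d6_to_mat(d6: np.ndarray) -> np.ndarray:
    d6 = np.asarray(d6, dtype=float)
    out = np.zeros(d6.shape[:-1] + (3, 3))
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


# ---------------------------------------------------------------------------
# histology rendering
# ---------------------------------------------------------------------------

_BG_VALUE = {
    "air": 250,  # bare glass slide outside the section
    "agarose": 242,
    "marker1": 170,
    "marker2": 170,
    "tissueA_rim": 225,
    "tissueA_core": 205,
    "tissueB": 225,
    "tissueB_hemosiderin": 222,
    "vessel": 215,
}
_NUCLEUS_VALUE = 60


def hist_label_image(gt: GroundTruth) -> np.ndarray:
    """Compartment index per histology pixel, via the ground-truth affine."""
    spec = gt.spec
    h0, h1 = gt.hist_shape
    inv = gt.affine_mr_mm_to_hist_px.inverse()
    c0, c1 = np.meshgrid(
        np.arange(h0, dtype=np.float32),
        np.arange(h1, dtype=np.float32),
        indexing="ij",
    )
    pts = inv.apply(np.column_stack([c0.ravel(), c1.ravel()]))
    fov = spec.fov_mm
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] < fov[0])
        & (pts[:, 1] >= 0) & (pts[:, 1] < fov[1])
    )
    labels = np.zeros(pts.shape[0], dtype=np.int8)
    labels[inside] = label_at_points(spec, pts[inside, 0], pts[inside, 1])
    return labels.reshape(h0, h1)


def render_histology(
    gt: GroundTruth, spec: PhantomSpec | None = None
) -> tuple[list[HistologyImage], np.ndarray, np.ndarray]:
    """Render one histology section per level, plus per-tile true counts.

    Returns ``(images, true_counts, label_image)`` where ``true_counts`` has
    shape ``(n_levels, n_tiles0, n_tiles1)`` and holds the Poisson-sampled
    nucleus counts actually drawn in each 100x100 um tile of each level.
    Nucleus placement noise is independent across levels; the geometry (and
    therefore the label image) is shared.
    """
    spec = spec or gt.spec
    if spec.coupling_slope < 0:
        raise ValueError("coupling slope c1 must be >= 0")
    if spec.coupling_intercept < 0:
        raise ValueError("coupling intercept c0 must be >= 0")
    labels = hist_label_image(gt)
    base = np.full(labels.shape, _BG_VALUE["air"], dtype=np.uint8)
    for name, value in _BG_VALUE.items():
        base[labels == spec.label_index(name)] = value

    tile_px = spec.tile_um / spec.hist_pixel_size_um
    n0 = int(np.floor(labels.shape[0] / tile_px))
    n1 = int(np.floor(labels.shape[1] / tile_px))

    # expected density per tile from the compartment at the tile centre
    # (tile centre in index coordinates: continuous centre minus half pixel)
    centers0 = (np.arange(n0) + 0.5) * tile_px - 0.5
    centers1 = (np.arange(n1) + 0.5) * tile_px - 0.5
    cc0, cc1 = np.meshgrid(centers0, centers1, indexing="ij")
    inv = gt.affine_mr_mm_to_hist_px.inverse()
    pts_mm = inv.apply(np.column_stack([cc0.ravel(), cc1.ravel()]))
    fov = spec.fov_mm
    inside = (
        (pts_mm[:, 0] >= 0) & (pts_mm[:, 0] < fov[0])
        & (pts_mm[:, 1] >= 0) & (pts_mm[:, 1] < fov[1])
    )
    tile_label = np.zeros(pts_mm.shape[0], dtype=np.int8)
    tile_label[inside] = label_at_points(
        spec, pts_mm[inside, 0], pts_mm[inside, 1]
    )
    density_lut = np.zeros(len(LABELS))
    for comp in spec.compartments:
        if comp.nucleus_density is not None:
            d = comp.nucleus_density
        else:
            d = float(spec.expected_density(comp.true_md()))
        density_lut[spec.label_index(comp.label)] = d
    tile_mean = density_lut[tile_label].reshape(n0, n1)

    r_px = max(1, int(round(spec.nucleus_radius_um / spec.hist_pixel_size_um)))
    dr, dc = np.meshgrid(
        np.arange(-r_px, r_px + 1), np.arange(-r_px, r_px + 1), indexing="ij"
    )
    stencil = np.column_stack(
        [dr.ravel(), dc.ravel()]
    )[(dr**2 + dc**2).ravel() <= r_px**2]

    images: list[HistologyImage] = []
    true_counts = np.zeros((len(spec.hist_levels), n0, n1))
    for li, level in enumerate(spec.hist_levels):
        rng = spec.rng(300 + int(level))
        mean = tile_mean
        if spec.coupling_eps_sd > 0:
            mean = np.maximum(
                mean + rng.normal(0.0, spec.coupling_eps_sd, size=mean.shape)
                * (tile_mean > 0),
                0.0,
            )
        counts = rng.poisson(mean)
        true_counts[li] = counts
        img = base.copy()
        # draw nuclei: uniform positions within each occupied tile
        occ = np.argwhere(counts > 0)
        if occ.size:
            reps = counts[counts > 0]
            tiles = np.repeat(occ, reps, axis=0)
            u = rng.random((tiles.shape[0], 2))
            pos = (tiles + u) * tile_px
            rr = np.floor(pos[:, 0]).astype(int)  # continuous -> pixel index
            cc = np.floor(pos[:, 1]).astype(int)
            for d0, d1 in stencil:
                r = np.clip(rr + d0, 0, img.shape[0] - 1)
                c = np.clip(cc + d1, 0, img.shape[1] - 1)
                img[r, c] = _NUCLEUS_VALUE
        images.append(
            HistologyImage(
                pixels=img,
                pixel_size=spec.hist_pixel_size_um,
                level_index=int(level),
            )
        )
    return images, true_counts, labels


# ---------------------------------------------------------------------------
# coupled MD / count sampling (generative coupling model)
# ---------------------------------------------------------------------------

def coupling_noise_sd_for_target_rho(
    md_values: np.ndarray, c0: float, c1: float, rho: float
) -> float:
    """Jitter SD that makes the true MD-count Pearson correlation ``-rho``.

    Counts are Poisson with mean ``c0 - c1 * MD + eps``; by the law of total
    variance the population correlation between MD and count is
    ``-c1 sd(MD) / sqrt(c1^2 var(MD) + E[mu] + eps_sd^2)``.  Solving for the
    jitter variance gives the returned SD.  Raises if the target magnitude is
    unattainable even at zero jitter (Poisson noise alone too large).
    """
    md = np.asarray(md_values, dtype=float)
    var_md = md.var()
    mean_mu = float(np.mean(c0 - c1 * md))
    if np.any(c0 - c1 * md < 0):
        raise ValueError("coupling clamps to zero inside the MD range; "
                         "the linear correlation target is ill-posed")
    need = c1**2 * var_md * (1.0 - rho**2) / rho**2 - mean_mu
    if need < 0:
        raise ValueError(
            f"target |rho|={rho} unattainable: Poisson noise alone caps the "
            f"correlation at {np.sqrt(c1**2 * var_md / (c1**2 * var_md + mean_mu)):.3f}"
        )
    return float(np.sqrt(need))


def sample_coupled_counts(
    md_values: np.ndarray,
    c0: float,
    c1: float,
    eps_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw nucleus counts from the generative coupling at given MD values."""
    md = np.asarray(md_values, dtype=float)
    mean = np.maximum(c0 - c1 * md + rng.normal(0.0, eps_sd, size=md.shape), 0.0)
    return rng.poisson(mean).astype(float)
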