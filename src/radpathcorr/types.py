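"""Shared spatial/domain containers used throughout the pipeline.

Conventions
-----------
* MR volumes are 3-D arrays indexed ``[x, y, z]`` with per-axis spacing in
  millimetres; the physical position of voxel ``(0, 0, 0)``'s corner is the
  origin, and voxel ``i`` covers the half-open interval ``[i*s, (i+1)*s)``
  along its axis (centre at ``(i + 0.5) * s``).
* 2-D images (histology, single MR slices, maps) are arrays indexed
  ``[axis0, axis1]`` and all 2-D points are ``(p0, p1)`` float coordinates in
  that same array-index order — there is no separate x/y convention to flip.
* Physical 2-D coordinates (landmarks in micrometres, ROI anchors) are the
  pixel-index coordinates scaled by the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTRAST_LABELS = ("T1w", "T2w", "T2star", "DWI", "b0", "MD")


@dataclass
class MRVolume:
    """A gridded scalar MR image: one weighted contrast or one DWI frame.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    spacing : tuple of 3 floats
        Per-axis voxel size in mm; all entries must be positive.
    origin : tuple of 3 floats
        Physical position (mm) of voxel (0, 0, 0).
    contrast_label : str
        One of ``CONTRAST_LABELS``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contrast_label: str = "T2w"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"MRVolume requires a 3-D grid, got {self.voxels.ndim} axes"
            )
        if any(n < 1 for n in self.voxels.shape):
            raise ValueError("MRVolume grid needs at least 1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive entries, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("MRVolume voxels must be finite")
        if self.contrast_label not in CONTRAST_LABELS:
            raise ValueError(
                f"unknown contrast label {self.contrast_label!r}; "
                f"expected one of {CONTRAST_LABELS}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def physical_extent(self) -> np.ndarray:
        """Half-open physical bounds, rows = (min, max), cols = axes (mm)."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return np.stack([lo, hi])


MIN_DWI_FRAMES = 7  # one b=0 reference plus six weighted directions


@dataclass
class GradientTable:
    """Per-frame diffusion weighting: b-factor (s/mm^2) and unit direction."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ValueError("bvals and bvecs disagree in frame count")
        if np.any(self.bvals < 0):
            raise ValueError("b-factors must be non-negative")
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(norms - 1.0) > 1e-6))
            raise ValueError(
                "weighted gradient directions must be unit vectors "
                f"(|g| = {norms[bad]:.6g} for one weighted frame)"
            )

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def n_weighted(self) -> int:
        return int(np.sum(self.bvals > 0))

    def validate_for_tensor_fit(self) -> None:
        """A tensor fit needs >= 1 reference frame and >= 6 weighted frames."""
        if self.n_b0 < 1:
            raise ValueError("no reference frame: gradient table has no b=0 entry")
        if self.n_weighted < 6:
            raise ValueError(
                f"tensor fit needs at least 6 weighted frames (7 total incl. b=0); "
                f"got {self.n_weighted} weighted"
            )


@dataclass
class LandmarkSet:
    """Ordered 2-D fiducial coordinates (pixels) on a named image frame."""

    points: np.ndarray
    frame: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class AffineTransform2D:
    """2-D affine map ``p -> matrix @ p + translation`` in pixel coordinates."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.translation)

    def compose(self, inner: "AffineTransform2D") -> "AffineTransform2D":
        """Return the transform equivalent to ``self(inner(p))``."""
        return AffineTransform2D(
            self.matrix @ inner.matrix,
            self.matrix @ inner.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def scaling(cls, factor: float) -> "AffineTransform2D":
        return cls(np.eye(2) * float(factor), np.zeros(2))


@dataclass
class RigidTransform3D:
    """3-D rotation + translation (mm), mapping moving to reference space."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class ROISpec:
    """Axis-aligned rectangular region of interest in physical micrometres.

    ``anchor`` is the low corner ``(p0, p1)`` in the image frame's physical
    coordinates; the ROI covers the half-open rectangle
    ``[anchor, anchor + (height, width))`` along (axis0, axis1).
    """

    anchor: tuple[float, float]
    height: float
    width: float
    label: str = ""
    image_frame: str = ""

    def __post_init__(self) -> None:
        self.anchor = (float(self.anchor[0]), float(self.anchor[1]))
        self.height = float(self.height)
        self.width = float(self.width)
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"ROI {self.label!r} needs positive width and height")
        if not np.all(np.isfinite(self.anchor)):
            raise ValueError(f"ROI {self.label!r} anchor must be finite")

    def corners(self) -> np.ndarray:
        """The four corner points, shape (4, 2), in physical units."""
        a0, a1 = self.anchor
        return np.array(
            [
                [a0, a1],
                [a0 + self.height, a1],
                [a0, a1 + self.width],
                [a0 + self.height, a1 + self.width],
            ]
        )

    @property
    def area(self) -> float:
        return self.height * self.width


@dataclass
class HistologyImage:
    """A digitised histology section (grayscale or RGB) with pixel size."""

    pixels: np.ndarray
    pixel_size: float  # micrometres per pixel
    level_index: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("histology image must be 2-D grayscale or RGB")
        self.pixel_size = float(self.pixel_size)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.level_index = int(self.level_index)
        if self.level_index < 1:
            raise ValueError("level_index counts sections from 1")

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class RegistrationResult:
    """Outcome of an intensity- or landmark-driven registration."""

    transform: object  # AffineTransform2D, RigidTransform3D or 3-D affine dict
    similarity: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    iterations: int = 0
    success: bool = True
    resampled: object = None

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float).ravel()
        if np.any(self.residuals < 0):
            raise ValueError("residual distances cannot be negative")
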