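"""Diffusion tensor estimation from a registered DWI series.

Per voxel the log-linearised signal model

    ln S_i = ln S0 - b_i g_i' D g_i

is solved by weighted linear least squares with weights w_i = (S_i / sigma)^2
(the weighting appropriate for log-transformed magnitude data).  Voxels whose
fitted tensor is indefinite are re-solved with D reparameterised through a
modified Cholesky factorisation D = L L' (L lower-triangular), which
constrains the result to be positive (semi-)definite; the refit minimises the
same weighted objective and is initialised at the eigenvalue-clamped
projection of the unconstrained solution.  Mean diffusivity is the eigenvalue
average, identical to trace(D)/3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.optimize import minimize

from .phantom import tensor_design_vector
from .types import GradientTable, MRVolume, RegistrationResult, RigidTransform3D

logger = logging.getLogger(__name__)

FLAG_OK = 0
FLAG_CONSTRAINED_REFIT = 1
FLAG_EXCLUDED = 2

_RAYLEIGH_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DiffusionTensorMap:
    """Per-voxel symmetric tensor (6 unique components), S0 and fit flags.

    ``tensors[..., :]`` is ordered (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm^2/s.
    """

    tensors: np.ndarray
    s0: np.ndarray
    flags: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.shape[-1] != 6:
            raise ValueError("tensor map stores 6 unique components per voxel")
        self.s0 = np.asarray(self.s0, dtype=float)
        self.flags = np.asarray(self.flags, dtype=np.int8)

    def matrices(self) -> np.ndarray:
        d = self.tensors
        out = np.zeros(d.shape[:-1] + (3, 3))
        out[..., 0, 0] = d[..., 0]
        out[..., 1, 1] = d[..., 1]
        out[..., 2, 2] = d[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
        return out

    def eigenvalues(self) -> np.ndarray:
        """Sorted eigenvalues, descending (lambda1 >= lambda2 >= lambda3)."""
        ev = np.linalg.eigvalsh(self.matrices())
        return ev[..., ::-1]


@dataclass
class ScalarMap:
    """A per-voxel scalar (e.g. MD in mm^2/s) on the DWI grid.

    ``display_scale`` is applied only when rendering (MD maps are
    conventionally displayed x1000); stored values are never altered.
    """

    values: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    display_scale: float = 1000.0
    name: str = "MD"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def display_values(self) -> np.ndarray:
        return self.values * self.display_scale


# ---------------------------------------------------------------------------
# noise estimation
# ---------------------------------------------------------------------------

def estimate_noise_sigma(b0: MRVolume | np.ndarray, background_mask: np.ndarray,
                         min_voxels: int = 50) -> float:
    """Rician noise SD from a signal-free background region of the b=0 image.

    In background air/gel-free voxels the magnitude signal is Rayleigh
    distributed with SD sigma * sqrt(2 - pi/2); the raw standard deviation is
    divided by that factor.  Deterministic given the mask.
    """
    data = b0.voxels if isinstance(b0, MRVolume) else np.asarray(b0)
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError("mask shape must match the b0 volume")
    n = int(mask.sum())
    if n < min_voxels:
        raise ValueError(
            f"background mask has {n} voxels; at least {min_voxels} needed "
            "for a stable noise estimate"
        )
    return float(np.std(data[mask]) / _RAYLEIGH_FACTOR)


# ---------------------------------------------------------------------------
# WLLS tensor fit
# ---------------------------------------------------------------------------

def _design_matrix(table: GradientTable) -> np.ndarray:
    """F x 7 design: column 0 multiplies ln S0, columns 1..6 the tensor."""
    q = tensor_design_vector(table.bvals, table.bvecs)
    return np.column_stack([np.ones(len(table)), -q])


def _check_design(table: GradientTable) -> np.ndarray:
    table.validate_for_tensor_fit()
    X = _design_matrix(table)
    if np.linalg.matrix_rank(X) < 7:
        with np.printoptions(precision=3, suppress=True):
            dirs = str(table.bvecs[table.bvals > 0])
        raise ValueError(
            "rank-deficient design: the weighted gradient directions do not "
            f"span the 6 tensor degrees of freedom; directions were\n{dirs}"
        )
    return X


def fit_tensor_wlls(
    signals: np.ndarray, table: GradientTable, sigma: float
) -> tuple[np.ndarray, float, int]:
    """Single-voxel weighted linear least squares tensor fit.

    Returns ``(d6, s0, flag)`` with d6 = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
    Weights are (S_i/sigma)^2 on each log-signal equation, one pass, using
    the observed signals.  Voxels with any non-positive signal are excluded
    (the log transform is undefined there).
    """
    if sigma <= 0:
        raise ValueError("noise sigma must be positive")
    signals = np.asarray(signals, dtype=float).ravel()
    X = _check_design(table)
    if signals.shape[0] != len(table):
        raise ValueError("signal count does not match the gradient table")
    if np.any(signals <= 0):
        return np.zeros(6), float("nan"), FLAG_EXCLUDED
    y = np.log(signals)
    sw = signals / sigma  # sqrt of the weights
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta[1:], float(np.exp(beta[0])), FLAG_OK


def fit_tensor_map(
    frames: list[MRVolume] | np.ndarray,
    table: GradientTable,
    sigma: float,
    mask: np.ndarray | None = None,
) -> DiffusionTensorMap:
    """Vectorised WLLS fit over a whole DWI volume series."""
    if sigma <= 0:
        raise ValueError("noise sigma must be positive")
    X = _check_design(table)
    if isinstance(frames, (list, tuple)):
        spacing = frames[0].spacing
        data = np.stack([f.voxels for f in frames], axis=-1)
    else:
        data = np.asarray(frames, dtype=float)
        spacing = (1.0, 1.0, 1.0)
    if data.shape[-1] != len(table):
        raise ValueError("frame count does not match the gradient table")
    shape = data.shape[:-1]
    S = data.reshape(-1, len(table))
    fit_mask = np.all(S > 0, axis=1)
    if mask is not None:
        fit_mask &= np.asarray(mask, dtype=bool).ravel()

    tensors = np.zeros((S.shape[0], 6))
    s0 = np.full(S.shape[0], np.nan)
    flags = np.full(S.shape[0], FLAG_EXCLUDED, dtype=np.int8)

    Sv = S[fit_mask]
    w = (Sv / sigma) ** 2
    y = np.log(Sv)
    # weighted normal equations, batched over voxels
    A = np.einsum("fi,vf,fj->vij", X, w, X, optimize=True)
    b = np.einsum("fi,vf->vi", X, w * y, optimize=True)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    tensors[fit_mask] = beta[:, 1:]
    s0[fit_mask] = np.exp(beta[:, 0])
    flags[fit_mask] = FLAG_OK
    return DiffusionTensorMap(
        tensors=tensors.reshape(shape + (6,)),
        s0=s0.reshape(shape),
        flags=flags.reshape(shape),
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# positive-definiteness constraint (modified Cholesky refit)
# ---------------------------------------------------------------------------

def _d6_to_mat(d6: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = d6
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def _mat_to_d6(m: np.ndarray) -> np.ndarray:
    return np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])


def _clamped_projection(d6: np.ndarray) -> np.ndarray:
    evals, vecs = np.linalg.eigh(_d6_to_mat(d6))
    evals = np.maximum(evals, 0.0)
    return _mat_to_d6((vecs * evals) @ vecs.T)


def _chol_lower(d6: np.ndarray) -> np.ndarray:
    """Lower-triangular L with L L' ~= D, tolerant of a singular PSD D."""
    mat = _d6_to_mat(d6)
    scale = max(np.trace(mat), 1e-12)
    jitter = 0.0
    for _ in range(20):
        try:
            L = np.linalg.cholesky(mat + jitter * np.eye(3))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-16 * scale)
    else:  # pragma: no cover - defensive
        L = np.diag(np.sqrt(np.maximum(np.diag(mat), 0.0)))
    L = L.copy()
    L[np.diag_indices(3)] += 1e-12
    return L


def _L_to_d6(theta: np.ndarray) -> np.ndarray:
    a, b, c, d, e, f = theta
    return np.array(
        [a * a, b * b + c * c, d * d + e * e + f * f,
         a * b, a * d, b * d + c * e]
    )


def _weighted_objective(d6: np.ndarray, q: np.ndarray, y: np.ndarray,
                        w: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Weighted residual with ln S0 profiled out; also returns dF/dd6."""
    # model: y_i = beta0 - q_i . d6
    beta0 = np.sum(w * (y + q @ d6)) / np.sum(w)
    r = y - (beta0 - q @ d6)
    f = float(np.sum(w * r**2))
    grad_d6 = 2.0 * (w * r) @ q
    return f, grad_d6, beta0


def enforce_positive_definite(
    d6: np.ndarray,
    signals: np.ndarray,
    table: GradientTable,
    sigma: float,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, int]:
    """Constrain a fitted tensor to be positive (semi-)definite.

    A tensor that is already PSD is returned unchanged with flag ``ok``.
    Otherwise the same weighted least-squares objective is re-minimised with
    D = L L' (L lower-triangular, 6 free parameters; ln S0 profiled out in
    closed form), initialised at the eigenvalue-clamped projection of the
    input.  The result always satisfies lambda_3 >= -1e-12 and its weighted
    residual never exceeds that of the clamped projection.

    Returns ``(d6_pd, s0, flag)``.
    """
    if sigma <= 0:
        raise ValueError("noise sigma must be positive")
    d6 = np.asarray(d6, dtype=float).ravel()
    signals = np.asarray(signals, dtype=float).ravel()
    q = tensor_design_vector(table.bvals, table.bvecs)
    y = np.log(signals)
    w = (signals / sigma) ** 2

    evals = np.linalg.eigvalsh(_d6_to_mat(d6))
    if evals.min() >= 0:
        _, _, beta0 = _weighted_objective(d6, q, y, w)
        return d6, float(np.exp(beta0)), FLAG_OK

    d6_clamp = _clamped_projection(d6)
    f_clamp, _, beta0_clamp = _weighted_objective(d6_clamp, q, y, w)

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        d = _L_to_d6(theta)
        f, g6, _ = _weighted_objective(d, q, y, w)
        gxx, gyy, gzz, gxy, gxz, gyz = g6
        a, b, c, dd, e, ff = theta
        grad = np.array(
            [
                2 * gxx * a + gxy * b + gxz * dd,
                2 * gyy * b + gxy * a + gyz * dd,
                2 * gyy * c + gyz * e,
                2 * gzz * dd + gxz * a + gyz * b,
                2 * gzz * e + gyz * c,
                2 * gzz * ff,
            ]
        )
        return f, grad

    L0 = _chol_lower(d6_clamp)
    x0 = np.array([L0[0, 0], L0[1, 0], L0[1, 1], L0[2, 0], L0[2, 1], L0[2, 2]])
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    d6_fit = _L_to_d6(res.x)
    f_fit, _, beta0_fit = _weighted_objective(d6_fit, q, y, w)
    if f_fit <= f_clamp * (1 + 1e-12) + 1e-300:
        return d6_fit, float(np.exp(beta0_fit)), FLAG_CONSTRAINED_REFIT
    warnings.warn(
        "constrained tensor refit did not improve on the clamped projection; "
        "voxel excluded from statistics",
        RuntimeWarning,
        stacklevel=2,
    )
    return d6_clamp, float(np.exp(beta0_clamp)), FLAG_EXCLUDED


def enforce_positive_definite_map(
    tmap: DiffusionTensorMap,
    frames: list[MRVolume] | np.ndarray,
    table: GradientTable,
    sigma: float,
) -> DiffusionTensorMap:
    """Apply the PD constraint to every violating voxel of a tensor map."""
    if isinstance(frames, (list, tuple)):
        data = np.stack([f.voxels for f in frames], axis=-1)
    else:
        data = np.asarray(frames, dtype=float)
    shape = tmap.tensors.shape[:-1]
    tensors = tmap.tensors.reshape(-1, 6).copy()
    s0 = tmap.s0.ravel().copy()
    flags = tmap.flags.ravel().copy()
    S = data.reshape(-1, len(table))

    fitted = flags == FLAG_OK
    lam_min = np.linalg.eigvalsh(
        DiffusionTensorMap(tensors[fitted], s0[fitted], flags[fitted]).matrices()
    )[:, 0]
    violators = np.flatnonzero(fitted)[lam_min < 0]
    logger.info("PD constraint: refitting %d of %d fitted voxels",
                violators.size, int(fitted.sum()))
    for idx in violators:
        d6, s0v, flag = enforce_positive_definite(
            tensors[idx], S[idx], table, sigma
        )
        tensors[idx] = d6
        s0[idx] = s0v
        flags[idx] = flag
    return DiffusionTensorMap(
        tensors=tensors.reshape(shape + (6,)),
        s0=s0.reshape(shape),
        flags=flags.reshape(shape),
        spacing=tmap.spacing,
    )


# ---------------------------------------------------------------------------
# mean diffusivity
# ---------------------------------------------------------------------------

def compute_md(tmap: DiffusionTensorMap) -> ScalarMap:
    """MD = (lambda1 + lambda2 + lambda3)/3 = trace(D)/3 per fitted voxel.

    Excluded voxels carry NaN.
    """
    md = tmap.tensors[..., :3].sum(axis=-1) / 3.0
    md = np.where(tmap.flags == FLAG_EXCLUDED, np.nan, md)
    return ScalarMap(values=md, spacing=tmap.spacing, display_scale=1000.0,
                     name="MD")


# ---------------------------------------------------------------------------
# rigid DWI-to-b0 registration
# ---------------------------------------------------------------------------

def _to_sitk(vol: MRVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(vol.voxels, (2, 1, 0)), dtype=np.float64)
    )
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(vol.origin, vol.spacing)))
    return img


def _from_sitk(img: sitk.Image, like: MRVolume, contrast: str) -> MRVolume:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return MRVolume(
        voxels=arr, spacing=like.spacing, origin=like.origin,
        contrast_label=contrast,
    )


def _euler_to_rigid(tx: sitk.Euler3DTransform) -> RigidTransform3D:
    R = np.asarray(tx.GetMatrix()).reshape(3, 3)
    c = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    # effective map: p -> R (p - c) + c + t; fold centre into the translation
    t_eff = t + c - R @ c
    # the sitk transform maps reference (fixed) coords to moving coords;
    # report the moving -> reference direction
    R_inv = R.T
    return RigidTransform3D(rotation=R_inv, translation=-R_inv @ t_eff)


def register_dwi_to_b0(
    series: list[MRVolume], table: GradientTable
) -> tuple[list[MRVolume], list[RegistrationResult]]:
    """Rigidly align every weighted frame to the b=0 reference frame.

    The similarity metric is the negated normalised cross-correlation:
    diffusion weighting attenuates each compartment differently, so frames
    differ by (roughly) per-structure scaling and an intensity-invariant
    metric is required.  Optimisation is rigid gradient descent.  If the
    optimised metric is no better than the identity's (evaluated with the
    same metric), the frame is kept unregistered and flagged.
    """
    if len(series) != len(table):
        raise ValueError(
            f"series has {len(series)} frames but gradient table {len(table)}"
        )
    b0_idx = np.flatnonzero(table.bvals == 0)
    if b0_idx.size != 1:
        raise ValueError(
            f"exactly one b=0 reference frame required, found {b0_idx.size}"
        )
    ref_idx = int(b0_idx[0])
    fixed = _to_sitk(series[ref_idx])

    aligned: list[MRVolume] = []
    results: list[RegistrationResult] = []
    for i, frame in enumerate(series):
        if i == ref_idx:
            aligned.append(frame)
            results.append(
                RegistrationResult(RigidTransform3D.identity(), similarity=0.0)
            )
            continue
        moving = _to_sitk(frame)

        def make_reg() -> sitk.ImageRegistrationMethod:
            r = sitk.ImageRegistrationMethod()
            r.SetMetricAsCorrelation()
            r.SetInterpolator(sitk.sitkLinear)
            # central differences instead of the recursive Gaussian gradient
            # filter, which needs >= 4 samples along every axis (we have
            # thin slabs of 3 slices)
            r.MetricUseFixedImageGradientFilterOff()
            r.MetricUseMovingImageGradientFilterOff()
            return r

        initial = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
        probe = make_reg()
        probe.SetInitialTransform(initial, inPlace=False)
        identity_metric = float(probe.MetricEvaluate(fixed, moving))

        reg = make_reg()
        reg.SetInitialTransform(initial, inPlace=False)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=0.5, minStep=1e-6, numberOfIterations=200,
            relaxationFactor=0.6,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        # thin-slab acquisition: through-plane motion is not identifiable
        # from a few structurally identical slices (a z-shift only smooths
        # noise), so restrict to in-plane rotation and translation
        reg.SetOptimizerWeights([0.0, 0.0, 1.0, 1.0, 1.0, 0.0])
        try:
            final = reg.Execute(fixed, moving)
            final_metric = float(reg.GetMetricValue())
            iters = int(reg.GetOptimizerIteration())
        except RuntimeError as exc:  # pragma: no cover - optimizer blow-up
            logger.warning("rigid registration failed for frame %d: %s", i, exc)
            final, final_metric, iters = None, np.inf, 0

        if final is None or final_metric > identity_metric:
            warnings.warn(
                f"rigid registration of frame {i} did not improve over the "
                "identity; frame left unregistered",
                RuntimeWarning,
                stacklevel=2,
            )
            aligned.append(frame)
            results.append(
                RegistrationResult(
                    RigidTransform3D.identity(),
                    similarity=identity_metric, iterations=iters,
                    success=False,
                )
            )
            continue
        resampled = sitk.Resample(
            moving, fixed, final, sitk.sitkLinear, 0.0, sitk.sitkFloat64
        )
        euler = sitk.Euler3DTransform(
            sitk.CompositeTransform(final).GetNthTransform(0)
        )
        aligned.append(_from_sitk(resampled, series[ref_idx], frame.contrast_label))
        results.append(
            RegistrationResult(
                _euler_to_rigid(euler),
                similarity=final_metric, iterations=iters, success=True,
            )
        )
    return aligned, results
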