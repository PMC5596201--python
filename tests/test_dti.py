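"""Tensor fitting, noise estimation, PD constraint, rigid DWI registration."""

from __future__ import annotations

import numpy as np
import pytest

from radpathcorr import dti
from radpathcorr import phantom as ph
from radpathcorr.types import GradientTable, MRVolume


def _signals_from_tensor(d6, table, s0=1000.0):
    q = ph.tensor_design_vector(table.bvals, table.bvecs)
    return s0 * np.exp(-(q @ np.asarray(d6, dtype=float)))


def _random_pd_d6(rng, scale=1e-3):
    A = rng.normal(size=(3, 3)) * scale
    D = A @ A.T + 0.05 * scale**2 * np.eye(3)
    return np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])


# ---------------------------------------------------------------------------
# single-voxel WLLS
# ---------------------------------------------------------------------------

def test_noiseless_recovery_single_voxel(table0, rng):
    for _ in range(10):
        d6 = _random_pd_d6(rng)
        sig = _signals_from_tensor(d6, table0)
        fit, s0, flag = dti.fit_tensor_wlls(sig, table0, sigma=20.0)
        assert flag == dti.FLAG_OK
        np.testing.assert_allclose(fit, d6, atol=1e-12)
        assert s0 == pytest.approx(1000.0, rel=1e-12)


def test_sigma_scale_invariance(table0, rng):
    d6 = _random_pd_d6(rng)
    sig = _signals_from_tensor(d6, table0) + rng.normal(0, 5, size=7)
    fit1, s01, _ = dti.fit_tensor_wlls(sig, table0, sigma=10.0)
    fit2, s02, _ = dti.fit_tensor_wlls(sig, table0, sigma=137.0)
    np.testing.assert_allclose(fit1, fit2, atol=1e-15)
    assert s01 == pytest.approx(s02, rel=1e-14)


def test_wlls_matches_normal_equations_oracle(table0, rng):
    d6 = _random_pd_d6(rng)
    sig = np.abs(_signals_from_tensor(d6, table0) + rng.normal(0, 30, size=7))
    sigma = 25.0
    fit, s0, _ = dti.fit_tensor_wlls(sig, table0, sigma)
    q = ph.tensor_design_vector(table0.bvals, table0.bvecs)
    X = np.column_stack([np.ones(7), -q])
    W = np.diag((sig / sigma) ** 2)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ np.log(sig))
    np.testing.assert_allclose(fit, beta[1:], atol=1e-12)
    assert s0 == pytest.approx(np.exp(beta[0]), rel=1e-12)


def test_nonpositive_signal_excluded(table0):
    sig = np.array([1000.0, 500, 500, 0.0, 500, 500, 500])
    d6, s0, flag = dti.fit_tensor_wlls(sig, table0, sigma=20.0)
    assert flag == dti.FLAG_EXCLUDED
    assert np.isnan(s0)


def test_invalid_sigma_rejected(table0):
    sig = np.full(7, 100.0)
    with pytest.raises(ValueError, match="sigma"):
        dti.fit_tensor_wlls(sig, table0, sigma=0.0)


def test_rank_deficient_directions_rejected():
    bvals = np.concatenate([[0.0], np.full(6, 1000.0)])
    bvecs = np.vstack([[0, 0, 0]] + [[1.0, 0.0, 0.0]] * 6)
    table = GradientTable(bvals=bvals, bvecs=bvecs)
    with pytest.raises(ValueError, match="rank-deficient"):
        dti.fit_tensor_wlls(np.full(7, 100.0), table, sigma=20.0)


def test_rotation_equivariance(table0, rng):
    d6 = _random_pd_d6(rng)
    D = np.array([[d6[0], d6[3], d6[4]],
                  [d6[3], d6[1], d6[5]],
                  [d6[4], d6[5], d6[2]]])
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0],
                  [0, 0, 1.0]])
    Dr = R @ D @ R.T
    d6r = np.array([Dr[0, 0], Dr[1, 1], Dr[2, 2],
                    Dr[0, 1], Dr[0, 2], Dr[1, 2]])
    # rotating the tensor equals counter-rotating the gradient directions
    table_rot = GradientTable(
        bvals=table0.bvals,
        bvecs=np.where(table0.bvals[:, None] > 0,
                       table0.bvecs @ R, table0.bvecs),
    )
    sig = _signals_from_tensor(d6r, table0)
    sig_rot = _signals_from_tensor(d6, table_rot)
    np.testing.assert_allclose(sig, sig_rot, rtol=1e-12)
    fit, _, _ = dti.fit_tensor_wlls(sig, table0, sigma=20.0)
    np.testing.assert_allclose(fit, d6r, atol=1e-12)


# ---------------------------------------------------------------------------
# map-level fit
# ---------------------------------------------------------------------------

def test_fit_tensor_map_matches_single_voxel(table0, rng):
    n = 50
    data = np.empty((n, 1, 1, 7))
    truth = []
    for v in range(n):
        d6 = _random_pd_d6(rng)
        truth.append(d6)
        data[v, 0, 0] = np.abs(
            _signals_from_tensor(d6, table0) + rng.normal(0, 20, size=7)
        )
    tmap = dti.fit_tensor_map(data, table0, sigma=20.0)
    for v in range(n):
        d6, s0, flag = dti.fit_tensor_wlls(data[v, 0, 0], table0, sigma=20.0)
        np.testing.assert_allclose(tmap.tensors[v, 0, 0], d6, atol=1e-10)
        assert tmap.s0[v, 0, 0] == pytest.approx(s0, rel=1e-10)


def test_fit_tensor_map_respects_mask(table0):
    data = np.full((4, 1, 1, 7), 500.0)
    data[..., 0] = 1000.0
    mask = np.zeros((4, 1, 1), dtype=bool)
    mask[:2] = True
    tmap = dti.fit_tensor_map(data, table0, sigma=20.0, mask=mask)
    assert np.all(tmap.flags[:2] == dti.FLAG_OK)
    assert np.all(tmap.flags[2:] == dti.FLAG_EXCLUDED)


def test_compute_md_is_trace_over_three_and_nan_for_excluded(table0, rng):
    d6 = _random_pd_d6(rng)
    sig = _signals_from_tensor(d6, table0)
    tmap = dti.fit_tensor_map(
        np.stack([sig, sig])[:, None, None, :], table0, sigma=20.0
    )
    tmap.flags[1, 0, 0] = dti.FLAG_EXCLUDED
    md = dti.compute_md(tmap)
    assert md.values[0, 0, 0] == pytest.approx(d6[:3].sum() / 3.0, abs=1e-15)
    assert np.isnan(md.values[1, 0, 0])
    ev = tmap.eigenvalues()[0, 0, 0]
    assert md.values[0, 0, 0] == pytest.approx(ev.mean(), abs=1e-15)


def test_display_values_scale_only_rendering():
    m = dti.ScalarMap(values=np.array([1e-3]), display_scale=1000.0)
    assert m.display_values()[0] == pytest.approx(1.0)
    assert m.values[0] == 1e-3


# ---------------------------------------------------------------------------
# noise sigma
# ---------------------------------------------------------------------------

def test_sigma_estimate_within_5_percent(rng):
    sigma = 20.0
    n = 10_000
    noise = np.sqrt(rng.normal(0, sigma, n) ** 2 + rng.normal(0, sigma, n) ** 2)
    vol = noise.reshape(100, 100, 1)
    est = dti.estimate_noise_sigma(vol, np.ones_like(vol, dtype=bool))
    assert est == pytest.approx(sigma, rel=0.05)


def test_sigma_estimate_rejects_small_mask():
    vol = np.zeros((10, 10, 1))
    mask = np.zeros_like(vol, dtype=bool)
    mask.ravel()[:10] = True
    with pytest.raises(ValueError, match="50"):
        dti.estimate_noise_sigma(vol, mask)


def test_sigma_estimate_rejects_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        dti.estimate_noise_sigma(np.zeros((4, 4, 1)), np.ones((5, 5, 1), bool))


# ---------------------------------------------------------------------------
# PD constraint
# ---------------------------------------------------------------------------

def test_pd_leaves_psd_tensor_unchanged(table0, rng):
    d6 = _random_pd_d6(rng)
    sig = _signals_from_tensor(d6, table0)
    out, s0, flag = dti.enforce_positive_definite(d6, sig, table0, sigma=20.0)
    assert flag == dti.FLAG_OK
    np.testing.assert_array_equal(out, d6)


def test_pd_refit_restores_definiteness_and_beats_clamp(table0, rng):
    # craft an indefinite fit by fitting very noisy signals
    found = 0
    for _ in range(200):
        d6 = np.array([0.3e-3, 0.3e-3, 0.3e-3, 0, 0, 0])
        sig = np.abs(_signals_from_tensor(d6, table0, s0=200.0)
                     + rng.normal(0, 60, size=7)) + 1e-6
        fit, _, flag = dti.fit_tensor_wlls(sig, table0, sigma=60.0)
        mat = np.array([[fit[0], fit[3], fit[4]],
                        [fit[3], fit[1], fit[5]],
                        [fit[4], fit[5], fit[2]]])
        if np.linalg.eigvalsh(mat).min() >= 0:
            continue
        found += 1
        out, s0, oflag = dti.enforce_positive_definite(fit, sig, table0,
                                                       sigma=60.0)
        m2 = np.array([[out[0], out[3], out[4]],
                       [out[3], out[1], out[5]],
                       [out[4], out[5], out[2]]])
        assert np.linalg.eigvalsh(m2).min() >= -1e-12
        assert oflag in (dti.FLAG_CONSTRAINED_REFIT, dti.FLAG_EXCLUDED)
        if found >= 5:
            break
    assert found >= 5  # the noise level must actually produce violators


# ---------------------------------------------------------------------------
# rigid DWI-to-b0 registration
# ---------------------------------------------------------------------------

def test_register_requires_single_b0(table0, noiseless_frames0):
    bad = GradientTable(bvals=np.zeros(7), bvecs=np.zeros((7, 3)))
    with pytest.raises(ValueError, match="exactly one b=0"):
        dti.register_dwi_to_b0(noiseless_frames0, bad)


def test_register_recovers_in_plane_shift(gt0, table0, frames0):
    """A frame shifted by (2, -1, 0) voxels is realigned to within 0.1 voxel."""
    table = GradientTable(bvals=table0.bvals[:2], bvecs=table0.bvecs[:2])
    # integer-voxel roll: an exact translation with no interpolation blur
    shifted = np.roll(frames0[0].voxels, (2, -1), axis=(0, 1))
    series = [frames0[0], MRVolume(shifted, frames0[0].spacing,
                                   contrast_label="DWI")]
    aligned, results = dti.register_dwi_to_b0(series, table)
    assert results[1].success
    t = results[1].transform  # moving -> reference, mm
    spacing = np.asarray(frames0[0].spacing)
    shift_vox = np.abs(np.asarray(t.translation)) / spacing
    np.testing.assert_allclose(shift_vox[:2], [2.0, 1.0], atol=0.1)
    assert shift_vox[2] == pytest.approx(0.0, abs=0.1)
    # the realigned frame matches the unshifted original in the interior
    core = (slice(10, -10), slice(10, -10), slice(None))
    orig = frames0[0].voxels[core]
    back = aligned[1].voxels[core]
    r = np.corrcoef(orig.ravel(), back.ravel())[0, 1]
    assert r > 0.98
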