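"""SENSE reconstruction and noise covariance propagation."""

import numpy as np
import pytest

import gsvs
from gsvs.core import ComplexVolumeStack
from gsvs.recon import (
    _under_blocks,
    marginalize_patch_cov,
    patch_whitener,
    propagate_noise,
    sense_reconstruct,
    whiten_channels,
    whiten_coils,
)

from conftest import complex_noise


def _noise_only_kspace(coils, scheme, n_vol, seed):
    zeros = ComplexVolumeStack(np.zeros(coils.grid_shape + (n_vol,), dtype=complex))
    ksp = gsvs.sample_kspace(zeros, coils, scheme, noise_sigma=1.0, seed=seed)
    return whiten_channels(ksp, coils.channel_cov)


class TestWhitening:
    def test_identity_covariance_is_noop(self, rng):
        z = complex_noise(rng, (3, 10))
        assert np.allclose(whiten_channels(z, np.eye(3)), z)

    def test_scalar_covariance_divides(self, rng):
        z = complex_noise(rng, (1, 10))
        assert np.allclose(whiten_channels(z, np.array([[4.0]])), z / 2.0)

    def test_whitened_noise_covariance_is_identity(self, rng):
        L = 4
        idx = np.arange(L)
        cov = (0.5 ** np.abs(idx[:, None] - idx[None, :])).astype(complex)
        chol = np.linalg.cholesky(cov)
        z = chol @ complex_noise(rng, (L, 20000))
        zw = whiten_channels(z, cov)
        emp = (zw @ zw.conj().T) / zw.shape[1]
        assert np.allclose(emp, np.eye(L), atol=0.05)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError, match="singular|indefinite"):
            whiten_channels(np.zeros((2, 4), complex), np.ones((2, 2)))


class TestReconstruction:
    def test_noiseless_full_unit_coil_recovers_truth(self, small_truth, unit_coil):
        ksp = gsvs.sample_kspace(small_truth, unit_coil,
                                 gsvs.SamplingScheme(mode="FULL"), noise_sigma=0.0)
        y = sense_reconstruct(ksp, unit_coil)
        assert np.allclose(y.data, small_truth.data, atol=1e-10)

    def test_noiseless_under_exact_unfolding(self, small_truth, small_coils,
                                             whitened_coils):
        scheme = gsvs.SamplingScheme(mode="UNDER", undersampling_factor=2)
        ksp = gsvs.sample_kspace(small_truth, small_coils, scheme, noise_sigma=0.0)
        y = sense_reconstruct(whiten_channels(ksp, small_coils.channel_cov),
                              whitened_coils)
        fov = y.meta["fov_mask"]
        err = np.abs(y.data - small_truth.data)[fov].max()
        assert err < 1e-4 * np.abs(small_truth.data).max()

    def test_noiseless_half_zero_fill_blurs_within_bound(self, small_truth,
                                                         small_coils, whitened_coils):
        scheme = gsvs.SamplingScheme(mode="HALF", pf_fraction=0.75,
                                     spectral_filter="zero_fill")
        ksp = gsvs.sample_kspace(small_truth, small_coils, scheme, noise_sigma=0.0)
        y = sense_reconstruct(whiten_channels(ksp, small_coils.channel_cov),
                              whitened_coils)
        fov = y.meta["fov_mask"]
        rel = np.linalg.norm((y.data - small_truth.data)[fov]) / np.linalg.norm(
            small_truth.data[fov])
        assert rel < 0.25  # PE blurring only; documented bound for this phantom

    def test_reconstruction_linearity(self, small_coils, whitened_coils):
        scheme = gsvs.SamplingScheme(mode="UNDER", undersampling_factor=2)
        z1 = _noise_only_kspace(small_coils, scheme, 3, seed=1)
        z2 = _noise_only_kspace(small_coils, scheme, 3, seed=2)
        y1 = sense_reconstruct(z1, whitened_coils).data
        y2 = sense_reconstruct(z2, whitened_coils).data
        both = z1
        both.data = z1.data + z2.data
        y12 = sense_reconstruct(both, whitened_coils).data
        assert np.allclose(y12, y1 + y2, atol=1e-10)


class TestPropagation:
    def test_full_unit_coil_unit_variance(self, unit_coil):
        nm = propagate_noise(unit_coil, gsvs.SamplingScheme(mode="FULL"))
        assert np.allclose(nm.variance_map, 1.0)

    def test_full_variance_matches_monte_carlo(self, whitened_coils):
        scheme = gsvs.SamplingScheme(mode="FULL")
        ana = propagate_noise(whitened_coils, scheme)
        mc = propagate_noise(whitened_coils, scheme, method="monte_carlo",
                             n_draws=3000, seed=0)
        fov = ana.variance_map > 0
        # elementwise agreement within 3 Monte-Carlo standard errors
        se = ana.variance_map[fov] * 3.0 / np.sqrt(3000)
        assert np.all(np.abs(mc.variance_map[fov] - ana.variance_map[fov]) < 3 * se + 1e-12)

    def test_under_variance_matches_monte_carlo(self, whitened_coils):
        scheme = gsvs.SamplingScheme(mode="UNDER", undersampling_factor=2)
        ana = propagate_noise(whitened_coils, scheme)
        mc = propagate_noise(whitened_coils, scheme, method="monte_carlo",
                             n_draws=3000, seed=1)
        fov = ana.variance_map > 0
        rel = mc.variance_map[fov] / ana.variance_map[fov]
        assert np.abs(np.median(rel) - 1) < 0.05
        assert np.abs(rel - 1).max() < 0.35

    def test_g_factor_identity(self, whitened_coils):
        # sigma_under / sigma_full = g * sqrt(U) voxelwise
        schemeU = gsvs.SamplingScheme(mode="UNDER", undersampling_factor=2)
        nmF = propagate_noise(whitened_coils, gsvs.SamplingScheme(mode="FULL"))
        nmU = propagate_noise(whitened_coils, schemeU)
        # independent g-factor computation from the sensitivity Gram matrices
        gram, K = _under_blocks(whitened_coils, schemeU)
        inv = np.linalg.inv(gram)
        s = whitened_coils.sensitivities
        rss2 = (np.abs(s) ** 2).sum(axis=0)  # (nx, ny, nz)
        U = 2
        g = np.zeros(whitened_coils.grid_shape)
        for u in range(U):
            # voxel (x, y=u*K + k, z) has position u within its aliased set
            g[:, u * K:(u + 1) * K, :] = np.sqrt(
                np.einsum("okzuu->okz", inv[..., u:u + 1, u:u + 1].real
                          ).transpose(0, 1, 2)
                * rss2[:, u * K:(u + 1) * K, :]
            )
        fov = nmF.variance_map > 0
        ratio = np.sqrt(nmU.variance_map[fov] / nmF.variance_map[fov])
        assert np.allclose(ratio, (g * np.sqrt(U))[fov], rtol=1e-6)
        assert np.all(g[fov] >= 1 - 1e-9)  # g-factor is at least one

    def test_half_analytic_matches_monte_carlo_patch_cov(self, whitened_coils):
        scheme = gsvs.SamplingScheme(mode="HALF", pf_fraction=0.75,
                                     spectral_filter="ramp")
        ana = propagate_noise(whitened_coils, scheme, method="analytic")
        n_draws = 10000
        mc = propagate_noise(whitened_coils, scheme, method="monte_carlo",
                             n_draws=n_draws, seed=2)
        members = np.arange(32)  # a PE column segment plus neighbors
        ca = marginalize_patch_cov(ana, members).matrix
        cm = marginalize_patch_cov(mc, members).matrix
        # sample covariance standard error: sqrt((var_i var_j + |c_ij|^2) / n)
        v = np.abs(np.diag(ca))
        se = np.sqrt((np.outer(v, v) + np.abs(ca) ** 2) / n_draws)
        assert np.abs(cm - ca).max() <= 4.5 * se.max()
        assert np.all(np.abs(cm - ca) <= 4.5 * se + 1e-9)
        # the correlation structure itself matches (not just zero)
        assert np.abs(ca).max() > 0.5 * v.max()


class TestPatchCovariance:
    def test_full_regime_diagonal(self, whitened_coils):
        nm = propagate_noise(whitened_coils, gsvs.SamplingScheme(mode="FULL"))
        members = np.array([0, 5, 100, 700])
        cov = marginalize_patch_cov(nm, members).matrix
        assert np.allclose(cov, np.diag(np.diag(cov)))
        assert np.allclose(np.diag(cov).real,
                           nm.variance_map.reshape(-1)[members])

    def test_under_aliased_pair_off_diagonal(self, whitened_coils):
        scheme = gsvs.SamplingScheme(mode="UNDER", undersampling_factor=2)
        nm = propagate_noise(whitened_coils, scheme)
        nx, ny, nz = nm.grid_shape
        K = ny // 2
        # voxel (3, 2, 1) aliases with (3, 2+K, 1)
        q1 = np.ravel_multi_index((3, 2, 1), nm.grid_shape)
        q2 = np.ravel_multi_index((3, 2 + K, 1), nm.grid_shape)
        q3 = np.ravel_multi_index((4, 2, 1), nm.grid_shape)
        cov_pair = marginalize_patch_cov(nm, np.array([q1, q2])).matrix
        assert np.abs(cov_pair[0, 1]) > 0
        expected = 2 * np.linalg.inv(
            _under_blocks(whitened_coils, scheme)[0][3, 2, 1])[0, 1]
        assert np.allclose(cov_pair[0, 1], expected, rtol=1e-5)
        cov_nopair = marginalize_patch_cov(nm, np.array([q1, q3])).matrix
        assert np.allclose(cov_nopair, np.diag(np.diag(cov_nopair)))

    def test_member_permutation_permutes_cov(self, whitened_coils):
        scheme = gsvs.SamplingScheme(mode="UNDER", undersampling_factor=2)
        nm = propagate_noise(whitened_coils, scheme)
        members = np.array([10, 266, 522, 33])
        perm = np.array([2, 0, 3, 1])
        c1 = marginalize_patch_cov(nm, members).matrix
        c2 = marginalize_patch_cov(nm, members[perm]).matrix
        assert np.allclose(c2, c1[np.ix_(perm, perm)])


class TestPatchWhitener:
    def test_identity_covariance_gives_identity(self):
        from gsvs.recon import PatchCovariance
        ups = patch_whitener(PatchCovariance(matrix=np.eye(5)))
        assert np.allclose(np.abs(ups @ ups.conj().T), np.eye(5))

    def test_diagonal_covariance(self):
        from gsvs.recon import PatchCovariance
        d = np.array([4.0, 9.0, 0.25])
        ups = patch_whitener(PatchCovariance(matrix=np.diag(d)))
        # Upsilon^H Upsilon = Sigma^{-1} (equivalent to diag(1/sigma) up to
        # a unitary factor)
        assert np.allclose(ups.conj().T @ ups, np.diag(1.0 / d))

    def test_whitened_noise_draws_identity_covariance(self, rng):
        from gsvs.recon import PatchCovariance
        M = 6
        A = complex_noise(rng, (M, M))
        sigma = A @ A.conj().T + 0.5 * np.eye(M)
        chol = np.linalg.cholesky(sigma)
        draws = chol @ complex_noise(rng, (M, 20000))
        ups = patch_whitener(PatchCovariance(matrix=sigma))
        w = ups @ draws
        emp = (w @ w.conj().T) / w.shape[1]
        assert np.allclose(emp, np.eye(M), atol=0.06)
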