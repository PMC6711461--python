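"""ESD modelling, D-transform, optimal shrinkage, AMSE, spiked limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsvs.recon import PatchCovariance
from gsvs.shrinkage import (
    ESDModel,
    d_transform,
    d_transform_deriv,
    estimate_amse,
    mp_closed_form_esd,
    mp_singular_quantiles,
    shrink,
    simulate_esd,
    spiked_limit,
)

from conftest import complex_noise


def _iid_cov(M):
    return PatchCovariance(matrix=np.eye(M))


def _spiked_patch(rng, M, N, sv_normalized):
    """Low-rank X + unit white noise; population sv on the eta/sqrt(N) scale."""
    R = len(sv_normalized)
    U, _ = np.linalg.qr(complex_noise(rng, (M, R)))
    V, _ = np.linalg.qr(complex_noise(rng, (N, R)))
    X = (U * (np.sqrt(N) * np.asarray(sv_normalized))) @ V.conj().T
    W = complex_noise(rng, (M, N))
    return X, X + W


class TestSimulateESD:
    def test_iid_edge_approaches_mp_bulk_edge(self):
        M, N = 64, 80
        esd = simulate_esd(_iid_cov(M), M, N, B=6, seed=0)
        assert np.isclose(esd.edge / np.sqrt(N), 1 + np.sqrt(M / N), rtol=0.03)

    def test_covariance_scaling_scales_spectrum(self):
        M, N, c = 24, 30, 2.5
        e1 = simulate_esd(_iid_cov(M), M, N, B=2, seed=5)
        e2 = simulate_esd(PatchCovariance(matrix=c ** 2 * np.eye(M)), M, N, B=2, seed=5)
        assert np.allclose(e2.spectrum, c * e1.spectrum, rtol=1e-10)

    def test_same_seed_identical(self):
        e1 = simulate_esd(_iid_cov(16), 16, 20, B=2, seed=3)
        e2 = simulate_esd(_iid_cov(16), 16, 20, B=2, seed=3)
        assert np.array_equal(e1.spectrum, e2.spectrum)

    def test_heteroscedastic_column_groups(self):
        M, N = 16, 24
        groups = {0: np.arange(12), 1: np.arange(12, 24)}
        per_enc = {0: np.eye(M), 1: 4.0 * np.eye(M)}
        pc = PatchCovariance(per_encoding=per_enc, volume_groups=groups)
        esd = simulate_esd(pc, M, N, B=2, seed=1)
        # spectrum energy equals the mixed variance: 12 cols at 1, 12 at 4
        energy = (esd.spectrum ** 2).sum() / 2  # B = 2 rescaling keeps M x N energy
        assert np.isclose(energy, M * 12 * (1 + 4.0), rtol=0.15)


class TestClosedFormESD:
    def test_gamma_to_zero_collapses_to_sigma(self):
        q = mp_singular_quantiles(1e-4, 500)
        assert np.all(np.abs(q - 1.0) < 0.05)

    def test_gamma_one_support(self):
        esd = mp_closed_form_esd(1.0, sigma=1.5, n_points=500)
        assert np.isclose(esd.edge, 3.0)
        assert esd.spectrum.min() >= 0

    def test_quantiles_match_simulation(self):
        """Kolmogorov-Smirnov distance between closed form and simulation."""
        M, N = 400, 800
        esd_sim = simulate_esd(_iid_cov(M), M, N, B=2, seed=7)
        q = mp_singular_quantiles(0.5, len(esd_sim.spectrum)) * np.sqrt(N)
        sim = np.sort(esd_sim.spectrum)
        ref = np.sort(q)
        grid = np.linspace(ref[0], ref[-1], 500)
        ks = np.abs(
            np.searchsorted(sim, grid) / len(sim)
            - np.searchsorted(ref, grid) / len(ref)
        ).max()
        assert ks < 0.03


class TestDTransform:
    def test_zero_noise_spectrum_reduces_to_inverse_square(self):
        esd = ESDModel(spectrum=np.zeros(32), edge=0.0, gamma=0.5)
        x = np.array([0.5, 1.0, 2.0])
        assert np.allclose(d_transform(x, esd), 1.0 / x ** 2)

    def test_large_x_asymptotics(self):
        esd = simulate_esd(_iid_cov(32), 32, 64, B=2, seed=0)
        x = 1e4
        assert np.isclose(x ** 2 * d_transform(x, esd), 1.0, rtol=1e-4)

    def test_derivative_matches_finite_differences(self):
        esd = simulate_esd(_iid_cov(32), 32, 64, B=2, seed=1)
        for x in [1.1 * esd.edge, 1.5 * esd.edge, 3 * esd.edge]:
            h = 1e-5 * x
            fd = (d_transform(x + h, esd) - d_transform(x - h, esd)) / (2 * h)
            assert np.isclose(d_transform_deriv(x, esd), fd, rtol=1e-6)

    def test_domain_error_at_or_below_edge(self):
        esd = simulate_esd(_iid_cov(16), 16, 20, B=2, seed=0)
        with pytest.raises(ValueError, match="edge"):
            d_transform(esd.edge, esd)


class TestShrink:
    def test_zero_noise_esd_is_identity(self):
        esd = ESDModel(spectrum=np.zeros(16), edge=0.0, gamma=0.5)
        eta = np.array([5.0, 3.0, 1.0, 0.5])
        res = shrink(eta, esd)
        assert np.allclose(res.eta_hat, eta, rtol=1e-12)
        assert res.rank == 4

    def test_all_below_edge_gives_zero(self):
        esd = simulate_esd(_iid_cov(16), 16, 20, B=2, seed=0)
        eta = np.full(16, 0.5 * esd.edge)
        res = shrink(eta, esd)
        assert res.rank == 0
        assert np.all(res.eta_hat == 0.0)
        assert res.amse == 0.0

    @pytest.mark.parametrize("gamma", [0.25, 0.5, 0.85])
    def test_white_noise_closed_form_oracle(self, gamma):
        """GSVS with the MP ESD equals the white-noise Frobenius shrinker."""
        esd = mp_closed_form_esd(gamma, 1.0, n_points=2000)
        edge = 1 + np.sqrt(gamma)
        y = np.linspace(4.0, 1.05 * edge, 60)
        res = shrink(y, esd)
        oracle = np.sqrt((y ** 2 - gamma - 1) ** 2 - 4 * gamma) / y
        assert np.all(np.abs(res.eta_hat - oracle) / oracle < 0.01)

    def test_shrinkage_never_increases_and_is_monotone(self, rng):
        M, N = 48, 64
        esd = simulate_esd(_iid_cov(M), M, N, B=2, seed=11)
        y = np.sort(rng.uniform(0.2, 4.0, size=M))[::-1] * np.sqrt(N)
        res = shrink(y, esd)
        assert np.all(res.eta_hat <= y + 1e-9)
        above = y > esd.edge
        assert np.all(np.diff(res.eta_hat[above]) <= 1e-9)  # decreasing with y

    def test_scale_equivariance(self):
        M, N, c = 32, 40, 3.0
        e1 = simulate_esd(_iid_cov(M), M, N, B=2, seed=2)
        e2 = simulate_esd(PatchCovariance(matrix=c ** 2 * np.eye(M)), M, N, B=2, seed=2)
        y = np.linspace(3.0, 1.2, 10) * np.sqrt(N)
        r1 = shrink(y, e1)
        r2 = shrink(c * y, e2)
        assert np.allclose(r2.eta_hat, c * r1.eta_hat, rtol=1e-8)


class TestAMSE:
    def test_rank_zero_amse_is_zero(self):
        esd = simulate_esd(_iid_cov(8), 8, 12, B=2, seed=0)
        res = shrink(np.full(8, 0.1), esd)
        assert estimate_amse(np.full(8, 0.1), res, esd) == 0.0

    def test_amse_tracks_realized_error(self, rng):
        """Estimated AMSE within 10% of the realized Frobenius error."""
        M, N, B = 128, 160, 2
        reals, ests = [], []
        for t in range(10):
            X, Y = _spiked_patch(rng, M, N, [3.0, 2.8, 2.6, 2.4, 2.2])
            esd = simulate_esd(_iid_cov(M), M, N, B=B, seed=50 + t)
            U, s, Vh = np.linalg.svd(Y, full_matrices=False)
            res = shrink(s, esd)
            Xh = (U * res.eta_hat) @ Vh
            reals.append(np.linalg.norm(Xh - X) ** 2)
            ests.append(res.amse)
        assert np.isclose(sum(ests), sum(reals), rtol=0.10)

    def test_amse_increases_with_noise_scale(self, rng):
        M, N = 64, 96
        X, _ = _spiked_patch(rng, M, N, [4.0, 3.0])
        amse = []
        for c in (1.0, 2.0):
            W = c * complex_noise(rng, (M, N))
            s = np.linalg.svd(X + W, compute_uv=False)
            esd = simulate_esd(PatchCovariance(matrix=c ** 2 * np.eye(M)),
                               M, N, B=2, seed=9)
            amse.append(shrink(s, esd).amse)
        assert amse[1] > amse[0]


class TestSpikedLimit:
    def test_printed_value(self):
        assert np.isclose(spiked_limit(4.0, 0.5), 14.0 / 3.0)

    def test_gamma_zero_no_inflation(self):
        assert np.isclose(spiked_limit(4.0, 1e-12), 4.0)

    @given(ex2=st.floats(1.05, 50), gamma=st.floats(0.01, 2.0))
    @settings(deadline=None, max_examples=50)
    def test_positive_bias(self, ex2, gamma):
        assert spiked_limit(ex2, gamma) > ex2

    def test_monte_carlo_agreement(self, rng):
        """Top sample eigenvalue of a simulated rank-1 spiked covariance."""
        from scipy.sparse.linalg import svds
        N, gamma, ex2 = 4000, 0.5, 4.0
        M = int(gamma * N)
        u = complex_noise(rng, M)
        u /= np.linalg.norm(u)
        G = complex_noise(rng, (M, N))
        # population covariance I + (ex2 - 1) u u^H
        Y = G + (np.sqrt(ex2) - 1) * u[:, None] * (u.conj() @ G)[None, :]
        top = svds(Y, k=1, return_singular_vectors=False)[0] ** 2 / N
        assert np.isclose(top, spiked_limit(ex2, gamma), rtol=0.02)


class TestRankRecovery:
    def test_well_separated_spikes_recovered(self, rng):
        """Planted rank-5 spikes at >= 2x the detection threshold."""
        M, N, R = 96, 120, 5
        gamma = M / N
        thresh = gamma ** 0.25  # population detection threshold, normalized
        sv = 2.0 * thresh * np.linspace(1.6, 1.0, R)
        hits = 0
        trials = 60
        for t in range(trials):
            X, Y = _spiked_patch(rng, M, N, sv)
            esd = simulate_esd(_iid_cov(M), M, N, B=2, seed=900 + t)
            s = np.linalg.svd(Y, compute_uv=False)
            hits += shrink(s, esd).rank == R
        assert hits / trials >= 0.95
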