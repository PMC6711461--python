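"""Linear SENSE reconstruction and exact noise-covariance propagation.

The forward model per volume is ``z = M F (S x) + w`` with ``F`` the unitary
in-plane DFT on the full reconstruction grid, ``S`` the coil sensitivities,
``M`` the line-selection mask, and ``w`` channel noise.  After channel
whitening the reconstruction is the linear least-squares inverse (SENSE),
optionally followed by a partial-Fourier spectral filter ``G``.  Because the
whole chain is linear, the channel noise maps to image-domain noise with a
covariance that this module computes exactly (FULL/UNDER) or by Monte-Carlo
application of the reconstruction operator to noise draws (HALF/INTER, with
an analytic per-PE-column path available for small grids).

Noise covariance summary per regime (whitened channels, unit k-space noise):

- FULL:  diagonal, sigma_q^2 = (S_q^H S_q)^{-1} per voxel;
- UNDER: U x U blocks over aliased voxel sets, U * (S_qU^H S_qU)^{-1}
  (the factor U reflects sampling the full-grid unitary DFT; the ratio of
  aliased to full noise amplitude is the g-factor times sqrt(U));
- HALF:  correlated along the PE axis through the spectral filter,
  G (S^H S)^{-1} G^H, per PE column;
- INTER: one HALF-type spatial model per encoding, with a volume-group
  indicator marking which columns of the Casorati matrix use which model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ComplexVolumeStack
from .phantom import (
    CoilSet,
    KSpaceData,
    SamplingScheme,
    _ifft2,
    acquired_lines,
    volume_mask,
)

__all__ = [
    "NoiseModel",
    "PatchCovariance",
    "whiten_channels",
    "whiten_coils",
    "sense_reconstruct",
    "spectral_filter_taps",
    "propagate_noise",
    "marginalize_patch_cov",
    "patch_whitener",
]

_EIG_FLOOR = 1e-8  # relative eigenvalue floor for covariance inversion
_SENS_TOL = 1e-6   # relative coil-coverage threshold defining the FOV


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

def _whitening_matrix(channel_cov: np.ndarray) -> np.ndarray:
    """Upsilon with Upsilon^H Upsilon = channel_cov^{-1} (Cholesky-based)."""
    cov = np.asarray(channel_cov, dtype=np.complex128)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        cond = np.linalg.cond(cov)
        raise ValueError(
            f"channel covariance is singular or indefinite (cond={cond:.3g})"
        ) from err
    L = cov.shape[0]
    return np.linalg.solve(chol, np.eye(L, dtype=np.complex128))


def whiten_channels(z, channel_cov: np.ndarray):
    """Apply the channel whitening transform along the coil axis (axis 0).

    Accepts a raw array ``(L, ...)`` or a :class:`KSpaceData`; returns the
    same type.  On noise-only input the whitened channel covariance is the
    identity.
    """
    ups = _whitening_matrix(channel_cov)
    if isinstance(z, KSpaceData):
        data = np.einsum("cl,l...->c...", ups, z.data)
        data *= z.mask[None, :, :, None, :]
        return KSpaceData(data=data, mask=z.mask, scheme=z.scheme,
                          noise_sigma=z.noise_sigma)
    return np.einsum("cl,l...->c...", ups, np.asarray(z))


def whiten_coils(coils: CoilSet) -> CoilSet:
    """Whitened sensitivities S_bar = Upsilon_z S, with identity channel cov."""
    ups = _whitening_matrix(coils.channel_cov)
    sens = np.einsum("cl,l...->c...", ups, coils.sensitivities)
    return CoilSet(sensitivities=sens,
                   channel_cov=np.eye(coils.n_coils, dtype=np.complex128))


# ---------------------------------------------------------------------------
# spectral filters
# ---------------------------------------------------------------------------

def spectral_filter_taps(n_pe: int, scheme: SamplingScheme, encoding: int = 0) -> np.ndarray:
    """Partial-Fourier filter taps on the full PE grid, raw FFT order.

    ``zero_fill``: indicator of acquired lines.  ``ramp`` (homodyne-style):
    weight ramps linearly from 2 to 0 across the symmetrically sampled band,
    is 2 on the asymmetric-only band, and 0 on unacquired lines, so that
    w(c) + w(-c) = 2 over the sampled region.
    """
    acq = acquired_lines(n_pe, scheme, encoding)
    if scheme.spectral_filter == "zero_fill":
        return acq.astype(float)
    if scheme.spectral_filter != "ramp":
        raise ValueError(f"unknown spectral filter {scheme.spectral_filter!r}")
    c = ((np.arange(n_pe) + n_pe // 2) % n_pe) - n_pe // 2
    _, side = scheme.pe_geometry(encoding)
    if side == "low":
        c = -c
    # side == 'high' geometry: negative side complete, positive truncated
    c_max = c[acq].max()
    taps = np.zeros(n_pe, dtype=float)
    if c_max <= 0:
        taps[acq] = 1.0
        return taps
    sym = np.abs(c) <= c_max
    taps[sym] = 1.0 - c[sym] / float(c_max)
    taps[acq & (c < -c_max)] = 2.0
    return taps


def _apply_pe_filter(img: np.ndarray, taps: np.ndarray, pe_axis: int) -> np.ndarray:
    """Apply G = F^H diag(taps) F along the PE axis of an image array."""
    ksp = np.fft.fft(img, axis=pe_axis, norm="ortho")
    shape = [1] * img.ndim
    shape[pe_axis] = len(taps)
    ksp *= taps.reshape(shape)
    return np.fft.ifft(ksp, axis=pe_axis, norm="ortho")


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _fov_mask(coils: CoilSet) -> np.ndarray:
    rss2 = (np.abs(coils.sensitivities) ** 2).sum(axis=0)
    return rss2 > (_SENS_TOL * rss2.max())


def _under_blocks(coils: CoilSet, scheme: SamplingScheme):
    """Per aliased set sensitivity Gram matrices for the UNDER regime.

    Returns (gram, pe_axis, K) with ``gram`` of shape (n_other, K, nz, U, U)
    where aliased voxels along the PE axis are separated by K = n_pe / U.
    """
    U = scheme.undersampling_factor
    s = coils.sensitivities
    if scheme.pe_axis == 0:
        s = s.transpose(0, 2, 1, 3)  # (L, other, pe, z)
    L, n_other, n_pe, nz = s.shape
    if n_pe % U:
        raise ValueError("undersampling factor must divide the PE grid size")
    K = n_pe // U
    s_sets = s.reshape(L, n_other, U, K, nz).transpose(0, 1, 3, 4, 2)  # (L,other,K,z,U)
    gram = np.einsum("lokzu,lokzv->okzuv", s_sets.conj(), s_sets)
    return gram, K


def _recon_batch(z: np.ndarray, coils: CoilSet, scheme: SamplingScheme,
                 encoding: int = 0, fov: np.ndarray | None = None) -> np.ndarray:
    """Reconstruct a batch of whitened k-space volumes sharing one encoding.

    ``z`` has shape (L, nx, ny, nz, B); returns (nx, ny, nz, B).
    """
    if fov is None:
        fov = _fov_mask(coils)
    img = _ifft2(z.transpose(1, 2, 3, 4, 0)).transpose(4, 0, 1, 2, 3)  # (L,...,B)
    num = np.einsum("lxyz,lxyzb->xyzb", coils.sensitivities.conj(), img)
    rss2 = (np.abs(coils.sensitivities) ** 2).sum(axis=0)

    if scheme.mode in ("FULL",) or (scheme.mode == "UNDER" and scheme.undersampling_factor == 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            y = num / rss2[..., None]
        y[~fov] = 0.0
        return y

    if scheme.mode == "UNDER":
        U = scheme.undersampling_factor
        gram, K = _under_blocks(coils, scheme)
        v = num
        if scheme.pe_axis == 0:
            v = v.transpose(1, 0, 2, 3)  # (other, pe, z, B)
        n_other, n_pe, nz, B = v.shape
        v_sets = v.reshape(n_other, U, K, nz, B).transpose(0, 2, 3, 1, 4)  # (o,K,z,U,B)
        A = gram / U  # E^H E blocks
        # ridge keeps rank-deficient (out-of-coverage) sets solvable; they are
        # zeroed by the FOV mask afterwards
        ridge = _EIG_FLOOR * np.einsum("okzuu->okz", A.real).max()
        A = A + ridge * np.eye(U)[None, None, None]
        x_sets = np.linalg.solve(A, v_sets)
        x = x_sets.transpose(0, 3, 1, 2, 4).reshape(n_other, n_pe, nz, B)
        if scheme.pe_axis == 0:
            x = x.transpose(1, 0, 2, 3)
        x[~fov] = 0.0
        return x

    # HALF / INTER: zero-filled voxelwise combine, then spectral filter G
    pe_axis, _ = scheme.pe_geometry(encoding)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = num / rss2[..., None]
    y[~fov] = 0.0
    taps = spectral_filter_taps(z.shape[1 + pe_axis], scheme, encoding)
    return _apply_pe_filter(y, taps, pe_axis)


def sense_reconstruct(kspace: KSpaceData, coils: CoilSet,
                      scheme: SamplingScheme | None = None) -> ComplexVolumeStack:
    """SENSE-reconstruct whitened k-space into a complex volume stack.

    Inputs must already be channel-whitened (see :func:`whiten_channels` and
    :func:`whiten_coils`); voxels without coil coverage are zeroed and
    excluded from the FOV mask (stored in ``meta['fov_mask']``).
    """
    scheme = scheme or kspace.scheme
    if coils.grid_shape != kspace.grid_shape:
        raise ValueError("coil maps and k-space grid shapes differ")
    fov = _fov_mask(coils)
    n_vol = kspace.n_volumes
    out = np.empty(kspace.grid_shape + (n_vol,), dtype=np.complex128)
    # group volumes by encoding so each group reconstructs as one batch
    for enc in scheme.encodings():
        cols = [n for n in range(n_vol) if scheme.encoding_of_volume(n) == enc]
        z = kspace.data[..., cols]
        out[..., cols] = _recon_batch(z, coils, scheme, enc, fov)
    return ComplexVolumeStack(data=out, meta={"fov_mask": fov, "regime": scheme.mode})


# ---------------------------------------------------------------------------
# noise models
# ---------------------------------------------------------------------------

@dataclass
class PatchCovariance:
    """Noise covariance of one patch's Casorati matrix.

    For stationary regimes ``matrix`` is the M x M spatial covariance (the
    covariance across volumes is the identity).  For the INTER regime the
    spatial covariance differs per encoding: ``per_encoding`` maps encoding
    index -> M x M matrix and ``volume_groups`` maps encoding -> column
    indices of the Casorati matrix.
    """

    matrix: np.ndarray | None = None
    per_encoding: dict | None = None
    volume_groups: dict | None = None
    members: np.ndarray | None = None

    @property
    def stationary(self) -> bool:
        return self.matrix is not None

    def mean_matrix(self) -> np.ndarray:
        """Column-count-weighted average spatial covariance."""
        if self.stationary:
            return self.matrix
        total = sum(len(v) for v in self.volume_groups.values())
        return sum(
            (len(self.volume_groups[a]) / total) * m
            for a, m in self.per_encoding.items()
        )


@dataclass
class NoiseModel:
    """Image-domain noise description produced by :func:`propagate_noise`."""

    regime: str
    grid_shape: tuple
    variance_map: np.ndarray | None = None
    # UNDER
    pe_axis: int | None = None
    undersampling_factor: int = 1
    block_cov: np.ndarray | None = None       # (n_other, K, nz, U, U)
    # HALF / INTER: per-encoding spatial models
    column_cov: dict = field(default_factory=dict)   # enc -> (n_other, nz, P, P)
    mc_draws: dict = field(default_factory=dict)     # enc -> (nx, ny, nz, n_draws)
    pe_axis_per_encoding: dict = field(default_factory=dict)
    volume_groups: dict = field(default_factory=dict)  # enc -> column indices
    method: str = "analytic"

    def patch_cov(self, members: np.ndarray) -> PatchCovariance:
        return marginalize_patch_cov(self, members)


def _analytic_column_cov(coils: CoilSet, scheme: SamplingScheme, encoding: int) -> np.ndarray:
    """Exact per-PE-column covariance for HALF-type regimes.

    The combine weights d_q = s_q^* / (s_q^H s_q) act voxelwise; the inverse
    DFT of the acquired-line mask couples voxels along the PE axis; the
    spectral filter G is circulant along PE.  Cross-column covariance is
    exactly zero.  Returns an array of shape (n_other, nz, P, P).
    """
    pe_axis, _ = scheme.pe_geometry(encoding)
    s = coils.sensitivities
    if pe_axis == 0:
        s = s.transpose(0, 2, 1, 3)
    L, n_other, P, nz = s.shape
    rss2 = (np.abs(s) ** 2).sum(axis=0)
    fov = rss2 > (_SENS_TOL * rss2.max())
    with np.errstate(divide="ignore", invalid="ignore"):
        d = s.conj() / rss2[None]
    d[:, ~fov] = 0.0
    mask = acquired_lines(P, scheme, encoding).astype(float)
    tau = np.fft.ifft(mask)  # tau(delta) = (1/P) sum_{k in acq} e^{2pi i k delta / P}
    delta = np.arange(P)[:, None] - np.arange(P)[None, :]
    T = tau[delta % P]
    coil_term = np.einsum("lopz,loqz->ozpq", d, d.conj())  # (other, z, P, P)
    C = coil_term * T[None, None]
    taps = spectral_filter_taps(P, scheme, encoding)
    # (F^H diag(g) F)_{pq} = (1/P) sum_k g_k e^{2pi i k (p-q)/P} = ifft(g)[(p-q) % P]
    Gm = np.fft.ifft(taps)[delta % P]
    return np.einsum("pq,ozqr,sr->ozps", Gm, C, Gm.conj())


def propagate_noise(
    coils: CoilSet,
    scheme: SamplingScheme,
    method: str = "auto",
    n_draws: int = 2000,
    seed: int = 0,
) -> NoiseModel:
    """Propagate unit whitened channel noise through the reconstruction.

    ``method`` is one of ``auto`` (analytic for FULL/UNDER, Monte-Carlo for
    HALF/INTER), ``analytic`` or ``monte_carlo``.  The Monte-Carlo path
    reconstructs ``n_draws`` noise-only k-space draws with the exact same
    operator used for data, and later forms patch covariances as sample
    covariances over the draws.
    """
    if method not in ("auto", "analytic", "monte_carlo"):
        raise ValueError(f"unknown propagation method {method!r}")
    grid_shape = coils.grid_shape
    rss2 = (np.abs(coils.sensitivities) ** 2).sum(axis=0)
    fov = _fov_mask(coils)

    if scheme.mode == "FULL" or (scheme.mode == "UNDER" and scheme.undersampling_factor == 1):
        if method == "monte_carlo":
            return _monte_carlo_model(coils, scheme, n_draws, seed)
        var = np.zeros(grid_shape)
        var[fov] = 1.0 / rss2[fov]
        return NoiseModel(regime="FULL", grid_shape=grid_shape, variance_map=var,
                          method="analytic")

    if scheme.mode == "UNDER":
        if method == "monte_carlo":
            return _monte_carlo_model(coils, scheme, n_draws, seed)
        U = scheme.undersampling_factor
        gram, K = _under_blocks(coils, scheme)
        ridge = _EIG_FLOOR * np.einsum("okzuu->okz", gram.real).max()
        cov = U * np.linalg.inv(gram + ridge * np.eye(U)[None, None, None])
        var = np.einsum("okzuu->okzu", cov.real)  # (other, K, z, U)
        var = var.transpose(0, 3, 1, 2).reshape(var.shape[0], U * K, var.shape[2])
        if scheme.pe_axis == 0:
            var = var.transpose(1, 0, 2)
        var = var * fov
        return NoiseModel(
            regime="UNDER", grid_shape=grid_shape, variance_map=var,
            pe_axis=scheme.pe_axis, undersampling_factor=U, block_cov=cov,
            method="analytic",
        )

    # HALF / INTER
    if method in ("auto", "monte_carlo"):
        return _monte_carlo_model(coils, scheme, n_draws, seed)
    nm = NoiseModel(regime=scheme.mode, grid_shape=grid_shape, method="analytic")
    n_vol = None if scheme.pe_axis_per_volume is None else len(scheme.pe_axis_per_volume)
    for enc in scheme.encodings():
        nm.column_cov[enc] = _analytic_column_cov(coils, scheme, enc)
        nm.pe_axis_per_encoding[enc] = scheme.pe_geometry(enc)[0]
        if scheme.mode == "INTER":
            nm.volume_groups[enc] = np.flatnonzero(scheme.pe_axis_per_volume == enc)
    if scheme.mode == "HALF":
        nm.volume_groups = {}
    var = np.zeros(grid_shape)
    for enc, cc in nm.column_cov.items():
        pe_axis = nm.pe_axis_per_encoding[enc]
        diag = np.einsum("ozpp->ozp", cc.real)  # (other, z, P)
        v = diag.transpose(0, 2, 1) if pe_axis == 1 else diag.transpose(2, 0, 1)
        var += v
    nm.variance_map = var / max(len(nm.column_cov), 1)
    return nm


def _monte_carlo_model(coils: CoilSet, scheme: SamplingScheme,
                       n_draws: int, seed: int) -> NoiseModel:
    rng = np.random.default_rng(seed)
    grid_shape = coils.grid_shape
    L = coils.n_coils
    fov = _fov_mask(coils)
    nm = NoiseModel(regime=scheme.mode, grid_shape=grid_shape, method="monte_carlo")
    var = np.zeros(grid_shape)
    encs = scheme.encodings()
    # chunk the draws so the (L, grid, chunk) noise arrays stay small
    chunk = max(1, min(n_draws, int(2e8 / (16 * L * np.prod(grid_shape)))))
    for enc in encs:
        mask = volume_mask(grid_shape, scheme, enc)
        parts = []
        done = 0
        while done < n_draws:
            b = min(chunk, n_draws - done)
            z = rng.standard_normal((L,) + grid_shape + (b,)) + 1j * rng.standard_normal(
                (L,) + grid_shape + (b,)
            )
            z /= np.sqrt(2.0)
            z *= mask[None, :, :, None, None]
            parts.append(_recon_batch(z, coils, scheme, enc, fov).astype(np.complex64))
            done += b
        draws = np.concatenate(parts, axis=-1)
        nm.mc_draws[enc] = draws
        nm.pe_axis_per_encoding[enc] = scheme.pe_geometry(enc)[0]
        if scheme.mode == "INTER":
            nm.volume_groups[enc] = np.flatnonzero(scheme.pe_axis_per_volume == enc)
        var += (np.abs(draws) ** 2).mean(axis=-1)
    nm.variance_map = var / len(encs)
    if scheme.mode == "UNDER":
        nm.pe_axis = scheme.pe_axis
        nm.undersampling_factor = scheme.undersampling_factor
    return nm


# ---------------------------------------------------------------------------
# patch marginalization and whitening
# ---------------------------------------------------------------------------

def _stationary_patch_matrix(nm: NoiseModel, members: np.ndarray, enc: int = 0) -> np.ndarray:
    members = np.asarray(members, dtype=int)
    M = len(members)
    nx, ny, nz = nm.grid_shape
    coords = np.stack(np.unravel_index(members, nm.grid_shape), axis=1)  # (M, 3)

    if nm.method == "monte_carlo":
        draws = nm.mc_draws[enc].reshape(nx * ny * nz, -1)[members]
        return (draws @ draws.conj().T) / draws.shape[1]

    if nm.regime == "FULL":
        return np.diag(nm.variance_map.reshape(-1)[members].astype(float))

    if nm.regime == "UNDER":
        U, pe = nm.undersampling_factor, nm.pe_axis
        K = nm.grid_shape[pe] // U
        cov = np.diag(nm.variance_map.reshape(-1)[members]).astype(np.complex128)
        other_axis = 1 - pe
        set_key = (coords[:, other_axis], coords[:, pe] % K, coords[:, 2],
                   coords[:, pe] // K)
        for i in range(M):
            for j in range(i + 1, M):
                same_set = (
                    set_key[0][i] == set_key[0][j]
                    and set_key[1][i] == set_key[1][j]
                    and set_key[2][i] == set_key[2][j]
                )
                if same_set:
                    blk = nm.block_cov[set_key[0][i], set_key[1][i], set_key[2][i]]
                    cov[i, j] = blk[set_key[3][i], set_key[3][j]]
                    cov[j, i] = np.conj(cov[i, j])
        return cov

    # analytic HALF/INTER: per-PE-column blocks, zero across columns
    pe = nm.pe_axis_per_encoding[enc]
    other_axis = 1 - pe
    cov = np.zeros((M, M), dtype=np.complex128)
    cc = nm.column_cov[enc]
    col_key = coords[:, other_axis] * nm.grid_shape[2] + coords[:, 2]
    for col in np.unique(col_key):
        idx = np.flatnonzero(col_key == col)
        o, z = divmod(int(col), nm.grid_shape[2])
        p = coords[idx, pe]
        cov[np.ix_(idx, idx)] = cc[o, z][np.ix_(p, p)]
    return cov


def marginalize_patch_cov(nm: NoiseModel, members: np.ndarray) -> PatchCovariance:
    """Restrict the image-domain noise covariance to a patch's member voxels.

    The returned covariance rows/columns follow the member ordering exactly
    (permuting members permutes the matrix consistently).
    """
    members = np.asarray(members, dtype=int)
    if nm.regime == "INTER":
        per_enc = {
            enc: _stationary_patch_matrix(nm, members, enc)
            for enc in (nm.column_cov or nm.mc_draws)
        }
        return PatchCovariance(per_encoding=per_enc, volume_groups=dict(nm.volume_groups),
                               members=members)
    enc = 0 if nm.regime != "INTER" else None
    if nm.method == "monte_carlo" and nm.regime in ("HALF",):
        enc = next(iter(nm.mc_draws))
    return PatchCovariance(matrix=_stationary_patch_matrix(nm, members, enc),
                           members=members)


def patch_whitener(pc: PatchCovariance) -> np.ndarray:
    """Whitening map with Upsilon_M^H Upsilon_M = Sigma_M^{-1}.

    Semi-definite covariances are regularized with an eigenvalue floor at
    1e-8 of the largest eigenvalue.  Only defined for stationary patch
    covariances (INTER families have no single whitener).
    """
    if not pc.stationary:
        raise ValueError("patch whitening requires a stationary covariance")
    sigma = np.asarray(pc.matrix, dtype=np.complex128)
    vals, vecs = np.linalg.eigh((sigma + sigma.conj().T) / 2.0)
    floor = _EIG_FLOOR * max(vals.max(), 0.0)
    if floor <= 0:
        raise ValueError("patch covariance has no positive eigenvalues")
    vals = np.maximum(vals, floor)
    return (vecs / np.sqrt(vals)).conj().T  # diag(1/sqrt(lam)) V^H
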