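"""Synthetic multi-shell diffusion phantom, coil arrays, and k-space sampling.

This module generates everything needed to exercise the denoising chain
without scanner data: a noise-free tensor-model diffusion phantom made of
nested ellipsoids, smooth complex coil sensitivity maps with a correlated
channel noise covariance, slicewise linear phase corruption, and Cartesian
multi-channel k-space sampling under four encoding regimes:

``FULL``
    fully sampled Cartesian encoding;
``UNDER``
    homogeneous in-plane undersampling by an integer factor ``U`` along the
    phase-encoding (PE) axis;
``HALF``
    partial-Fourier acquisition of a fraction of the PE lines, reconstructed
    with a zero-fill or homodyne-style ramp spectral filter;
``INTER``
    partial-Fourier with the PE encoding interleaved volumewise among up to
    four in-plane choices (two axes x two readout polarities).

All Fourier transforms are unitary DFTs over the full reconstruction grid,
applied per 2D slice (in-plane axes 0 and 1); k-space arrays are stored in
raw FFT order, with centered-index conventions used only when constructing
sampling masks and spectral filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ComplexVolumeStack

__all__ = [
    "Ellipsoid",
    "Region",
    "PhantomSpec",
    "CoilSet",
    "SamplingScheme",
    "PhaseCorruption",
    "KSpaceData",
    "default_spec",
    "make_phantom",
    "make_coils",
    "random_phase_corruption",
    "corrupt_phase",
    "sample_kspace",
    "fibonacci_directions",
]

SLICE_AXIS = 2
INPLANE_AXES = (0, 1)

# encoding index -> (PE axis, omitted k-space side) used by the INTER regime
INTER_ENCODINGS = {0: (1, "high"), 1: (1, "low"), 2: (0, "high"), 3: (0, "low")}


# ---------------------------------------------------------------------------
# geometry and phantom specification
# ---------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    """Axis-aligned-by-default ellipsoid in voxel coordinates.

    ``center`` and ``semi_axes`` are in voxel units; an optional rotation
    matrix orients the principal axes.
    """

    center: tuple
    semi_axes: tuple
    rotation: np.ndarray | None = None

    def mask(self, grid_shape) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        rel = np.stack(
            [idx[i] - self.center[i] for i in range(3)], axis=-1
        )  # (nx, ny, nz, 3)
        if self.rotation is not None:
            rel = rel @ np.asarray(self.rotation)
        scaled = rel / np.asarray(self.semi_axes, dtype=float)
        return (scaled ** 2).sum(axis=-1) <= 1.0


@dataclass
class Region:
    geometry: Ellipsoid
    s0: float
    tensor: np.ndarray  # 3x3 symmetric positive definite, um^2/ms

    def __post_init__(self):
        D = np.asarray(self.tensor, dtype=float)
        if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("diffusion tensor must be 3x3 symmetric")
        if np.linalg.eigvalsh(D).min() <= 0:
            raise ValueError("diffusion tensor must be positive definite")
        self.tensor = D


@dataclass
class PhantomSpec:
    """Full description of the synthetic object and diffusion protocol.

    ``shells`` holds b-values in ms/um^2 and ``directions`` one array of unit
    gradient vectors per shell.  Overlapping regions are painted in order:
    the later region wins.
    """

    grid_shape: tuple = (32, 32, 32)
    voxel_size: tuple = (2.5, 2.5, 2.5)
    shells: list = field(default_factory=list)
    directions: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.shells) != len(self.directions):
            raise ValueError("need one direction set per shell")
        for dirs in self.directions:
            dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
            norms = np.linalg.norm(dirs, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("gradient directions must be unit norm")

    @property
    def bvals(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(np.atleast_2d(d)), b) for b, d in zip(self.shells, self.directions)]
        )

    @property
    def bvecs(self) -> np.ndarray:
        return np.concatenate([np.atleast_2d(d) for d in self.directions], axis=0)

    @property
    def n_volumes(self) -> int:
        return sum(len(np.atleast_2d(d)) for d in self.directions)


def fibonacci_directions(n: int) -> np.ndarray:
    """Roughly uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    v = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _tensor(evals, rotation=None) -> np.ndarray:
    D = np.diag(np.asarray(evals, dtype=float))
    if rotation is not None:
        R = np.asarray(rotation)
        D = R @ D @ R.T
    return D


def _rot_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def default_spec(grid_shape=(32, 32, 32), seed: int = 0) -> PhantomSpec:
    """Default nested-ellipsoid phantom with a 4-shell, 48-volume protocol.

    The outer "brain" ellipsoid is nearly isotropic; two inner "tract"
    bundles carry strongly anisotropic tensors with distinct orientations,
    giving directional contrast between shells.
    """
    nx, ny, nz = grid_shape
    c = (nx / 2.0 - 0.5, ny / 2.0 - 0.5, nz / 2.0 - 0.5)
    brain = Region(
        geometry=Ellipsoid(center=c, semi_axes=(0.42 * nx, 0.42 * ny, 0.40 * nz)),
        s0=100.0,
        tensor=_tensor((0.9e-3, 0.8e-3, 0.85e-3)) * 1e3,  # ~isotropic, um^2/ms
    )
    tract1 = Region(
        geometry=Ellipsoid(
            center=(c[0] - 0.12 * nx, c[1], c[2]),
            semi_axes=(0.10 * nx, 0.26 * ny, 0.10 * nz),
        ),
        s0=110.0,
        tensor=_tensor((1.7e-3, 0.25e-3, 0.25e-3), _rot_z(np.pi / 2)) * 1e3,
    )
    tract2 = Region(
        geometry=Ellipsoid(
            center=(c[0] + 0.14 * nx, c[1], c[2]),
            semi_axes=(0.10 * nx, 0.22 * ny, 0.14 * nz),
            rotation=_rot_z(np.pi / 4),
        ),
        s0=105.0,
        tensor=_tensor((1.6e-3, 0.3e-3, 0.3e-3), _rot_z(np.pi / 4)) * 1e3,
    )
    shells = [0.0, 0.4, 1.0, 2.5]
    ndirs = [6, 12, 14, 16]
    directions = [fibonacci_directions(n) for n in ndirs]
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        shells=shells,
        directions=directions,
        regions=[brain, tract1, tract2],
        seed=seed,
    )


def make_phantom(spec: PhantomSpec) -> ComplexVolumeStack:
    """Evaluate the tensor model on the grid: S0 * exp(-b g^T D g).

    Background voxels are zero; the result is real-valued (zero phase)
    before any phase corruption is applied.
    """
    bvals, bvecs = spec.bvals, spec.bvecs
    n_vol = len(bvals)
    data = np.zeros(spec.grid_shape + (n_vol,), dtype=np.complex128)
    for region in spec.regions:
        mask = region.geometry.mask(spec.grid_shape)
        # signal per volume; g^T D g is a scalar per direction
        gdg = np.einsum("ni,ij,nj->n", bvecs, region.tensor, bvecs)
        signal = region.s0 * np.exp(-bvals * gdg)
        data[mask, :] = signal  # later region wins on overlap
    return ComplexVolumeStack(
        data=data, voxel_size=spec.voxel_size, bvals=bvals, bvecs=bvecs,
        meta={"seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# coils
# ---------------------------------------------------------------------------

@dataclass
class CoilSet:
    """Complex receive sensitivities and the channel noise covariance."""

    sensitivities: np.ndarray  # (L, nx, ny, nz) complex
    channel_cov: np.ndarray    # (L, L) Hermitian positive definite

    def __post_init__(self):
        self.sensitivities = np.asarray(self.sensitivities, dtype=np.complex128)
        cov = np.asarray(self.channel_cov, dtype=np.complex128)
        if not np.allclose(cov, cov.conj().T, atol=1e-10):
            raise ValueError("channel covariance must be Hermitian")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("channel covariance must be positive definite")
        self.channel_cov = cov

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.sensitivities.shape[1:]


def make_coils(
    grid_shape,
    n_coils: int = 8,
    seed: int = 0,
    correlation: float = 0.25,
    uniform: bool = False,
) -> CoilSet:
    """Smooth complex coil sensitivity lobes around the FOV boundary.

    Each coil is a spatial Gaussian magnitude lobe centered outside the
    in-plane FOV circle at evenly spaced angles (jittered by ``seed``), with
    a smooth linear phase.  The channel covariance is an exponential-decay
    Toeplitz matrix ``correlation**|i-j|`` (Hermitian positive definite for
    |correlation| < 1).  With ``uniform=True`` every coil is 1 everywhere
    and the covariance is the identity.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    grid_shape = tuple(grid_shape)
    if uniform:
        sens = np.ones((n_coils,) + grid_shape, dtype=np.complex128)
        cov = np.eye(n_coils, dtype=np.complex128)
        return CoilSet(sensitivities=sens, channel_cov=cov)

    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    X, Y, Z = np.indices(grid_shape, dtype=float)
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    radius = 0.65 * max(nx, ny)
    width = 0.55 * max(nx, ny)
    angles = 2 * np.pi * (np.arange(n_coils) + rng.uniform(0, 1)) / n_coils
    sens = np.empty((n_coils,) + grid_shape, dtype=np.complex128)
    for c, ang in enumerate(angles):
        px = cx + radius * np.cos(ang)
        py = cy + radius * np.sin(ang)
        pz = cz + rng.uniform(-0.2, 0.2) * nz
        d2 = (X - px) ** 2 + (Y - py) ** 2 + 0.25 * (Z - pz) ** 2
        mag = np.exp(-d2 / (2 * width ** 2))
        # smooth linear phase per coil
        gx, gy, gz = rng.uniform(-np.pi, np.pi, size=3) / max(nx, ny, nz)
        phase = gx * (X - cx) + gy * (Y - cy) + gz * (Z - cz) + rng.uniform(0, 2 * np.pi)
        sens[c] = mag * np.exp(1j * phase)
    # normalize so the root-sum-of-squares is ~1 at FOV center
    rss = np.sqrt((np.abs(sens) ** 2).sum(axis=0))
    sens /= rss[nx // 2, ny // 2, nz // 2]
    idx = np.arange(n_coils)
    cov = correlation ** np.abs(idx[:, None] - idx[None, :])
    return CoilSet(sensitivities=sens, channel_cov=cov.astype(np.complex128))


# ---------------------------------------------------------------------------
# sampling scheme
# ---------------------------------------------------------------------------

@dataclass
class SamplingScheme:
    """Cartesian sampling structure for one acquisition.

    ``pe_axis`` is the in-plane phase-encoding axis (0 or 1) for the
    stationary regimes; for ``INTER`` the encoding per volume is given by
    ``pe_axis_per_volume`` indexing :data:`INTER_ENCODINGS`.
    ``spectral_filter`` selects the partial-Fourier filter G: ``zero_fill``
    or ``ramp`` (homodyne-style); ``none`` is only valid for FULL/UNDER.
    """

    mode: str = "FULL"
    undersampling_factor: int = 1
    pf_fraction: float = 1.0
    pe_axis: int = 1
    pf_side: str = "high"
    pe_axis_per_volume: np.ndarray | None = None
    spectral_filter: str = "none"

    def __post_init__(self):
        if self.mode not in ("FULL", "UNDER", "HALF", "INTER"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.mode not in ("HALF", "INTER") and self.pf_fraction != 1.0:
            raise ValueError("pf_fraction must be 1 unless mode is HALF or INTER")
        if self.mode in ("HALF", "INTER"):
            if not (0.5 <= self.pf_fraction <= 1.0):
                raise ValueError("pf_fraction must lie in [0.5, 1]")
            if self.undersampling_factor != 1:
                raise ValueError(
                    "unsupported regime combination: partial Fourier with "
                    "in-plane undersampling is not implemented"
                )
            if self.spectral_filter not in ("zero_fill", "ramp"):
                raise ValueError("HALF/INTER require spectral_filter zero_fill or ramp")
        if self.mode == "UNDER" and self.undersampling_factor < 1:
            raise ValueError("undersampling factor must be >= 1")
        if self.mode == "INTER" and self.pe_axis_per_volume is None:
            raise ValueError("INTER requires pe_axis_per_volume")
        if self.pe_axis not in (0, 1):
            raise ValueError("pe_axis must be an in-plane axis (0 or 1)")
        if self.pe_axis_per_volume is not None:
            self.pe_axis_per_volume = np.asarray(self.pe_axis_per_volume, dtype=int)

    def encoding_of_volume(self, n: int) -> int:
        if self.mode == "INTER":
            return int(self.pe_axis_per_volume[n])
        return 0

    def encodings(self) -> list:
        if self.mode == "INTER":
            return sorted(set(self.pe_axis_per_volume.tolist()))
        return [0]

    def pe_geometry(self, encoding: int = 0) -> tuple:
        """Return (pe_axis, pf_side) for an encoding index."""
        if self.mode == "INTER":
            return INTER_ENCODINGS[int(encoding)]
        return self.pe_axis, self.pf_side


def _centered_indices(n: int) -> np.ndarray:
    """Centered k-space index of each raw-FFT-order position."""
    return ((np.arange(n) + n // 2) % n) - n // 2


def acquired_lines(n_pe: int, scheme: SamplingScheme, encoding: int = 0) -> np.ndarray:
    """Boolean acquired-line mask along the PE axis, in raw FFT order."""
    c = _centered_indices(n_pe)
    if scheme.mode == "FULL":
        return np.ones(n_pe, dtype=bool)
    if scheme.mode == "UNDER":
        # every U-th line of the full grid, keeping DC
        if n_pe % scheme.undersampling_factor:
            raise ValueError("undersampling factor must divide the PE grid size")
        return (np.arange(n_pe) % scheme.undersampling_factor) == 0
    n_acq = int(round(scheme.pf_fraction * n_pe))
    if n_acq < 1:
        raise ValueError("partial-Fourier fraction yields fewer than one line")
    _, side = scheme.pe_geometry(encoding)
    if side == "high":
        # omit the highest positive frequencies
        return c <= (n_acq - 1 - n_pe // 2)
    return c >= (n_pe - n_acq) - n_pe // 2


def volume_mask(grid_shape, scheme: SamplingScheme, encoding: int = 0) -> np.ndarray:
    """In-plane (nx, ny) boolean k-space mask for one encoding."""
    nx, ny, _ = grid_shape
    pe_axis, _ = scheme.pe_geometry(encoding)
    n_pe = (nx, ny)[pe_axis]
    line = acquired_lines(n_pe, scheme, encoding)
    mask = np.ones((nx, ny), dtype=bool)
    if pe_axis == 0:
        mask &= line[:, None]
    else:
        mask &= line[None, :]
    return mask


# ---------------------------------------------------------------------------
# phase corruption
# ---------------------------------------------------------------------------

@dataclass
class PhaseCorruption:
    """Per (slice, volume) linear phase: harmonics (cycles/FOV) and offsets.

    ``harmonics`` has shape (nz, N, 2) in cycles per FOV along the in-plane
    axes; ``offsets`` has shape (nz, N) in radians.  The ramp's phase origin
    is the grid center index ``n // 2``.
    """

    harmonics: np.ndarray
    offsets: np.ndarray

    def __post_init__(self):
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.harmonics.shape[:2] != self.offsets.shape or self.harmonics.shape[2] != 2:
            raise ValueError("harmonics must be (nz, N, 2) and offsets (nz, N)")

    def phase_map(self, grid_shape) -> np.ndarray:
        """Unit-modulus phase factor, shape (nx, ny, nz, N)."""
        nx, ny, nz = grid_shape
        rx = (np.arange(nx) - nx // 2) / nx
        ry = (np.arange(ny) - ny // 2) / ny
        kx = self.harmonics[None, None, :, :, 0]  # (1,1,nz,N)
        ky = self.harmonics[None, None, :, :, 1]
        ang = (
            2 * np.pi * (kx * rx[:, None, None, None] + ky * ry[None, :, None, None])
            + self.offsets[None, None, :, :]
        )
        return np.exp(1j * ang)


def random_phase_corruption(
    grid_shape,
    bvals,
    seed: int = 0,
    max_harmonic: float = 3.0,
    amplitude_scale: float = 1.0,
    integer_harmonics: bool = True,
) -> PhaseCorruption:
    """Draw slicewise linear phase corruption.

    Ramp amplitude grows as sqrt(b / b_max), reflecting stronger phase
    fluctuations at higher diffusion sensitization; ``integer_harmonics``
    restricts ramps to the DFT harmonic lattice (where demodulation by peak
    picking is exact).
    """
    rng = np.random.default_rng(seed)
    bvals = np.asarray(bvals, dtype=float)
    nz = grid_shape[2]
    n_vol = len(bvals)
    bmax = bvals.max() if bvals.max() > 0 else 1.0
    scale = amplitude_scale * np.sqrt(bvals / bmax)  # (N,)
    raw = rng.uniform(-max_harmonic, max_harmonic, size=(nz, n_vol, 2))
    harmonics = raw * scale[None, :, None]
    if integer_harmonics:
        harmonics = np.round(harmonics)
    offsets = rng.uniform(-np.pi, np.pi, size=(nz, n_vol)) * (scale[None, :] > 0)
    return PhaseCorruption(harmonics=harmonics, offsets=offsets)


def corrupt_phase(x: ComplexVolumeStack, pc: PhaseCorruption) -> ComplexVolumeStack:
    """Multiply each slice of each volume by its unit-modulus linear phase."""
    nz, n_vol = pc.offsets.shape
    if x.grid_shape[2] != nz or x.n_volumes != n_vol:
        raise ValueError("phase corruption shape does not match the stack")
    return x.copy_with(x.data * pc.phase_map(x.grid_shape))


# ---------------------------------------------------------------------------
# k-space sampling
# ---------------------------------------------------------------------------

@dataclass
class KSpaceData:
    """Sampled multi-channel k-space: (L, nx, ny, nz, N) in raw FFT order.

    ``mask`` is (nx, ny, N): the acquired in-plane lines per volume (shared
    across slices).  Unacquired samples are exactly zero.
    """

    data: np.ndarray
    mask: np.ndarray
    scheme: SamplingScheme
    noise_sigma: float = 0.0

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[1:4]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[4]


def _fft2(img: np.ndarray) -> np.ndarray:
    """Unitary forward 2D DFT over the in-plane axes (0, 1)."""
    return np.fft.fft2(img, axes=INPLANE_AXES, norm="ortho")


def _ifft2(ksp: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(ksp, axes=INPLANE_AXES, norm="ortho")


def sample_kspace(
    x: ComplexVolumeStack,
    coils: CoilSet,
    scheme: SamplingScheme,
    noise_sigma: float = 1.0,
    seed: int = 0,
) -> KSpaceData:
    """Sample multi-channel Cartesian k-space with channel-correlated noise.

    Per volume n: ``z_n = mask * F(S x_n) + w_n`` with ``F`` the unitary
    in-plane DFT and ``w_n`` circularly symmetric complex Gaussian noise of
    per-sample channel covariance ``noise_sigma**2 * channel_cov``,
    independent across k-space samples and volumes.
    """
    if coils.grid_shape != x.grid_shape:
        raise ValueError("coil maps and image grid shapes differ")
    rng = np.random.default_rng(seed)
    nx, ny, nz = x.grid_shape
    n_vol = x.n_volumes
    L = coils.n_coils
    z = np.zeros((L, nx, ny, nz, n_vol), dtype=np.complex128)
    mask = np.zeros((nx, ny, n_vol), dtype=bool)
    chol = np.linalg.cholesky(coils.channel_cov)

    for n in range(n_vol):
        m = volume_mask(x.grid_shape, scheme, scheme.encoding_of_volume(n))
        mask[:, :, n] = m
        coil_imgs = coils.sensitivities * x.data[None, :, :, :, n]
        ksp = _fft2(coil_imgs.transpose(1, 2, 3, 0)).transpose(3, 0, 1, 2)
        ksp *= m[None, :, :, None]
        z[..., n] = ksp

    if noise_sigma > 0:
        # unit complex Gaussian, correlated across channels via Cholesky
        w = rng.standard_normal((L, nx, ny, nz, n_vol)) + 1j * rng.standard_normal(
            (L, nx, ny, nz, n_vol)
        )
        w *= noise_sigma / np.sqrt(2.0)
        w = np.einsum("cl,l...->c...", chol, w)
        w *= mask[None, :, :, None, :]
        z += w
    return KSpaceData(data=z, mask=mask, scheme=scheme, noise_sigma=noise_sigma)
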