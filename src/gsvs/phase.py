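"""Slicewise linear phase estimation, demodulation, and remodulation.

Bulk motion during the diffusion gradients leaves each reconstructed slice
with an approximately linear phase (a ramp plus a constant offset) that
differs per volume and slice.  Left in place, it inflates the rank of the
patch Casorati matrices; removing even a gross linear approximation makes
the complex signal far more redundant.  By the Fourier shift theorem, a
linear phase ramp shifts the slice spectrum: the ramp is read off as the
harmonic of the peak of the 2D DFT magnitude and the offset as the phase of
that peak coefficient.  Only integer-bin harmonics are used by default — a
deliberately robust gross approximation; subpixel refinement is available
behind a flag.

The estimated field is stored with the raw peak phase; the reconstruction of
the unit-modulus phase factor uses an index-0 ramp origin, which makes the
estimate-then-demodulate round trip exact (up to the global phase of the
slice's own DC coefficient) for integer-harmonic corruption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ComplexVolumeStack

__all__ = [
    "LinearPhaseField",
    "estimate_linear_phase",
    "estimate_phase_field",
    "demodulate",
    "remodulate",
    "export_phase_table",
]


@dataclass
class LinearPhaseField:
    """Per (slice, volume) integer harmonics and offsets.

    ``harmonics``: (nz, N, 2) integers (DFT bins, centered convention);
    ``offsets``: (nz, N) radians.  Applying then conjugate-applying the
    field is the identity and the factor has unit modulus everywhere.
    """

    harmonics: np.ndarray
    offsets: np.ndarray
    grid_shape: tuple

    def phase_factor(self) -> np.ndarray:
        """Unit-modulus factor Phi of shape (nx, ny, nz, N)."""
        nx, ny, nz = self.grid_shape
        rx = np.arange(nx) / nx
        ry = np.arange(ny) / ny
        kx = self.harmonics[None, None, :, :, 0]
        ky = self.harmonics[None, None, :, :, 1]
        ang = (
            2 * np.pi * (kx * rx[:, None, None, None] + ky * ry[None, :, None, None])
            + self.offsets[None, None, :, :]
        )
        return np.exp(1j * ang)


def estimate_linear_phase(slice_image: np.ndarray, subpixel: bool = False):
    """Estimate (harmonic, offset) of the dominant linear phase of a slice.

    Returns the centered-harmonic location of the peak of ``|DFT|`` and the
    phase of the DFT coefficient there.  An all-zero slice returns zeros.
    """
    img = np.asarray(slice_image)
    if img.ndim != 2:
        raise ValueError("expected a 2D slice")
    if not np.any(img):
        return np.zeros(2), 0.0
    spec = np.fft.fft2(img)
    idx = np.unravel_index(np.argmax(np.abs(spec)), spec.shape)
    n = np.array(spec.shape)
    harmonic = (np.array(idx) + n // 2) % n - n // 2
    offset = float(np.angle(spec[idx]))
    if subpixel:
        # parabolic refinement of the log-magnitude peak per axis
        harmonic = harmonic.astype(float)
        for ax in (0, 1):
            lo = list(idx); hi = list(idx)
            lo[ax] = (idx[ax] - 1) % n[ax]
            hi[ax] = (idx[ax] + 1) % n[ax]
            a, b, c = (np.abs(spec[tuple(lo)]), np.abs(spec[idx]), np.abs(spec[tuple(hi)]))
            denom = a - 2 * b + c
            if denom != 0:
                harmonic[ax] += 0.5 * (a - c) / denom
    return harmonic, offset


def estimate_phase_field(y: ComplexVolumeStack, subpixel: bool = False) -> LinearPhaseField:
    """Estimate the linear phase per 2D slice per volume (b=0 included)."""
    nx, ny, nz = y.grid_shape
    n_vol = y.n_volumes
    harmonics = np.zeros((nz, n_vol, 2), dtype=float if subpixel else int)
    offsets = np.zeros((nz, n_vol))
    for z in range(nz):
        for n in range(n_vol):
            h, off = estimate_linear_phase(y.data[:, :, z, n], subpixel=subpixel)
            harmonics[z, n] = h
            offsets[z, n] = off
    return LinearPhaseField(harmonics=harmonics, offsets=offsets, grid_shape=y.grid_shape)


def demodulate(y: ComplexVolumeStack, field: LinearPhaseField) -> ComplexVolumeStack:
    """y_tilde = Phi^H y: subtract the linear phase (magnitude preserved)."""
    return y.copy_with(y.data * np.conj(field.phase_factor()))


def remodulate(x: ComplexVolumeStack, field: LinearPhaseField) -> ComplexVolumeStack:
    """x_hat = Phi x_tilde_hat: exact inverse of :func:`demodulate`."""
    return x.copy_with(x.data * field.phase_factor())


def export_phase_table(field: LinearPhaseField, path) -> None:
    """Write a (slice, volume, kx, ky, offset) audit table as TSV."""
    nz, n_vol = field.offsets.shape
    with open(path, "w") as fh:
        fh.write("slice\tvolume\tkx\tky\toffset\n")
        for z in range(nz):
            for n in range(n_vol):
                kx, ky = field.harmonics[z, n]
                fh.write(f"{z}\t{n}\t{kx:g}\t{ky:g}\t{field.offsets[z, n]:.6f}\n")
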