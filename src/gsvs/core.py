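"""Core containers shared across the package.

The canonical in-memory object is a :class:`ComplexVolumeStack`: a 3D voxel
grid of ``Q`` voxels carrying ``N`` complex diffusion-weighted volumes, stored
as a single complex array of shape ``(nx, ny, nz, N)``.  Axes 0 and 1 are the
in-plane axes (one of them is the phase-encoding axis), axis 2 is the slice
axis.  Voxel indexing is 0-based and row-major over ``(x, y, z)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ComplexVolumeStack"]


@dataclass
class ComplexVolumeStack:
    """A stack of complex diffusion volumes on a common voxel grid.

    Parameters
    ----------
    data : complex ndarray, shape (nx, ny, nz, N)
        Complex image values; volume index last.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    bvals : ndarray of shape (N,), optional
        Diffusion sensitization per volume (ms/um^2).
    bvecs : ndarray of shape (N, 3), optional
        Unit gradient direction per volume.
    """

    data: np.ndarray
    voxel_size: tuple = (2.5, 2.5, 2.5)
    bvals: np.ndarray | None = None
    bvecs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected a (nx, ny, nz, N) array, got shape {self.data.shape}"
            )
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.grid_shape
        return nx * ny * nz

    def flat(self) -> np.ndarray:
        """Return a (Q, N) view with voxels flattened row-major."""
        return self.data.reshape(self.n_voxels, self.n_volumes)

    def copy_with(self, data: np.ndarray) -> "ComplexVolumeStack":
        return ComplexVolumeStack(
            data=data,
            voxel_size=self.voxel_size,
            bvals=None if self.bvals is None else np.asarray(self.bvals).copy(),
            bvecs=None if self.bvecs is None else np.asarray(self.bvecs).copy(),
            meta=dict(self.meta),
        )
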