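"""Spherical sliding patches: layout, Casorati extraction, and assembly.

Patches are spheres in voxel space: each patch is the set of the M voxels
closest (Euclidean distance, ties broken by lexicographic flat index) to a
center voxel, restricted to the FOV, so the sphere deforms at boundaries
instead of zero-padding.  Patch centers slide on a stride-T lattice over the
FOV, augmented with extra centers so every FOV voxel is covered by at least
one patch.  The patch voxel count follows from the requested aspect ratio
gamma of the Casorati matrix: M = round(gamma * N).

Overlapping per-patch estimates are merged by a convex per-voxel combination
(weights form a partition of unity): uniform, inverse-variance
(1 / per-patch AMSE), or Gaussian-in-distance weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PatchLayout",
    "AssemblyWeights",
    "build_layout",
    "extract",
    "assemble",
    "nominal_patch_radius",
]


def nominal_patch_radius(M: int) -> float:
    """Radius (voxels) of a sphere holding M unit-voxel cells."""
    return (3.0 * M / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class PatchLayout:
    """Sliding spherical patch geometry on a voxel grid.

    ``centers``: (n_patches, 3) voxel coordinates; ``member_lists``:
    (n_patches, M) flat voxel indices ordered by non-decreasing distance
    from the center (ties by flat index); ``gamma`` = M / N.
    """

    grid_shape: tuple
    centers: np.ndarray
    member_lists: np.ndarray
    M: int
    N: int
    stride: int

    @property
    def gamma(self) -> float:
        return self.M / self.N

    @property
    def n_patches(self) -> int:
        return len(self.centers)

    def member_distances(self) -> np.ndarray:
        """Euclidean distance of each member voxel to its patch center."""
        coords = np.stack(np.unravel_index(self.member_lists, self.grid_shape), axis=-1)
        rel = coords - self.centers[:, None, :]
        return np.sqrt((rel.astype(float) ** 2).sum(axis=-1))


@dataclass
class AssemblyWeights:
    """Patch combination rule: 'uniform', 'inverse_variance' or 'gaussian'.

    ``gaussian_width`` defaults to half the nominal patch radius when None.
    """

    scheme: str = "inverse_variance"
    gaussian_width: float | None = None

    def __post_init__(self):
        if self.scheme not in ("uniform", "inverse_variance", "gaussian"):
            raise ValueError(f"unknown assembly scheme {self.scheme!r}")


def _nearest_members(tree: cKDTree, fov_flat: np.ndarray, center: np.ndarray,
                     M: int, n_fov: int) -> np.ndarray:
    """M nearest FOV voxels by (squared distance, flat index)."""
    k = min(M + 64, n_fov)
    while True:
        d, idx = tree.query(center, k=k)
        d, idx = np.atleast_1d(d), np.atleast_1d(idx)
        # integer squared distances make tie detection exact
        d2 = np.round(d * d).astype(np.int64)
        if k == n_fov or d2[M - 1] < d2[-1]:
            break
        k = min(2 * k, n_fov)
    order = np.lexsort((fov_flat[idx], d2))
    return fov_flat[idx[order[:M]]]


def build_layout(fov_mask: np.ndarray, N: int, gamma: float, stride: int = 2) -> PatchLayout:
    """Build a spherical patch layout covering the FOV.

    M = round(gamma * N); centers lie on a stride lattice intersected with
    the FOV and are augmented until every FOV voxel belongs to >= 1 patch.
    """
    if gamma <= 0 or N < 1 or stride < 1:
        raise ValueError("need gamma > 0, N >= 1, stride >= 1")
    fov_mask = np.asarray(fov_mask, dtype=bool)
    M = max(int(round(gamma * N)), 1)
    n_fov = int(fov_mask.sum())
    if M > n_fov:
        raise ValueError(f"patch size M={M} exceeds the {n_fov}-voxel FOV")

    fov_coords = np.argwhere(fov_mask)
    fov_flat = np.ravel_multi_index(fov_coords.T, fov_mask.shape)
    tree = cKDTree(fov_coords.astype(float))

    on_lattice = np.all(fov_coords % stride == 0, axis=1)
    centers = [fov_coords[on_lattice]] if on_lattice.any() else []
    center_list = centers[0].tolist() if centers else []

    members = [
        _nearest_members(tree, fov_flat, np.asarray(c, dtype=float), M, n_fov)
        for c in center_list
    ]
    covered = np.zeros(fov_mask.shape, dtype=bool)
    for m in members:
        covered.reshape(-1)[m] = True

    # augment with centers at uncovered voxels until the FOV is covered
    uncovered = fov_mask & ~covered
    while uncovered.any():
        c = np.argwhere(uncovered)[0]
        m = _nearest_members(tree, fov_flat, c.astype(float), M, n_fov)
        center_list.append(c.tolist())
        members.append(m)
        covered.reshape(-1)[m] = True
        uncovered = fov_mask & ~covered

    return PatchLayout(
        grid_shape=fov_mask.shape,
        centers=np.asarray(center_list, dtype=int),
        member_lists=np.asarray(members, dtype=np.int64),
        M=M,
        N=N,
        stride=stride,
    )


def extract(stack, layout: PatchLayout, noise_model=None):
    """Yield (patch_index, Y, PatchCovariance) per patch.

    Row m of Y is the m-closest member voxel's N-vector of complex values;
    the covariance is the noise model marginalized to the member voxels (or
    None when no noise model is given).
    """
    flat = stack.flat()
    for i in range(layout.n_patches):
        members = layout.member_lists[i]
        Y = flat[members, :]
        cov = noise_model.patch_cov(members) if noise_model is not None else None
        yield i, Y, cov


def assemble(
    estimates,
    layout: PatchLayout,
    weights: AssemblyWeights | None = None,
    amse: np.ndarray | None = None,
    fov_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Combine overlapping patch estimates into (nx, ny, nz, N) volumes.

    ``estimates`` is a sequence (or dict patch_index -> matrix) of M x N
    per-patch estimates.  Per output voxel the contributing patch values are
    averaged with weights normalized to sum to one; a voxel covered by no
    patch violates the layout guarantee and raises.
    """
    weights = weights or AssemblyWeights()
    n_vox = int(np.prod(layout.grid_shape))
    num = np.zeros((n_vox, layout.N), dtype=np.complex128)
    den = np.zeros(n_vox)

    if weights.scheme == "gaussian":
        width = weights.gaussian_width
        if width is None:
            width = 0.5 * nominal_patch_radius(layout.M)
        dist = layout.member_distances()
        w_geo = np.exp(-(dist ** 2) / (2.0 * width ** 2))
    else:
        w_geo = None

    if weights.scheme == "inverse_variance":
        if amse is None:
            raise ValueError("inverse_variance assembly needs per-patch AMSE values")
        amse = np.asarray(amse, dtype=float)
        floor = max(amse[amse > 0].min() if np.any(amse > 0) else 1.0, 1e-30)
        w_patch = 1.0 / np.maximum(amse, 1e-3 * floor)
    else:
        w_patch = None

    items = estimates.items() if isinstance(estimates, dict) else enumerate(estimates)
    for i, X in items:
        members = layout.member_lists[i]
        if weights.scheme == "uniform":
            w = np.ones(len(members))
        elif weights.scheme == "inverse_variance":
            w = np.full(len(members), w_patch[i])
        else:
            w = w_geo[i]
        num[members] += w[:, None] * X
        den[members] += w

    covered = den > 0
    if fov_mask is not None and np.any(np.asarray(fov_mask, bool).reshape(-1) & ~covered):
        raise ValueError("assembly found FOV voxels covered by no patch")
    out = np.zeros_like(num)
    out[covered] = num[covered] / den[covered, None]
    return out.reshape(layout.grid_shape + (layout.N,))
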