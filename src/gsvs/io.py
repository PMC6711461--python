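"""HDF5 container and NIfTI export helpers.

A single HDF5 file carries a simulated acquisition end to end: the
ground-truth complex stack, coil sensitivities and channel covariance,
sampled k-space with its mask, and the true phase corruption.  Complex
volumes export to NIfTI as paired files (``_real``/``_imag`` or
``_mag``/``_phase``) because complex NIfTI support is inconsistent across
tools; magnitude-only views export as single files.
"""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np

from .core import ComplexVolumeStack
from .phantom import CoilSet, KSpaceData, PhaseCorruption, SamplingScheme

__all__ = [
    "save_container",
    "load_container",
    "export_nifti",
    "export_complex_nifti",
]


def save_container(path, truth: ComplexVolumeStack | None = None,
                   coils: CoilSet | None = None,
                   kspace: KSpaceData | None = None,
                   phase_true: PhaseCorruption | None = None,
                   extra: dict | None = None) -> None:
    """Write a simulation container with named datasets."""
    with h5py.File(path, "w") as f:
        if truth is not None:
            f.create_dataset("truth", data=truth.data)
            f.attrs["voxel_size"] = truth.voxel_size
            if truth.bvals is not None:
                f.create_dataset("bvals", data=truth.bvals)
            if truth.bvecs is not None:
                f.create_dataset("bvecs", data=truth.bvecs)
        if coils is not None:
            f.create_dataset("coils", data=coils.sensitivities)
            f.create_dataset("channel_cov", data=coils.channel_cov)
        if kspace is not None:
            f.create_dataset("kspace", data=kspace.data)
            f.create_dataset("mask", data=kspace.mask)
            s = kspace.scheme
            grp = f.create_group("scheme")
            grp.attrs.update({
                "mode": s.mode, "undersampling_factor": s.undersampling_factor,
                "pf_fraction": s.pf_fraction, "pe_axis": s.pe_axis,
                "pf_side": s.pf_side, "spectral_filter": s.spectral_filter,
                "noise_sigma": kspace.noise_sigma,
            })
            if s.pe_axis_per_volume is not None:
                grp.create_dataset("pe_axis_per_volume", data=s.pe_axis_per_volume)
        if phase_true is not None:
            f.create_dataset("phase_true/harmonics", data=phase_true.harmonics)
            f.create_dataset("phase_true/offsets", data=phase_true.offsets)
        for key, val in (extra or {}).items():
            f.create_dataset(key, data=val)


def load_container(path) -> dict:
    """Load a simulation container; returns a dict of reconstructed objects."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "truth" in f:
            out["truth"] = ComplexVolumeStack(
                data=f["truth"][()],
                voxel_size=tuple(f.attrs.get("voxel_size", (1.0, 1.0, 1.0))),
                bvals=f["bvals"][()] if "bvals" in f else None,
                bvecs=f["bvecs"][()] if "bvecs" in f else None,
            )
        if "coils" in f:
            out["coils"] = CoilSet(sensitivities=f["coils"][()],
                                   channel_cov=f["channel_cov"][()])
        if "kspace" in f:
            grp = f["scheme"]
            scheme = SamplingScheme(
                mode=grp.attrs["mode"],
                undersampling_factor=int(grp.attrs["undersampling_factor"]),
                pf_fraction=float(grp.attrs["pf_fraction"]),
                pe_axis=int(grp.attrs["pe_axis"]),
                pf_side=str(grp.attrs["pf_side"]),
                spectral_filter=str(grp.attrs["spectral_filter"]),
                pe_axis_per_volume=(grp["pe_axis_per_volume"][()]
                                    if "pe_axis_per_volume" in grp else None),
            )
            out["kspace"] = KSpaceData(
                data=f["kspace"][()], mask=f["mask"][()], scheme=scheme,
                noise_sigma=float(grp.attrs.get("noise_sigma", 0.0)),
            )
        if "phase_true" in f:
            out["phase_true"] = PhaseCorruption(
                harmonics=f["phase_true/harmonics"][()],
                offsets=f["phase_true/offsets"][()],
            )
    return out


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def export_nifti(array: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a real-valued array (3D or 4D) as a NIfTI file."""
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), _affine(voxel_size)), str(path))


def export_complex_nifti(stack: ComplexVolumeStack, prefix,
                         dialect: str = "real_imag") -> tuple:
    """Write a complex stack as a NIfTI pair; returns the two paths."""
    if dialect == "real_imag":
        parts = {"_real": stack.data.real, "_imag": stack.data.imag}
    elif dialect == "mag_phase":
        parts = {"_mag": np.abs(stack.data), "_phase": np.angle(stack.data)}
    else:
        raise ValueError("dialect must be 'real_imag' or 'mag_phase'")
    paths = []
    for suffix, arr in parts.items():
        p = f"{prefix}{suffix}.nii.gz"
        export_nifti(arr, p, stack.voxel_size)
        paths.append(p)
    return tuple(paths)
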