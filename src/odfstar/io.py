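"""Readers and writers: NIfTI volumes, FSL gradient tables, reports.

The on-disk bundle mirrors a standard FSL-style diffusion layout:
``dwi.nii.gz`` (4D), ``bvals`` (one space-separated row of b-values in
s/mm^2) and ``bvecs`` (three rows: x, y, z components, image coordinate
frame), plus optional ``mask.nii.gz`` and a JSON ground-truth sidecar
for simulated data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .simulate import GradientScheme, RigidMotion, SimulatedAcquisition

__all__ = [
    "AcquisitionBundle",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "save_acquisition",
    "load_acquisition",
    "save_odf_image",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AcquisitionBundle:
    """Paths of one diffusion acquisition on disk."""

    dwi_path: Path
    bvals_path: Path
    bvecs_path: Path
    mask_path: Path | None = None

    @classmethod
    def in_dir(cls, directory: str | Path) -> "AcquisitionBundle":
        d = Path(directory)
        mask = d / "mask.nii.gz"
        return cls(
            dwi_path=d / "dwi.nii.gz",
            bvals_path=d / "bvals",
            bvecs_path=d / "bvecs",
            mask_path=mask if mask.exists() else None,
        )


def read_bvals_bvecs(bvals_path, bvecs_path) -> GradientScheme:
    """Read an FSL-format gradient table, renormalizing slightly off vectors."""
    bvals = np.atleast_1d(np.loadtxt(bvals_path)).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.ndim == 1 and bvecs.size == 3:  # single volume
        bvecs = bvecs[:, None]
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ValueError(f"bvecs must have 3 rows (or columns), got shape {bvecs.shape}")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"{bvals.size} b-values but {bvecs.shape[0]} gradient vectors"
        )
    is_b0 = bvals < 50.0
    norms = np.linalg.norm(bvecs, axis=1)
    bad = ~is_b0 & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} diffusion bvecs deviate from unit norm by more than 1e-3"
        )
    fix = ~is_b0 & (norms > 0)
    bvecs[fix] /= norms[fix, None]
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def write_bvals_bvecs(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.bvecs.T, fmt="%.10g")


def save_acquisition(acq: SimulatedAcquisition, directory, voxel_size: float = 2.0) -> AcquisitionBundle:
    """Write a simulated acquisition as an FSL-style bundle + ground truth JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(acq.data.astype(np.float32), affine), d / "dwi.nii.gz")
    write_bvals_bvecs(acq.scheme, d / "bvals", d / "bvecs")
    truth = {
        "snr": acq.snr if np.isfinite(acq.snr) else None,
        "noise_sigma": acq.noise_sigma,
        "seed": acq.seed,
        "motion": None
        if acq.motion is None
        else {
            "theta": int(acq.motion.theta),
            "rotation": acq.motion.rotation.tolist(),
            "translation": acq.motion.translation.tolist(),
        },
    }
    (d / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return AcquisitionBundle.in_dir(d)


def save_mask(mask: np.ndarray, path, voxel_size: float = 2.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path)


def load_acquisition(bundle: AcquisitionBundle):
    """Load a bundle; returns ``(data 4D array, scheme, mask or None)``."""
    img = nib.load(str(bundle.dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    scheme = read_bvals_bvecs(bundle.bvals_path, bundle.bvecs_path)
    if data.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"{data.shape[-1]} volumes in {bundle.dwi_path} but "
            f"{scheme.n_volumes} entries in the gradient table"
        )
    mask = None
    if bundle.mask_path is not None:
        mimg = nib.load(str(bundle.mask_path))
        if not np.allclose(mimg.affine, img.affine, atol=1e-4):
            raise ValueError("mask affine does not match the DWI affine")
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match the DWI volumes")
    return data, scheme, mask


def save_odf_image(odf_coeffs: np.ndarray, model, path, voxel_size: float = 2.0) -> None:
    """Write SH ODF coefficients as 4D NIfTI plus a JSON basis sidecar."""
    path = Path(path)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(odf_coeffs.astype(np.float32), affine), path)
    sidecar = {
        "basis": "real symmetric spherical harmonics, even degrees",
        "ordering": "(l, m) pairs: l = 0, 2, ..., order; m = -l..l within each l",
        "order": int(model.order),
        "n_coeffs": int(model.n_coeffs),
        "lm": model.lm.tolist(),
    }
    sidecar_path = path.with_name(path.name.split(".")[0] + "_basis.json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
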