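"""NIfTI and gradient-table I/O (FSL bvals/bvecs dialect)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .deformation import BinaryMask, DeformationField
from .errors import ConfigurationError
from .tensor import DWISeries, FAMap, TensorField


def load_volume(path):
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(data, affine, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def load_mask(path) -> BinaryMask:
    data, affine = load_volume(path)
    return BinaryMask(data > 0.5, affine)


def save_mask(mask: BinaryMask, path) -> None:
    save_volume(mask.voxels.astype(np.uint8), mask.affine, path)


def load_bvals_bvecs(bvals_path, bvecs_path):
    """FSL dialect: bvals one whitespace-delimited row; bvecs three rows."""
    bvals = np.loadtxt(str(bvals_path)).ravel()
    bvecs = np.loadtxt(str(bvecs_path))
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ConfigurationError("bvecs must be a 3xN (or Nx3) table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T      # ambiguous; FSL convention is 3 rows
    if bvecs.shape[0] != bvals.size:
        raise ConfigurationError(
            f"{bvals.size} bvals but {bvecs.shape[0]} gradient directions")
    return bvals, bvecs


def save_bvals_bvecs(bvals, bvecs, bvals_path, bvecs_path) -> None:
    np.savetxt(str(bvals_path), np.asarray(bvals)[None, :], fmt="%.6g")
    np.savetxt(str(bvecs_path), np.asarray(bvecs).T, fmt="%.8f")


def load_dwi(nifti_path, bvals_path, bvecs_path) -> DWISeries:
    data, affine = load_volume(nifti_path)
    bvals, bvecs = load_bvals_bvecs(bvals_path, bvecs_path)
    return DWISeries(signal=data, bvals=bvals, bvecs=bvecs, affine=affine)


def save_dwi(dwi: DWISeries, nifti_path, bvals_path, bvecs_path) -> None:
    save_volume(dwi.signal.astype(np.float32), dwi.affine, nifti_path)
    save_bvals_bvecs(dwi.bvals, dwi.bvecs, bvals_path, bvecs_path)


def save_fa(fa: FAMap, path) -> None:
    save_volume(fa.fa.astype(np.float32), fa.affine, path)


def save_tensor(tf: TensorField, path) -> None:
    """Tensor components as a 4D volume (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    save_volume(tf.components.astype(np.float32), tf.affine, path)


def save_deformation(df: DeformationField, path, sidecar_path=None) -> None:
    """4D NIfTI with 3 components; component order recorded in a sidecar."""
    save_volume(df.vectors.astype(np.float32), df.affine, path)
    sidecar = Path(sidecar_path) if sidecar_path else Path(str(path)).with_suffix(".json")
    sidecar.write_text(json.dumps({
        "components": ["x_mm", "y_mm", "z_mm"],
        "frame": "world",
        "shrinkage_voxels": df.shrinkage_voxels,
        "converged": df.converged,
    }, indent=2))


def load_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
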