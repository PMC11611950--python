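"""Deformation-field estimation between two binary lesion masks.

The field describes, per voxel of the region of increase, how the lesion
surface moved between timepoint 1 and timepoint 2.  Two estimators are
provided:

``nearest_boundary`` (default)
    For every voxel in the expansion region (mask2 minus mask1), the vector
    from the nearest timepoint-1 surface voxel (Euclidean distance in mm) to
    that voxel.  Deterministic and fully specified; its magnitudes equal the
    distance transform of the timepoint-1 surface by construction.

``demons``
    A classical demons iteration driven by the signed-distance mismatch of
    the two masks, with Gaussian regularisation of the update field.

Shrinkage (mask1 minus mask2) is never part of the support; its volume is
reported on the returned field so that callers can audit what the analysis
ignores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError, DomainError, GridMismatchError
from .tensor import voxel_sizes

__all__ = [
    "BinaryMask",
    "DeformationField",
    "DeformationParams",
    "expansion_region",
    "mask_surface",
    "estimate_deformation",
    "decompose_components",
]

_CROSS6 = ndi.generate_binary_structure(3, 1)


@dataclass
class BinaryMask:
    """A 3D boolean volume with its voxel->world affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ConfigurationError("mask must be 3D")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm, world frame) on a support region."""

    vectors: np.ndarray          # (X, Y, Z, 3)
    support: np.ndarray          # bool
    affine: np.ndarray
    shrinkage_voxels: int = 0    # |mask1 \ mask2|, excluded from the analysis
    converged: bool = True

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.vectors.shape != self.support.shape + (3,):
            raise GridMismatchError("vectors and support grids do not match")

    @property
    def shape(self) -> tuple:
        return self.support.shape

    def magnitudes(self) -> np.ndarray:
        """Vector length in mm everywhere (zero off support)."""
        return np.linalg.norm(self.vectors, axis=-1)


@dataclass
class DeformationParams:
    method: str = "nearest_boundary"          # nearest_boundary | demons
    smoothing_sigma_mm: float = 2.0
    step_size: float = 0.5
    max_iterations: int = 200
    tolerance_mm: float = 0.01
    min_magnitude_mm: float = 0.1
    support_region: str = "expansion"         # expansion | boundary | union

    def __post_init__(self):
        if self.method not in ("nearest_boundary", "demons"):
            raise ConfigurationError(f"unknown deformation method {self.method!r}")
        if self.support_region not in ("expansion", "boundary", "union"):
            raise ConfigurationError(f"unknown support_region {self.support_region!r}")
        if self.smoothing_sigma_mm < 0 or self.min_magnitude_mm < 0:
            raise ConfigurationError("sigma and min_magnitude must be nonnegative")
        if not (0 < self.step_size <= 1):
            raise ConfigurationError("step_size must lie in (0, 1]")
        if self.max_iterations < 1 or self.tolerance_mm <= 0:
            raise ConfigurationError("max_iterations >= 1 and tolerance_mm > 0 required")


def _check_same_grid(mask1: BinaryMask, mask2: BinaryMask) -> None:
    if mask1.shape != mask2.shape:
        raise GridMismatchError(
            f"mask grids differ: {mask1.shape} vs {mask2.shape}")
    if not np.allclose(mask1.affine, mask2.affine):
        raise GridMismatchError("mask affines differ")


def expansion_region(mask1: BinaryMask, mask2: BinaryMask) -> BinaryMask:
    """Voxels present at timepoint 2 but not at timepoint 1 (may be empty)."""
    _check_same_grid(mask1, mask2)
    return BinaryMask(mask2.voxels & ~mask1.voxels, mask1.affine)


def mask_surface(voxels: np.ndarray) -> np.ndarray:
    """6-connectivity surface voxels of a binary volume."""
    voxels = np.asarray(voxels, dtype=bool)
    return voxels & ~ndi.binary_erosion(voxels, structure=_CROSS6, border_value=0)


def nearest_surface_vectors(mask1: BinaryMask):
    """Displacement from the nearest mask1-surface voxel to every voxel.

    Returns ``(vectors, distances)`` where vectors are world-mm displacements
    (shape ``(X, Y, Z, 3)``) and distances the corresponding Euclidean
    distances (the EDT of the surface, sampled with the voxel sizes).
    """
    surf = mask_surface(mask1.voxels)
    if not surf.any():
        raise DomainError("mask has no surface voxels (empty mask)")
    spacing = voxel_sizes(mask1.affine)
    dist, idx = ndi.distance_transform_edt(~surf, sampling=spacing, return_indices=True)
    delta = np.indices(mask1.shape) - idx           # voxel-index offsets
    linear = mask1.affine[:3, :3]
    vectors = np.einsum("ab,b...->...a", linear, delta.astype(float))
    return vectors, dist


def _support_from_region(mask1: BinaryMask, mask2: BinaryMask, region: str) -> np.ndarray:
    grown = mask2.voxels & ~mask1.voxels
    if region == "expansion":
        return grown
    if region == "boundary":
        return mask_surface(mask2.voxels) & grown
    # union: all candidate voxels of either mask; inward/zero-magnitude
    # displacements are removed afterwards, which reduces it to the expansion
    # region for the nearest-boundary method
    return mask1.voxels | mask2.voxels


def _signed_distance(voxels: np.ndarray, spacing) -> np.ndarray:
    """Negative inside the mask, positive outside, in mm."""
    inside = ndi.distance_transform_edt(voxels, sampling=spacing)
    outside = ndi.distance_transform_edt(~voxels, sampling=spacing)
    return outside - inside


def _estimate_nearest_boundary(mask1, mask2, params):
    vectors, _ = nearest_surface_vectors(mask1)
    support = _support_from_region(mask1, mask2, params.support_region)
    # exclude voxels of mask1 itself: their displacement points inward/zero
    support = support & ~mask1.voxels
    out = np.zeros(mask1.shape + (3,), dtype=float)
    out[support] = vectors[support]
    return out, support


def _estimate_demons(mask1, mask2, params):
    spacing = voxel_sizes(mask1.affine)
    fixed = _signed_distance(mask2.voxels, spacing)
    moving = _signed_distance(mask1.voxels, spacing)
    grad = np.stack(np.gradient(fixed, *spacing), axis=-1)

    shape = mask1.shape
    # backward (pull) field in voxel units: x in TP2 frame maps to x + u(x) in TP1
    u = np.zeros(shape + (3,), dtype=float)
    coords = np.indices(shape).astype(float)
    sigma_vox = params.smoothing_sigma_mm / spacing
    converged = False
    for _ in range(params.max_iterations):
        sample = [coords[i] + u[..., i] / spacing[i] for i in range(3)]
        warped = ndi.map_coordinates(moving, sample, order=1, mode="nearest")
        diff = warped - fixed
        g2 = (grad ** 2).sum(axis=-1)
        denom = g2 + diff ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            force = -(diff[..., None] * grad) / denom[..., None]
        force[denom < 1e-12] = 0.0
        update = params.step_size * force
        for i in range(3):
            u[..., i] = ndi.gaussian_filter(u[..., i] + update[..., i], sigma_vox[i])
        if np.abs(update).max() < params.tolerance_mm:
            converged = True
            break
    if not converged:
        warnings.warn("demons iteration did not reach tolerance; returning field",
                      RuntimeWarning, stacklevel=3)

    # growth displacement at x is the forward motion of the surface: -u
    growth = -u
    support = _support_from_region(mask1, mask2, params.support_region)
    mag = np.linalg.norm(growth, axis=-1)
    # outward = along the gradient of mask1's signed distance (away from lesion)
    grad1 = np.stack(np.gradient(moving, *spacing), axis=-1)
    outward = (growth * grad1).sum(axis=-1) > 0
    support = support & (mag > params.min_magnitude_mm) & outward & ~mask1.voxels
    out = np.zeros_like(growth)
    out[support] = growth[support]
    return out, support, converged


def estimate_deformation(mask1: BinaryMask, mask2: BinaryMask,
                         params: DeformationParams | None = None) -> DeformationField:
    """Estimate the lesion growth field between two timepoint masks.

    Raises
    ------
    DomainError
        If either mask is empty.
    GridMismatchError
        If the masks do not share a grid.
    """
    params = params or DeformationParams()
    _check_same_grid(mask1, mask2)
    if not mask1.voxels.any() or not mask2.voxels.any():
        raise DomainError("lesion masks must be nonempty")

    shrinkage = int((mask1.voxels & ~mask2.voxels).sum())
    if params.method == "nearest_boundary":
        vectors, support = _estimate_nearest_boundary(mask1, mask2, params)
        converged = True
    else:
        vectors, support, converged = _estimate_demons(mask1, mask2, params)
    return DeformationField(vectors=vectors, support=support, affine=mask1.affine,
                            shrinkage_voxels=shrinkage, converged=converged)


def decompose_components(df: DeformationField):
    """Split the field into its x, y, z world-frame component volumes (lossless)."""
    v = df.vectors
    return v[..., 0].copy(), v[..., 1].copy(), v[..., 2].copy()
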