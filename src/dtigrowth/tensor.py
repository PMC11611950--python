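"""Diffusion tensor estimation and scalar maps.

The single-tensor model relates the diffusion-weighted signal ``S_k`` acquired
with b-value ``b_k`` and unit gradient direction ``g_k`` to the 3x3 symmetric
diffusion tensor ``D`` (mm^2/s)::

    S_k = S_0 * exp(-b_k * g_k^T D g_k)

With one b=0 volume and six non-coplanar directions at a single shell the
log-linearised system is exactly determined; more volumes are handled by
ordinary least squares, the standard clinical fitting approach.

Tensor components are stored in the order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in
the frame of the gradient table (taken to be the voxel frame, matching the
FSL bvecs dialect).  Eigenvectors are returned in the *world* (mm) frame by
applying the rotational part of the NIfTI affine, so that angles computed
downstream live in physical space even for strongly anisotropic voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import polar

from .errors import ConfigurationError, DomainError, GridMismatchError

__all__ = [
    "DWISeries",
    "TensorField",
    "EigenSystem",
    "FAMap",
    "fit_tensor",
    "eigendecompose",
    "compute_fa",
    "fa_from_eigenvalues",
    "diagonal_elements",
    "mean_fa_in_roi",
]

#: component order used throughout the package
TENSOR_COMPONENT_ORDER = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


def affine_rotation(affine: np.ndarray) -> np.ndarray:
    """Orthogonal (rotation/reflection) part of a 4x4 voxel->world affine.

    Obtained by polar decomposition of the 3x3 linear block, which discards
    voxel scaling and (approximately) shear.
    """
    u, _ = polar(np.asarray(affine, dtype=float)[:3, :3])
    return u


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths in mm (column norms of the linear block)."""
    return np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)


@dataclass
class DWISeries:
    """A diffusion-weighted acquisition: 4D signal plus gradient table.

    Parameters
    ----------
    signal
        Nonnegative intensities, shape ``(X, Y, Z, V)``.
    bvals
        One b-value (s/mm^2) per volume, shape ``(V,)``.
    bvecs
        One gradient direction per volume, shape ``(V, 3)``; unit norm for
        b>0 volumes, the zero vector is allowed for b=0 volumes.
    affine
        4x4 voxel-index -> world-mm transform.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.signal.ndim != 4:
            raise ConfigurationError("signal must be 4D (x, y, z, volume)")
        nvol = self.signal.shape[3]
        if self.bvals.shape != (nvol,) or self.bvecs.shape != (nvol, 3):
            raise ConfigurationError(
                f"gradient table shape mismatch: {nvol} volumes, "
                f"{self.bvals.shape[0]} bvals, {self.bvecs.shape[0]} bvecs"
            )
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ConfigurationError("signal must be finite and nonnegative")
        b0 = self.bvals <= 0
        if not np.any(b0):
            raise ConfigurationError("at least one b=0 volume is required")
        dw = ~b0
        if dw.sum() < 6:
            raise ConfigurationError("at least 6 diffusion-weighted volumes are required")
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ConfigurationError("b>0 gradient directions must have unit norm (1e-6)")

    @property
    def shape(self) -> tuple:
        return self.signal.shape[:3]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor, 6 components per voxel.

    ``components[..., :]`` is (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm^2/s in the
    gradient/voxel frame; ``valid_mask`` marks voxels where the fit succeeded.
    """

    components: np.ndarray
    affine: np.ndarray
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ConfigurationError("components must have shape (X, Y, Z, 6)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.components.shape[:3], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.components.shape[:3]:
            raise GridMismatchError("valid_mask grid does not match components")
        if not np.all(np.isfinite(self.components[self.valid_mask])):
            raise ConfigurationError("tensor components must be finite where valid")

    @property
    def shape(self) -> tuple:
        return self.components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Reassemble full symmetric 3x3 matrices, shape ``(X, Y, Z, 3, 3)``."""
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    @classmethod
    def from_matrices(cls, matrices: np.ndarray, affine: np.ndarray,
                      valid_mask: np.ndarray = None) -> "TensorField":
        m = np.asarray(matrices, dtype=float)
        c = np.stack([m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
                      m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]], axis=-1)
        return cls(c, affine, valid_mask)


@dataclass
class EigenSystem:
    """Sorted eigendecomposition of a tensor field.

    ``eigenvalues[..., i]`` are sorted descending (lambda1 >= lambda2 >=
    lambda3, mm^2/s); ``eigenvectors[..., i, :]`` is the unit eigenvector of
    ``eigenvalues[..., i]`` expressed in the world (mm) frame.  Eigenvector
    sign is arbitrary; downstream consumers must be sign-invariant.  Negative
    eigenvalues from noisy fits are retained and flagged in
    ``negative_mask``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    affine: np.ndarray
    valid_mask: np.ndarray = None
    negative_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.eigenvalues.shape[:-1], dtype=bool)
        if self.negative_mask is None:
            self.negative_mask = np.any(self.eigenvalues < 0, axis=-1) & self.valid_mask

    @property
    def shape(self) -> tuple:
        return self.eigenvalues.shape[:-1]

    @property
    def principal_direction(self) -> np.ndarray:
        """Unit e1 field (world frame), shape ``(X, Y, Z, 3)``."""
        return self.eigenvectors[..., 0, :]


@dataclass
class FAMap:
    """Fractional anisotropy per voxel, in [0, 1]; 0 where the fit is invalid."""

    fa: np.ndarray
    affine: np.ndarray
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.fa = np.asarray(self.fa, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.fa.shape, dtype=bool)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to ln S_k."""
    b = bvals[:, None]
    g = bvecs
    return np.column_stack([
        np.ones(len(bvals)),
        -b[:, 0] * g[:, 0] ** 2,
        -b[:, 0] * g[:, 1] ** 2,
        -b[:, 0] * g[:, 2] ** 2,
        -2 * b[:, 0] * g[:, 0] * g[:, 1],
        -2 * b[:, 0] * g[:, 0] * g[:, 2],
        -2 * b[:, 0] * g[:, 1] * g[:, 2],
    ])


def fit_tensor(dwi: DWISeries, brain_mask: np.ndarray = None) -> TensorField:
    """Ordinary least-squares fit of the log-linearised tensor model.

    Multiple b=0 volumes are averaged into a single reference volume before
    fitting.  Voxels inside the mask with any nonpositive signal cannot enter
    the log domain and are marked invalid rather than clipped.

    Parameters
    ----------
    dwi
        Validated acquisition.
    brain_mask
        Boolean volume on the same grid; ``None`` fits everywhere.

    Returns
    -------
    TensorField
        With ``valid_mask`` marking voxels where the fit succeeded.
    """
    shape = dwi.shape
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != shape:
        raise GridMismatchError(
            f"brain_mask grid {brain_mask.shape} does not match DWI grid {shape}")

    b0 = dwi.bvals <= 0
    if b0.sum() > 1:
        s0 = dwi.signal[..., b0].mean(axis=-1, keepdims=True)
        signal = np.concatenate([s0, dwi.signal[..., ~b0]], axis=-1)
        bvals = np.concatenate([[0.0], dwi.bvals[~b0]])
        bvecs = np.concatenate([np.zeros((1, 3)), dwi.bvecs[~b0]], axis=0)
    else:
        signal, bvals, bvecs = dwi.signal, dwi.bvals, dwi.bvecs

    if len(bvals) < 7:
        raise ConfigurationError("tensor fit needs at least 7 volumes (1 b0 + 6 DW)")
    design = _design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(design) < 7:
        raise ConfigurationError(
            "rank-deficient design matrix: gradient directions are collinear/coplanar")
    pinv = np.linalg.pinv(design)

    flat = signal.reshape(-1, signal.shape[-1])
    inmask = brain_mask.ravel()
    positive = np.all(flat > 0, axis=1)
    valid = inmask & positive

    comps = np.zeros((flat.shape[0], 6), dtype=float)
    if np.any(valid):
        logs = np.log(flat[valid])
        coef = logs @ pinv.T          # (n_valid, 7)
        comps[valid] = coef[:, 1:]
    return TensorField(
        components=comps.reshape(shape + (6,)),
        affine=dwi.affine,
        valid_mask=valid.reshape(shape),
    )


def eigendecompose(tf: TensorField) -> EigenSystem:
    """Symmetric eigendecomposition per voxel, eigenvalues sorted descending.

    Eigenvectors are rotated into the world frame using the rotational part of
    the affine.  Negative eigenvalues are kept (and flagged) so that fit
    diagnostics survive; FA computation clamps them separately.
    """
    mats = tf.as_matrices()
    w, v = np.linalg.eigh(mats)                # ascending; v[..., :, i] is evec i
    w = w[..., ::-1]
    v = v[..., ::-1]
    rot = affine_rotation(tf.affine)
    # world_evec_i = R @ voxel_evec_i; store as eigenvectors[..., i, :]
    evecs = np.einsum("ab,...bi->...ia", rot, v)
    return EigenSystem(
        eigenvalues=w,
        eigenvectors=evecs,
        affine=tf.affine,
        valid_mask=tf.valid_mask.copy(),
    )


def fa_from_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, negatives clamped.

    Accepts any array with eigenvalue triples on the last axis.  All-zero
    triples map to FA = 0.
    """
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    # pairwise-difference form of the same formula; exact at both extremes
    num = 0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2)
    den = (lam ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa(es: EigenSystem) -> FAMap:
    """Fractional anisotropy map from an eigensystem (invalid voxels -> 0)."""
    fa = fa_from_eigenvalues(es.eigenvalues)
    fa = np.where(es.valid_mask, fa, 0.0)
    return FAMap(fa=fa, affine=es.affine, valid_mask=es.valid_mask.copy())


def diagonal_elements(tf: TensorField):
    """The (Dxx, Dyy, Dzz) scalar volumes, exact copies of the components."""
    c = tf.components
    return c[..., 0].copy(), c[..., 1].copy(), c[..., 2].copy()


def mean_fa_in_roi(fa: FAMap, roi: np.ndarray) -> float:
    """Arithmetic mean FA over the valid voxels of a region of interest."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != fa.fa.shape:
        raise GridMismatchError(
            f"ROI grid {roi.shape} does not match FA grid {fa.fa.shape}")
    if not roi.any():
        raise DomainError("ROI is empty")
    use = roi & fa.valid_mask
    if not use.any():
        raise DomainError("ROI contains no valid voxels")
    return float(fa.fa[use].mean())
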