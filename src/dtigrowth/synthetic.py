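"""Synthetic phantoms: fiber fields, DWI signals and growing lesion masks.

Every pipeline stage gets a ground truth it can be checked against:

* ``make_fiber_field`` builds a coherent white-matter orientation model
  (uniform, curved, or two-region) and the matching anisotropic tensors.
* ``simulate_dwi`` produces the forward DWI signal for a clinical single-shell
  scheme (one b=0 volume plus six fixed directions at b=1000 s/mm^2), with
  optional Rician noise.
* ``grow_lesion`` produces a pair of longitudinal lesion masks whose region of
  increase has a tunable directional bias relative to the fiber field.

Lesion growth is a *noisy front* model: starting from a spherical seed
(timepoint 1), the timepoint-2 mask contains every voxel whose distance to the
seed surface is below a direction- and space-dependent threshold::

    mask2 = mask1  union  { x : dist_mm(x) <= T * m(psi(x)) * exp(a * eps(x)) }

where ``psi(x)`` is the angle between the voxel's outward direction (from the
nearest seed-surface voxel, the same correspondence the analysis pipeline
measures) and the local fiber axis, ``m(psi) = exp(-kappa * tan^2(psi))`` is a
transverse-Gaussian extent kernel (kappa = 0 is exactly isotropic; large kappa
confines growth to a narrow cone around the fiber axis, the perineural-spread
caricature), ``eps`` is a smooth Gaussian random field giving the front a
realistic irregularity, and the global threshold ``T`` is solved so the lesion
reaches the requested volume ratio.  The model is deterministic given its
seed, monotone (mask1 is always contained in mask2), and lattice-isotropic at
kappa = 0 up to voxelisation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .deformation import BinaryMask, nearest_surface_vectors
from .errors import ConfigurationError, DomainError
from .tensor import DWISeries, TensorField, fa_from_eigenvalues

__all__ = [
    "FiberPhantomSpec",
    "GrowthSpec",
    "SIX_DIRECTION_SCHEME",
    "make_fiber_field",
    "simulate_dwi",
    "grow_lesion",
    "make_cohort",
    "gradient_scheme",
]

#: classic non-coplanar dual-gradient scheme used by 6-direction clinical DTI
SIX_DIRECTION_SCHEME = np.array([
    [1, 1, 0], [1, -1, 0],
    [1, 0, 1], [1, 0, -1],
    [0, 1, 1], [0, 1, -1],
], dtype=float) / np.sqrt(2.0)


@dataclass
class FiberPhantomSpec:
    """Geometry and microstructure of a fiber phantom.

    ``orientation_model``:

    * ``uniform`` - constant fiber axis ``axis`` everywhere.
    * ``curved`` - circular fibers around the line through ``line_point_mm``
      with direction ``line_axis`` (divergence-free circulation).
    * ``two_region`` - axis ``axis`` on the negative side of the plane
      ``n . x = offset``, ``axis_b`` on the positive side.

    ``lambdas`` are the white-matter tensor eigenvalues (mm^2/s, descending);
    voxels where the orientation is undefined (on the curved model's axis
    line) receive an isotropic tensor with eigenvalue ``background_lambda``.
    """

    grid_shape: tuple = (48, 48, 48)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    orientation_model: str = "uniform"
    axis: tuple = (1.0, 0.0, 0.0)
    axis_b: tuple = (0.0, 1.0, 0.0)
    line_point_mm: tuple | None = None
    line_axis: tuple = (0.0, 0.0, 1.0)
    plane_normal: tuple = (1.0, 0.0, 0.0)
    plane_offset_mm: float | None = None
    lambdas: tuple = (1.7e-3, 0.2e-3, 0.2e-3)
    background_lambda: float = 0.7e-3

    def __post_init__(self):
        l1, l2, l3 = self.lambdas
        if not (l1 >= l2 >= l3 > 0):
            raise ConfigurationError("lambdas must satisfy l1 >= l2 >= l3 > 0")
        if self.orientation_model not in ("uniform", "curved", "two_region"):
            raise ConfigurationError(
                f"unknown orientation model {self.orientation_model!r}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def center_mm(self) -> np.ndarray:
        return (np.array(self.grid_shape) - 1) / 2 * np.array(self.voxel_size_mm)


@dataclass
class GrowthSpec:
    """Parameters of the longitudinal lesion-growth model.

    ``bias_kappa`` is the transverse precision of the growth kernel
    ``exp(-kappa tan^2 psi)``: 0 grows isotropically, values around 8 confine
    essentially all growth to within ~20 degrees of the fiber axis.
    ``noise_amp``/``noise_length_mm`` control the lognormal front
    irregularity (amplitude in log units, correlation length in mm).
    """

    seed_center_mm: tuple | None = None        # None = grid centre
    seed_radius_mm: float = 12.0
    target_volume_ratio: float = 2.0
    bias_kappa: float = 0.0
    rng_seed: int = 0
    noise_amp: float = 0.15
    noise_length_mm: float = 4.0

    def __post_init__(self):
        if self.seed_radius_mm <= 0:
            raise ConfigurationError("seed_radius_mm must be positive")
        if self.target_volume_ratio < 1.0:
            raise ConfigurationError("target_volume_ratio must be >= 1")
        if self.bias_kappa < 0:
            raise ConfigurationError("bias_kappa must be nonnegative")
        if self.noise_amp < 0 or self.noise_length_mm <= 0:
            raise ConfigurationError("noise parameters out of range")


def _world_coordinates(shape, affine):
    idx = np.indices(shape).astype(float)
    lin, trans = affine[:3, :3], affine[:3, 3]
    coords = np.einsum("ab,b...->...a", lin, idx)
    return coords + trans


def _normalize(v, axis=-1):
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = v / n
    return np.where(n > 1e-12, out, 0.0), np.squeeze(n, axis) > 1e-12


def make_fiber_field(spec: FiberPhantomSpec):
    """Build the unit fiber-direction field and the matching tensor field.

    Returns ``(directions, tensor_field)``; ``directions`` has shape
    ``(X, Y, Z, 3)`` with zero vectors where the orientation is undefined.
    """
    shape = tuple(spec.grid_shape)
    coords = _world_coordinates(shape, spec.affine)

    if spec.orientation_model == "uniform":
        axis = np.asarray(spec.axis, float)
        axis = axis / np.linalg.norm(axis)
        dirs = np.broadcast_to(axis, shape + (3,)).copy()
        defined = np.ones(shape, dtype=bool)
    elif spec.orientation_model == "curved":
        p = np.asarray(spec.line_point_mm if spec.line_point_mm is not None
                       else spec.center_mm(), float)
        a = np.asarray(spec.line_axis, float)
        a = a / np.linalg.norm(a)
        rel = coords - p
        radial = rel - (rel @ a)[..., None] * a
        dirs, defined = _normalize(np.cross(a, radial))
    else:  # two_region
        n = np.asarray(spec.plane_normal, float)
        n = n / np.linalg.norm(n)
        offset = (spec.plane_offset_mm if spec.plane_offset_mm is not None
                  else float(spec.center_mm() @ n))
        side = (coords @ n) >= offset
        axis_a = np.asarray(spec.axis, float) / np.linalg.norm(spec.axis)
        axis_b = np.asarray(spec.axis_b, float) / np.linalg.norm(spec.axis_b)
        dirs = np.where(side[..., None], axis_b, axis_a)
        defined = np.ones(shape, dtype=bool)

    l1, l2, l3 = spec.lambdas
    # D = l3*I + (l2-l3)*(I - e1 e1^T - ...) is only needed in full generality
    # when l2 != l3; build from an orthonormal frame completed around e1
    e1 = dirs
    helper = np.where(np.abs(e1[..., 2:3]) < 0.9,
                      np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]))
    e2, _ = _normalize(np.cross(e1, helper))
    e3 = np.cross(e1, e2)
    mats = (l1 * e1[..., :, None] * e1[..., None, :]
            + l2 * e2[..., :, None] * e2[..., None, :]
            + l3 * e3[..., :, None] * e3[..., None, :])
    iso = spec.background_lambda * np.eye(3)
    mats[~defined] = iso
    tf = TensorField.from_matrices(mats, spec.affine)
    return dirs, tf


def gradient_scheme(n_directions: int = 6) -> np.ndarray:
    """Fixed diffusion-gradient directions: the 6-direction dual-gradient
    scheme, extended deterministically with spherical-Fibonacci points when
    more directions are requested."""
    if n_directions < 6:
        raise ConfigurationError("at least 6 directions required")
    dirs = [SIX_DIRECTION_SCHEME]
    extra = n_directions - 6
    if extra:
        k = np.arange(extra)
        golden = (1 + 5 ** 0.5) / 2
        z = (k + 0.5) / extra          # upper hemisphere
        phi = 2 * np.pi * k / golden
        r = np.sqrt(1 - z ** 2)
        dirs.append(np.column_stack([r * np.cos(phi), r * np.sin(phi), z]))
    return np.concatenate(dirs, axis=0)


def simulate_dwi(tf: TensorField, s0: float = 1000.0, bval: float = 1000.0,
                 n_directions: int = 6, noise_sigma: float = 0.0,
                 noise_model: str = "rician", rng_seed: int = 0) -> DWISeries:
    """Forward-simulate the DWI signal S_k = s0 exp(-b g_k^T D g_k).

    One b=0 volume precedes the diffusion-weighted volumes.  With
    ``noise_sigma > 0``, Rician noise (magnitude of two independent Gaussian
    channels) is added, matching magnitude MR images; ``noise_model =
    "gaussian"`` adds plain Gaussian noise for analytic checks.
    """
    if s0 <= 0:
        raise DomainError("s0 must be positive")
    if noise_model not in ("rician", "gaussian"):
        raise ConfigurationError(f"unknown noise model {noise_model!r}")
    g = gradient_scheme(n_directions)
    mats = tf.as_matrices()
    # quadratic form per direction: g^T D g
    q = np.einsum("kd,...de,ke->...k", g, mats, g)
    dw = s0 * np.exp(-bval * q)
    signal = np.concatenate([np.full(tf.shape + (1,), s0), dw], axis=-1)
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        if noise_model == "rician":
            n1 = rng.normal(0, noise_sigma, signal.shape)
            n2 = rng.normal(0, noise_sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
        else:
            signal = np.clip(signal + rng.normal(0, noise_sigma, signal.shape), 0, None)
    bvals = np.concatenate([[0.0], np.full(len(g), bval)])
    bvecs = np.concatenate([np.zeros((1, 3)), g], axis=0)
    return DWISeries(signal=signal, bvals=bvals, bvecs=bvecs, affine=tf.affine)


def grow_lesion(fiber_dirs: np.ndarray, spec: GrowthSpec,
                affine: np.ndarray) -> tuple[BinaryMask, BinaryMask]:
    """Grow a lesion with directional bias along the fiber field.

    Returns the timepoint-1 seed mask and the grown timepoint-2 mask
    (``mask1`` is always a subset of ``mask2``).  Raises :class:`DomainError`
    if the seed sphere does not fit inside the grid or the target volume
    ratio cannot be reached.
    """
    affine = np.asarray(affine, dtype=float)
    shape = fiber_dirs.shape[:3]
    coords = _world_coordinates(shape, affine)
    center = (np.asarray(spec.seed_center_mm, float)
              if spec.seed_center_mm is not None
              else (_world_coordinates(shape, affine)
                    [tuple((np.array(shape) - 1) // 2)]))
    r2 = ((coords - center) ** 2).sum(axis=-1)
    seed = r2 <= spec.seed_radius_mm ** 2
    if not seed.any():
        raise DomainError("seed sphere contains no voxels")
    edge = (seed[0].any() or seed[-1].any() or seed[:, 0].any()
            or seed[:, -1].any() or seed[:, :, 0].any() or seed[:, :, -1].any())
    if edge:
        raise DomainError("seed sphere touches the grid border")
    mask1 = BinaryMask(seed, affine)

    target = int(np.ceil(spec.target_volume_ratio * seed.sum()))
    need = target - int(seed.sum())
    if need <= 0:
        return mask1, BinaryMask(seed.copy(), affine)

    vectors, dist = nearest_surface_vectors(mask1)
    mag = np.linalg.norm(vectors, axis=-1)
    fdot = np.abs((vectors * fiber_dirs).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(mag > 0, fdot / mag, 0.0)
    cos = np.clip(cos, 0.0, 1.0)
    if spec.bias_kappa > 0:
        sin2 = 1.0 - cos ** 2
        log_m = -spec.bias_kappa * sin2 / np.maximum(cos ** 2, 1e-30)
        extent = np.exp(np.maximum(log_m, -700.0))
    else:
        extent = np.ones(shape)

    rng = np.random.default_rng(spec.rng_seed)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    sigma_vox = spec.noise_length_mm / spacing
    eps = ndi.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    eps /= eps.std()
    extent = extent * np.exp(spec.noise_amp * eps)

    outside = ~seed
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(extent > 0, dist / np.maximum(extent, 1e-300), np.inf)
    q_out = q[outside]
    reachable = np.isfinite(q_out).sum()
    if reachable < need:
        raise DomainError(
            f"target volume ratio unreachable: need {need} voxels, "
            f"only {reachable} available")
    threshold = np.partition(q_out, need - 1)[need - 1]
    grown = outside & (q <= threshold)
    mask2 = BinaryMask(seed | grown, affine)
    return mask1, mask2


def _spec_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
            for k, v in d.items()}


def make_cohort(n_tp: int, n_tra: int, tp_spec: GrowthSpec, tra_spec: GrowthSpec,
                phantom: FiberPhantomSpec, rng_seed: int, out_dir,
                noise_sigma: float = 0.0, radius_jitter: float = 0.10,
                ratio_jitter: float = 0.10, write_dwi: bool = True) -> pd.DataFrame:
    """Write a reproducible synthetic cohort to disk.

    Per subject: a DWI series (NIfTI + FSL-dialect bvals/bvecs) simulated from
    the shared fiber phantom, and the two timepoint lesion masks.  Seed radius
    and target volume ratio are lognormally jittered between subjects
    (fractional SDs ``radius_jitter``/``ratio_jitter``) to emulate lesion-size
    heterogeneity.  All randomness derives from ``rng_seed``; rerunning with
    the same seed reproduces every output byte-for-byte.

    Returns the cohort manifest (also written as ``cohort.csv`` plus a
    ``manifest.json`` with the full generating parameters).
    """
    from . import io as dio   # deferred: keeps numpy-only use import-light

    if n_tp < 1 or n_tra < 1:
        raise ConfigurationError("need at least one subject per group")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dirs, tf = make_fiber_field(phantom)
    root = np.random.SeedSequence(rng_seed)
    rows = []
    labels = ["TP"] * n_tp + ["TRA"] * n_tra
    templates = [tp_spec] * n_tp + [tra_spec] * n_tra
    for i, (group, template) in enumerate(zip(labels, templates)):
        sid = f"sub-{i:03d}"
        child = root.spawn(1)[0]
        seeds = child.generate_state(3)
        jrng = np.random.default_rng(seeds[0])
        spec = dataclasses.replace(
            template,
            seed_radius_mm=float(template.seed_radius_mm
                                 * np.exp(jrng.normal(0, radius_jitter))),
            target_volume_ratio=float(max(1.0, template.target_volume_ratio
                                          * np.exp(jrng.normal(0, ratio_jitter)))),
            rng_seed=int(seeds[1]),
        )
        mask1, mask2 = grow_lesion(dirs, spec, phantom.affine)
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        if write_dwi:
            dwi = simulate_dwi(tf, noise_sigma=noise_sigma, rng_seed=int(seeds[2]))
            dio.save_dwi(dwi, sdir / "dwi.nii", sdir / "bvals", sdir / "bvecs")
        dio.save_mask(mask1, sdir / "mask_tp1.nii")
        dio.save_mask(mask2, sdir / "mask_tp2.nii")
        rows.append({
            "subject_id": sid, "group": group,
            "seed_radius_mm": spec.seed_radius_mm,
            "target_volume_ratio": spec.target_volume_ratio,
            "bias_kappa": spec.bias_kappa,
            "rng_seed": spec.rng_seed,
            "n_voxels_tp1": mask1.count(), "n_voxels_tp2": mask2.count(),
        })

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "cohort.csv", index=False)
    meta = {
        "rng_seed": rng_seed,
        "n_tp": n_tp, "n_tra": n_tra,
        "noise_sigma": noise_sigma,
        "radius_jitter": radius_jitter, "ratio_jitter": ratio_jitter,
        "phantom": _spec_dict(phantom),
        "tp_spec": _spec_dict(tp_spec),
        "tra_spec": _spec_dict(tra_spec),
    }
    meta["config_sha256"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return manifest
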