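import numpy as np
import pytest

from dtigrowth import (EigenSystem, DeformationField, FiberPhantomSpec,
                       eigendecompose, make_fiber_field)


@pytest.fixture(scope="session")
def uniform_phantom():
    """Small uniform-fiber phantom along x: (spec, directions, tensors, eigensystem)."""
    spec = FiberPhantomSpec(grid_shape=(24, 24, 24))
    dirs, tf = make_fiber_field(spec)
    es = eigendecompose(tf)
    return spec, dirs, tf, es


def sphere_mask(shape, center_vox, radius_vox):
    idx = np.indices(shape)
    d2 = sum((idx[i] - center_vox[i]) ** 2 for i in range(3))
    return d2 <= radius_vox ** 2


def synthetic_field(vectors, affine=None):
    """Wrap an (N, 3) array of growth vectors as a DeformationField on an Nx1x1 grid."""
    v = np.asarray(vectors, dtype=float).reshape(-1, 1, 1, 3)
    support = np.ones(v.shape[:3], dtype=bool)
    return DeformationField(vectors=v, support=support,
                            affine=np.eye(4) if affine is None else affine)


def synthetic_eigensystem(e1, affine=None):
    """Wrap an (N, 3) array of unit principal directions as an EigenSystem."""
    e1 = np.asarray(e1, dtype=float).reshape(-1, 1, 1, 3)
    n = e1.shape[0]
    evecs = np.zeros((n, 1, 1, 3, 3))
    evecs[..., 0, :] = e1
    evals = np.broadcast_to(np.array([1.7e-3, 0.2e-3, 0.2e-3]), (n, 1, 1, 3)).copy()
    return EigenSystem(eigenvalues=evals, eigenvectors=evecs,
                       affine=np.eye(4) if affine is None else affine)
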