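"""Phantom construction: fiber fields, DWI simulation, lesion growth."""

import numpy as np
import pytest

from dtigrowth import (ConfigurationError, DomainError, FiberPhantomSpec,
                       GrowthSpec, bin_growth, estimate_deformation,
                       eigendecompose, fa_from_eigenvalues, fit_tensor,
                       grow_lesion, gradient_scheme, make_cohort,
                       make_fiber_field, simulate_dwi)


class TestFiberField:
    def test_uniform_axis_and_analytic_fa(self):
        spec = FiberPhantomSpec(grid_shape=(10, 10, 10), axis=(0, 0, 1))
        dirs, tf = make_fiber_field(spec)
        assert np.allclose(np.abs(dirs[..., 2]), 1.0)
        es = eigendecompose(tf)
        expected = fa_from_eigenvalues(np.array(spec.lambdas))
        fa = fa_from_eigenvalues(es.eigenvalues)
        assert np.allclose(fa, expected, atol=1e-9)

    def test_curved_field_unit_norm_and_tangential(self):
        spec = FiberPhantomSpec(grid_shape=(16, 16, 16), orientation_model="curved")
        dirs, _ = make_fiber_field(spec)
        norms = np.linalg.norm(dirs, axis=-1)
        defined = norms > 0.5
        assert np.allclose(norms[defined], 1.0, atol=1e-9)
        # tangential: perpendicular to the radial direction from the line
        from dtigrowth.synthetic import _world_coordinates
        coords = _world_coordinates(spec.grid_shape, spec.affine)
        rel = coords - spec.center_mm()
        radial = rel.copy()
        radial[..., 2] = 0
        dot = (dirs * radial).sum(-1)
        assert np.abs(dot[defined]).max() < 1e-9
        assert np.abs((dirs[..., 2])[defined]).max() < 1e-9

    def test_two_region_split_counts(self):
        spec = FiberPhantomSpec(grid_shape=(12, 12, 12),
                                orientation_model="two_region",
                                axis=(1, 0, 0), axis_b=(0, 1, 0),
                                plane_normal=(1, 0, 0), plane_offset_mm=11.0)
        dirs, _ = make_fiber_field(spec)
        uniq = np.unique(dirs.reshape(-1, 3), axis=0)
        assert len(uniq) == 2
        # plane at x = 11 mm = index 5.5 on a 2 mm grid: 6 of 12 slabs per side
        side_b = np.isclose(dirs[..., 1], 1.0)
        assert side_b.sum() == 6 * 12 * 12

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            FiberPhantomSpec(orientation_model="swirl")

    def test_lambda_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            FiberPhantomSpec(lambdas=(0.2e-3, 1.7e-3, 0.2e-3))


class TestSimulateDwi:
    def test_isotropic_closed_form(self):
        spec = FiberPhantomSpec(grid_shape=(4, 4, 4))
        _, tf = make_fiber_field(spec)
        iso = np.broadcast_to(1e-3 * np.eye(3), (4, 4, 4, 3, 3))
        from dtigrowth import TensorField
        tfi = TensorField.from_matrices(iso, spec.affine)
        dwi = simulate_dwi(tfi, s0=1000.0)
        assert np.allclose(dwi.signal[..., 0], 1000.0)
        assert np.allclose(dwi.signal[..., 1:], 1000.0 * np.exp(-1.0), atol=1e-9)

    def test_zero_tensor_gives_flat_signal(self):
        from dtigrowth import TensorField
        tf = TensorField(np.zeros((3, 3, 3, 6)), np.eye(4))
        dwi = simulate_dwi(tf, s0=700.0)
        assert np.allclose(dwi.signal, 700.0)

    def test_noiseless_roundtrip_through_fit(self, uniform_phantom):
        _, _, tf, _ = uniform_phantom
        dwi = simulate_dwi(tf)
        fitted = fit_tensor(dwi)
        assert np.abs(fitted.components - tf.components).max() < 1e-10

    def test_rician_noise_seeded_and_biased_up(self):
        from dtigrowth import TensorField
        tf = TensorField(np.zeros((8, 8, 8, 6)), np.eye(4))
        d1 = simulate_dwi(tf, s0=50.0, noise_sigma=20.0, rng_seed=3)
        d2 = simulate_dwi(tf, s0=50.0, noise_sigma=20.0, rng_seed=3)
        assert np.array_equal(d1.signal, d2.signal)
        assert np.all(d1.signal >= 0)
        # Rician noise inflates the mean of low-SNR magnitudes
        assert d1.signal.mean() > 50.0

    def test_gradient_scheme_well_posed(self):
        g = gradient_scheme(6)
        assert np.allclose(np.linalg.norm(g, axis=1), 1.0)
        assert np.linalg.matrix_rank(g) == 3
        g9 = gradient_scheme(9)
        assert g9.shape == (9, 3)
        assert np.allclose(np.linalg.norm(g9, axis=1), 1.0)

    def test_bad_s0_rejected(self, uniform_phantom):
        _, _, tf, _ = uniform_phantom
        with pytest.raises(DomainError):
            simulate_dwi(tf, s0=0.0)


class TestGrowLesion:
    @staticmethod
    def _phantom(shape=(32, 32, 32)):
        spec = FiberPhantomSpec(grid_shape=shape)
        dirs, tf = make_fiber_field(spec)
        return spec, dirs, tf

    def test_ratio_one_returns_equal_masks(self):
        spec, dirs, _ = self._phantom()
        m1, m2 = grow_lesion(dirs, GrowthSpec(seed_radius_mm=10,
                                              target_volume_ratio=1.0), spec.affine)
        assert np.array_equal(m1.voxels, m2.voxels)

    def test_monotone_and_ratio_reached(self):
        spec, dirs, _ = self._phantom()
        gs = GrowthSpec(seed_radius_mm=10, target_volume_ratio=2.0, rng_seed=2)
        m1, m2 = grow_lesion(dirs, gs, spec.affine)
        assert np.all(m2.voxels[m1.voxels])
        assert m2.count() == int(np.ceil(2.0 * m1.count()))

    def test_deterministic_given_seed(self):
        spec, dirs, _ = self._phantom()
        gs = GrowthSpec(seed_radius_mm=10, bias_kappa=2.0, rng_seed=5)
        a = grow_lesion(dirs, gs, spec.affine)
        b = grow_lesion(dirs, gs, spec.affine)
        assert np.array_equal(a[1].voxels, b[1].voxels)

    def test_seed_outside_grid_rejected(self):
        spec, dirs, _ = self._phantom((16, 16, 16))
        with pytest.raises(DomainError):
            grow_lesion(dirs, GrowthSpec(seed_radius_mm=20), spec.affine)

    def test_unreachable_ratio_rejected(self):
        spec, dirs, _ = self._phantom((16, 16, 16))
        with pytest.raises(DomainError):
            grow_lesion(dirs, GrowthSpec(seed_radius_mm=10,
                                         target_volume_ratio=50.0), spec.affine)

    def test_recovery_monotone_in_kappa(self):
        spec = FiberPhantomSpec(grid_shape=(48, 48, 48))
        dirs, tf = make_fiber_field(spec)
        es = eigendecompose(tf)
        means = []
        for kappa in (0.0, 1.0, 2.0, 4.0, 8.0):
            vals = []
            for seed in range(20):
                gs = GrowthSpec(seed_radius_mm=14, bias_kappa=kappa, rng_seed=seed)
                m1, m2 = grow_lesion(dirs, gs, spec.affine)
                df = estimate_deformation(m1, m2)
                vals.append(bin_growth(df, es).parallel_pct())
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestMakeCohort:
    def test_structure_and_determinism(self, tmp_path):
        spec = FiberPhantomSpec(grid_shape=(20, 20, 20))
        gs = GrowthSpec(seed_radius_mm=7)
        m1 = make_cohort(2, 2, gs, gs, spec, rng_seed=42, out_dir=tmp_path / "a",
                         write_dwi=False)
        assert len(m1) == 4
        assert sorted(m1["group"]) == ["TP", "TP", "TRA", "TRA"]
        for sid in m1["subject_id"]:
            assert (tmp_path / "a" / sid / "mask_tp1.nii").exists()
        make_cohort(2, 2, gs, gs, spec, rng_seed=42, out_dir=tmp_path / "b",
                    write_dwi=False)
        assert (tmp_path / "a" / "cohort.csv").read_bytes() == \
               (tmp_path / "b" / "cohort.csv").read_bytes()
        ja = (tmp_path / "a" / "manifest.json").read_text()
        jb = (tmp_path / "b" / "manifest.json").read_text()
        assert ja == jb

    def test_kappa_separated_cohorts_detected_by_mwu(self):
        # biased (kappa=4) vs unbiased (kappa=0) groups of 20 subjects each:
        # the Mann-Whitney test on parallel percentages should nearly always reject
        from dtigrowth import bin_growth, eigendecompose, estimate_deformation, \
            mann_whitney_u
        spec = FiberPhantomSpec(grid_shape=(20, 20, 20))
        dirs, tf = make_fiber_field(spec)
        es = eigendecompose(tf)
        seeds = iter(np.random.SeedSequence(77).generate_state(200 * 40) % (2 ** 31))

        def parallel(kappa):
            gs = GrowthSpec(seed_radius_mm=7.0, bias_kappa=kappa,
                            rng_seed=int(next(seeds)))
            m1, m2 = grow_lesion(dirs, gs, spec.affine)
            return bin_growth(estimate_deformation(m1, m2), es).parallel_pct()

        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            tp = [parallel(4.0) for _ in range(20)]
            tra = [parallel(0.0) for _ in range(20)]
            hits += mann_whitney_u(tp, tra).p_value < 0.05
        assert hits / n_rep >= 0.8

    def test_subjects_vary_between_seeds(self, tmp_path):
        spec = FiberPhantomSpec(grid_shape=(20, 20, 20))
        gs = GrowthSpec(seed_radius_mm=7)
        a = make_cohort(1, 1, gs, gs, spec, rng_seed=1, out_dir=tmp_path / "a",
                        write_dwi=False)
        b = make_cohort(1, 1, gs, gs, spec, rng_seed=2, out_dir=tmp_path / "b",
                        write_dwi=False)
        assert not a.drop(columns="subject_id").equals(b.drop(columns="subject_id"))
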