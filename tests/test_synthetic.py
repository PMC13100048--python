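"""Synthetic-scene generators: determinism and ground-truth consistency."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import tomovault as tv
from tomovault.errors import SizingError
from tomovault.rotations import rotation_angle_deg
from tomovault.synthetic import bilayer_profile_model


class TestBilayerScene:
    def test_seeded_determinism(self):
        spec = tv.BilayerSpec(noise_sd=0.1, seed=3)
        v1, m1, _ = tv.make_bilayer_scene(spec)
        v2, m2, _ = tv.make_bilayer_scene(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_seed_changes_only_noise(self):
        base = dict(noise_sd=0.1)
        v1, _, _ = tv.make_bilayer_scene(tv.BilayerSpec(**base, seed=1))
        v2, _, _ = tv.make_bilayer_scene(tv.BilayerSpec(**base, seed=2))
        assert not np.array_equal(v1.data, v2.data)
        n1, _, _ = tv.make_bilayer_scene(
            tv.BilayerSpec(noise_sd=0.0, seed=1))
        n2, _, _ = tv.make_bilayer_scene(
            tv.BilayerSpec(noise_sd=0.0, seed=2))
        np.testing.assert_array_equal(n1.data, n2.data)

    def test_trough_positions_match_numerical_minimisation(
            self, flat_bilayer_scene):
        # oracle: minimise the closed-form two-Gaussian profile
        spec, volume, _, truth = flat_bilayer_scene
        res = minimize_scalar(
            lambda s: bilayer_profile_model(np.array([s]), 6.0, 1.0)[0],
            bounds=(1.0, 5.0), method="bounded")
        oracle_separation = 2.0 * res.x          # ~6.0 nm
        iz = np.argsort(volume.data[:, 32, 32])[:2]   # two darkest z samples
        measured = abs(iz[0] - iz[1]) * spec.voxel_size
        assert measured == pytest.approx(oracle_separation,
                                         abs=spec.voxel_size / 2)

    def test_patch_ground_truth_thickness(self, patch_scene):
        spec, _, _, truth = patch_scene
        assert np.all(truth.thickness[truth.in_patch]
                      == spec.leaflet_separation - spec.patch_thinning)
        assert np.all(truth.thickness[~truth.in_patch]
                      == spec.leaflet_separation)

    def test_noiseless_volume_symmetric_about_midsurface(
            self, flat_bilayer_scene):
        _, volume, _, _ = flat_bilayer_scene
        data = volume.data
        np.testing.assert_allclose(data, data[::-1], atol=1e-12)

    def test_indent_ring_curvature_sign(self):
        spec = tv.BilayerSpec(grid_shape=(64, 96, 96),
                              indent_ring_radius=20.0, indent_depth=4.0)
        _, _, truth = tv.make_bilayer_scene(spec)
        ny, nx = truth.mid_z.shape
        xx, yy = np.meshgrid(truth.x, truth.y)
        r = np.hypot(xx - truth.x.mean(), yy - truth.y.mean())
        on_ring = np.abs(r - spec.indent_ring_radius) < 1.0
        # the membrane is indented at the ring: mean curvature negative
        assert np.median(truth.mean_curvature[on_ring]) < 0

    def test_oversized_geometry_rejected(self):
        with pytest.raises(SizingError, match="patch"):
            tv.make_bilayer_scene(tv.BilayerSpec(
                grid_shape=(48, 32, 32), patch_radius=30.0,
                patch_thinning=1.0))
        with pytest.raises(SizingError, match="envelope"):
            tv.make_bilayer_scene(tv.BilayerSpec(
                grid_shape=(8, 32, 32), leaflet_separation=6.0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            tv.BilayerSpec(leaflet_separation=-1.0)
        with pytest.raises(ValueError):
            tv.BilayerSpec(patch_thinning=7.0, leaflet_separation=6.0)


class TestParametricMeshes:
    def test_sphere_analytic_curvature(self):
        mesh, analytic = tv.make_parametric_mesh(
            tv.MeshSpec(kind="sphere", radius=10.0, target_vertex_count=642))
        np.testing.assert_allclose(analytic["H"], 0.1)
        np.testing.assert_allclose(analytic["K"], 0.01)
        radii = np.linalg.norm(mesh.vertices, axis=1)
        np.testing.assert_allclose(radii, 10.0, atol=1e-9)

    def test_jittered_sphere_stays_on_sphere(self):
        mesh, _ = tv.make_parametric_mesh(
            tv.MeshSpec(kind="sphere", radius=10.0, target_vertex_count=642,
                        jitter_sd=0.05, seed=5))
        np.testing.assert_allclose(np.linalg.norm(mesh.vertices, axis=1),
                                   10.0, atol=1e-9)

    def test_plane_flat(self):
        _, analytic = tv.make_parametric_mesh(
            tv.MeshSpec(kind="plane", extent=20.0, target_vertex_count=400))
        assert np.all(analytic["H"] == 0)
        assert np.all(analytic["K"] == 0)

    def test_cylinder_principal_curvatures(self):
        _, analytic = tv.make_parametric_mesh(
            tv.MeshSpec(kind="cylinder", radius=5.0, extent=20.0,
                        target_vertex_count=400))
        np.testing.assert_allclose(analytic["k1"], 0.2)
        np.testing.assert_allclose(analytic["k2"], 0.0, atol=1e-15)
        np.testing.assert_allclose(analytic["K"], 0.0, atol=1e-15)

    def test_saddle_negative_gaussian_curvature(self):
        _, analytic = tv.make_parametric_mesh(
            tv.MeshSpec(kind="saddle", radius=10.0, extent=20.0,
                        target_vertex_count=400))
        assert np.all(analytic["K"] < 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            tv.MeshSpec(kind="torus")


class TestPosePopulation:
    def test_encapsulation_count_by_construction(self):
        spec = tv.PopulationSpec(n_vaults_cytosolic=50,
                                 encapsulation_fraction_cytosolic=0.1, seed=9)
        _, _, truth = tv.make_pose_population(spec)
        assert int(truth.encapsulated.sum()) == 5

    def test_large_kappa_concentrates_axes(self):
        spec = tv.PopulationSpec(n_vaults_cytosolic=30,
                                 encapsulation_fraction_cytosolic=1.0,
                                 n_free_ribosomes=0, kappa=1e7, seed=2,
                                 box_extent=1500.0)
        _, _, truth = tv.make_pose_population(spec)
        assert np.all(truth.rel_angle_deg < 1.0)

    def test_uniform_axes_have_small_resultant(self):
        spec = tv.PopulationSpec(n_vaults_cytosolic=10000,
                                 encapsulation_fraction_cytosolic=1.0,
                                 n_free_ribosomes=0,
                                 relative_orientation_mode="uniform",
                                 min_separation=0.0, box_extent=5000.0,
                                 seed=11)
        vaults, ribosomes, truth = tv.make_pose_population(spec)
        # Monte-Carlo oracle: uniform directions have resultant ~ 1/sqrt(n)
        ref = np.array([0.0, 0.0, 1.0])
        vault_idx = truth.vault_index.to_numpy()
        rel = np.einsum("nji,njk->nik", vaults.rotations[vault_idx],
                        ribosomes.rotations)      # R_vault^T @ R_ribosome
        axes = rel @ ref
        assert np.linalg.norm(axes.mean(axis=0)) < 0.05

    def test_encapsulated_within_cutoff_free_far_away(self):
        spec = tv.PopulationSpec(n_vaults_cytosolic=40,
                                 encapsulation_fraction_cytosolic=0.25,
                                 seed=4)
        vaults, ribosomes, truth = tv.make_pose_population(spec)
        for i, row in truth.iterrows():
            dists = np.linalg.norm(vaults.positions - ribosomes.positions[i],
                                   axis=1)
            if row.encapsulated:
                assert dists[row.vault_index] < spec.pairing_cutoff
            else:
                assert dists.min() >= 2 * spec.pairing_cutoff

    def test_packing_error_when_box_too_small(self):
        with pytest.raises(tv.synthetic.PackingError):
            tv.make_pose_population(tv.PopulationSpec(
                n_vaults_cytosolic=100, box_extent=100.0,
                min_separation=60.0, seed=1))

    def test_determinism(self):
        spec = tv.PopulationSpec(n_vaults_cytosolic=20, seed=8)
        v1, r1, t1 = tv.make_pose_population(spec)
        v2, r2, t2 = tv.make_pose_population(spec)
        np.testing.assert_array_equal(v1.positions, v2.positions)
        np.testing.assert_array_equal(r1.rotations, r2.rotations)
        assert t1.equals(t2)


class TestSubtomograms:
    def test_noiseless_identity_rotation_equals_template(self, template_pair):
        tpl_a, tpl_b = template_pair
        subs = tv.make_subtomograms(tpl_a, tpl_b, n=2, noise_sd=0.0, seed=0,
                                    rotation_pool=np.eye(3)[None],
                                    n_class_a=2)
        for sub in subs:
            np.testing.assert_allclose(sub.volume.data, tpl_a.data,
                                       atol=1e-12)
            assert rotation_angle_deg(sub.true_rotation, np.eye(3)) < 1e-9

    def test_open_wedge_is_identity(self, template_pair):
        tpl_a, tpl_b = template_pair
        kw = dict(n=2, noise_sd=0.0, seed=1, n_class_a=1)
        open_wedge = tv.make_subtomograms(tpl_a, tpl_b,
                                          wedge_halfangle=90.0, **kw)
        no_wedge = tv.make_subtomograms(tpl_a, tpl_b, **kw)
        for s1, s2 in zip(open_wedge, no_wedge):
            np.testing.assert_array_equal(s1.volume.data, s2.volume.data)

    def test_narrow_wedge_removes_power(self, template_pair):
        tpl_a, tpl_b = template_pair
        kw = dict(n=1, noise_sd=0.0, seed=2, n_class_a=1,
                  rotation_pool=np.eye(3)[None])
        wedged = tv.make_subtomograms(tpl_a, tpl_b, wedge_halfangle=60.0,
                                      **kw)[0]
        assert (wedged.volume.data**2).sum() < (tpl_a.data**2).sum()

    def test_shape_mismatch_rejected(self, template_pair):
        tpl_a, _ = template_pair
        small = tv.DensityVolume(np.zeros((8, 8, 8)), 1.0)
        with pytest.raises(ValueError, match="shape"):
            tv.make_subtomograms(tpl_a, small, n=1)
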