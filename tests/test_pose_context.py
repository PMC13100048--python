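"""Ribosome-vault pairing, relative orientations and printed-count summaries."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tomovault as tv
from tomovault.errors import DegenerateStatisticsError
from tomovault.pose_context import PairAssignment, histogram_bin_directions
from tomovault.rotations import random_rotations

Z = np.array([0.0, 0.0, 1.0])


def pose_set(positions, rotations=None, tomogram_ids=None):
    positions = np.atleast_2d(positions)
    if rotations is None:
        rotations = np.tile(np.eye(3), (len(positions), 1, 1))
    return tv.PoseSet(positions, rotations, tomogram_ids=tomogram_ids)


class TestPairNearest:
    def test_cutoff_boundary(self):
        vaults = pose_set([[0.0, 0.0, 0.0]])
        near = pose_set([[9.9, 0.0, 0.0]])
        far = pose_set([[10.1, 0.0, 0.0]])
        assert len(tv.pair_nearest(near, vaults, cutoff=10.0)) == 1
        assert len(tv.pair_nearest(far, vaults, cutoff=10.0)) == 0

    def test_equidistant_tie_goes_to_lower_index(self):
        vaults = pose_set([[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        ribosome = pose_set([[0.0, 0.0, 0.0]])
        pairs = tv.pair_nearest(ribosome, vaults, cutoff=10.0)
        assert pairs[0].vault_index == 0

    def test_matching_is_per_tomogram(self):
        vaults = pose_set([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]],
                          tomogram_ids=["t1", "t2"])
        ribosomes = pose_set([[99.0, 0.0, 0.0]], tomogram_ids=["t2"])
        pairs = tv.pair_nearest(ribosomes, vaults, cutoff=10.0)
        assert len(pairs) == 1 and pairs[0].vault_index == 1

    def test_unknown_tomogram_id_rejected(self):
        vaults = pose_set([[0.0, 0.0, 0.0]], tomogram_ids=["t1"])
        ribosomes = pose_set([[1.0, 0.0, 0.0]], tomogram_ids=["t9"])
        with pytest.raises(ValueError, match="tomogram"):
            tv.pair_nearest(ribosomes, vaults, cutoff=10.0)

    def test_generator_population_recovered_exactly(self):
        spec = tv.PopulationSpec(n_vaults_cytosolic=50,
                                 encapsulation_fraction_cytosolic=0.1,
                                 seed=21)
        vaults, ribosomes, truth = tv.make_pose_population(spec)
        pairs = tv.pair_nearest(ribosomes, vaults, cutoff=10.0)
        found = {(p.ribosome_index, p.vault_index) for p in pairs}
        expected = {(i, int(row.vault_index))
                    for i, row in truth.iterrows() if row.encapsulated}
        assert found == expected          # precision = recall = 1


class TestRelativeAxis:
    def test_equal_poses_return_reference(self):
        rot = random_rotations(np.random.default_rng(0), 1)[0]
        pair = PairAssignment(0, 0, 1.0, rot.T @ rot)
        np.testing.assert_allclose(tv.relative_axis(pair, Z), Z, atol=1e-12)

    def test_inplane_rotation_fixes_its_axis(self):
        r_rel = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        pair = PairAssignment(0, 0, 1.0, r_rel)
        np.testing.assert_allclose(tv.relative_axis(pair, Z), Z, atol=1e-12)

    def test_matches_direct_matrix_arithmetic(self):
        rng = np.random.default_rng(3)
        r_vault, r_rib = random_rotations(rng, 2)
        vaults = pose_set([[0.0, 0.0, 0.0]], r_vault[None])
        ribosomes = pose_set([[1.0, 0.0, 0.0]], r_rib[None])
        pair = tv.pair_nearest(ribosomes, vaults, cutoff=10.0)[0]
        expected = r_vault.T @ r_rib @ Z        # brute-force oracle
        np.testing.assert_allclose(tv.relative_axis(pair, Z), expected,
                                   atol=1e-12)

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(4)
        r_vault, r_rib, r_global = random_rotations(rng, 3)
        pos_v = np.array([3.0, -2.0, 1.0])
        pos_r = pos_v + [2.0, 1.0, -1.0]
        base = tv.pair_nearest(pose_set(pos_r, r_rib[None]),
                               pose_set(pos_v, r_vault[None]), 10.0)[0]
        moved = tv.pair_nearest(
            pose_set((r_global @ pos_r), (r_global @ r_rib)[None]),
            pose_set((r_global @ pos_v), (r_global @ r_vault)[None]), 10.0)[0]
        assert moved.distance == pytest.approx(base.distance, abs=1e-9)
        np.testing.assert_allclose(tv.relative_axis(moved, Z),
                                   tv.relative_axis(base, Z), atol=1e-9)


class TestSphericalHistogram:
    def test_identical_axes_fill_one_bin(self):
        axes = np.tile(histogram_bin_directions(1)[7], (25, 1))
        hist = tv.spherical_histogram(axes, n_subdiv=1)
        assert hist.total == 25
        assert hist.counts.max() == 25
        assert (hist.counts > 0).sum() == 1

    def test_empty_input_gives_zero_histogram(self):
        hist = tv.spherical_histogram(np.zeros((0, 3)), n_subdiv=1)
        assert hist.total == 0
        assert (hist.counts == 0).all()

    def test_uniform_directions_spread_evenly(self):
        rng = np.random.default_rng(5)
        axes = rng.normal(size=(100000, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        hist = tv.spherical_histogram(axes, n_subdiv=1)
        assert hist.total == 100000
        assert hist.counts.max() / hist.counts.min() < 1.5

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(6)
        axes = rng.normal(size=(500, 3))
        hist = tv.spherical_histogram(axes, n_subdiv=2)
        assert hist.counts.sum() == hist.total == 500

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            tv.spherical_histogram(np.zeros((3, 3)))


class TestClassifyRtc:
    def _pair_at_angle(self, angle_deg):
        r_rel = Rotation.from_euler("x", angle_deg, degrees=True).as_matrix()
        return PairAssignment(0, 0, 1.0, r_rel)

    def test_aligned_axes_always_rtc_like(self):
        pair = self._pair_at_angle(0.0)
        for theta in (5.0, 30.0, 89.0):
            assert tv.classify_rtc([pair], Z, Z, theta) == ["RTC-like"]

    def test_perpendicular_axes_never_rtc_like(self):
        # the cytosolic configuration: longitudinal axes perpendicular
        pair = self._pair_at_angle(90.0)
        assert tv.classify_rtc([pair], Z, Z, 30.0) == ["other"]
        assert tv.classify_rtc([pair], Z, Z, 89.0) == ["other"]

    def test_boundary_is_inclusive(self):
        pair = self._pair_at_angle(30.0)
        assert tv.classify_rtc([pair], Z, Z, 30.0) == ["RTC-like"]


class TestSummaries:
    def test_orientation_contingency_printed_counts(self):
        membrane = ["RTC-like"] * 3 + ["other"]
        cytosolic = ["other"] * 80
        table, result = tv.orientation_contingency(membrane, cytosolic)
        assert (table.a, table.b, table.c, table.d) == (3, 1, 0, 80)
        assert result.p_value < 1e-4

    def test_balanced_table_not_significant(self):
        table, result = tv.orientation_contingency(
            ["RTC-like", "other"], ["RTC-like", "other"])
        assert result.p_value == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            tv.orientation_contingency([], ["other"])

    def test_encapsulation_summary_printed_counts(self):
        classes = ["cytosolic"] * 985 + ["membrane"] * 14
        pairs = [PairAssignment(i, i, 5.0, np.eye(3)) for i in range(80)]
        pairs += [PairAssignment(900 + i, 985 + i, 5.0, np.eye(3))
                  for i in range(4)]
        summary = tv.encapsulation_summary(classes, pairs)
        assert summary.counts["cytosolic"] == (80, 905)
        assert summary.counts["membrane"] == (4, 10)
        assert summary.percentages == {"cytosolic": 8, "membrane": 29}
        assert summary.test.p_value == pytest.approx(0.0242, abs=5e-5)

    def test_unlabelled_vault_rejected(self):
        with pytest.raises(ValueError, match="class"):
            tv.encapsulation_summary(["cytosolic", ""], [])

    def test_class_fractions_one_decimal(self):
        classes = ["membrane"] * 14 + ["cytosolic"] * 985
        out = tv.class_fraction_summary(classes)
        assert out["membrane"]["percent"] == 1.4
        assert out["cytosolic"]["percent"] == 98.6
        assert tv.class_fraction_summary(["a"] * 999)["a"]["percent"] == 100.0


class TestConcentrationSignature:
    def test_concentrated_mass_in_top_bin_uniform_spread_out(self):
        mode_axis = tuple(histogram_bin_directions(1)[0])
        common = dict(n_vaults_cytosolic=150,
                      encapsulation_fraction_cytosolic=1.0,
                      n_free_ribosomes=0, box_extent=2000.0,
                      target_axis=mode_axis)
        conc_spec = tv.PopulationSpec(**common, seed=31)
        unif_spec = tv.PopulationSpec(**common, seed=32,
                                      relative_orientation_mode="uniform")
        results = {}
        for name, spec in (("conc", conc_spec), ("unif", unif_spec)):
            vaults, ribosomes, _ = tv.make_pose_population(spec)
            pairs = tv.pair_nearest(ribosomes, vaults, 10.0)
            axes = [tv.relative_axis(p, Z) for p in pairs]
            hist = tv.spherical_histogram(axes, n_subdiv=1)
            results[name] = hist.counts.max() / hist.total
        assert results["conc"] > 0.8
        assert results["unif"] < 0.2
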