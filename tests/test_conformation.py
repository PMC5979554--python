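"""Genotype-to-pose kinematics, RMSD, and genotype repair."""

import numpy as np
import pytest

from adhdock.conformation import (Genotype, SearchBox, build_pose,
                                  normalize_orientation, random_genotype,
                                  repair_genotype, repair_vector, rmsd)
from adhdock.fixtures import make_toy_complex

IDQ = np.array([1.0, 0.0, 0.0, 0.0])


def _identity_genotype(toy):
    return toy.planted_genotype.copy()


class TestOrientation:
    @pytest.mark.parametrize("q", [(1, 0, 0, 0), (2, 0, 0, 0), (0.3, -1.2, 0.7, 2.0)])
    def test_normalization_preserves_direction(self, q):
        g = Genotype(np.zeros(3), np.array(q, float), np.zeros(0))
        out = normalize_orientation(g)
        assert np.linalg.norm(out.orientation) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            out.orientation, np.asarray(q, float) / np.linalg.norm(q), atol=1e-12)

    def test_zero_quaternion_rejected(self):
        g = Genotype(np.zeros(3), np.zeros(4), np.zeros(0))
        with pytest.raises(ValueError, match="degenerate orientation"):
            normalize_orientation(g)


class TestBuildPose:
    def test_identity_genotype_recovers_reference(self, toy):
        pose = build_pose(toy.ligand, _identity_genotype(toy), toy.box)
        np.testing.assert_allclose(pose.coords, toy.ligand.reference_coords,
                                   atol=1e-12)

    def test_translation_equivariance(self, toy):
        g = _identity_genotype(toy)
        base = build_pose(toy.ligand, g, toy.box).coords
        g.translation = g.translation + np.array([1.0, 0.0, 0.0])
        shifted = build_pose(toy.ligand, g, toy.box).coords
        np.testing.assert_allclose(shifted - base,
                                   np.tile([1.0, 0.0, 0.0], (len(base), 1)),
                                   atol=1e-12)

    def test_half_turn_about_z(self, toy):
        g = _identity_genotype(toy)
        base = build_pose(toy.ligand, g, toy.box).coords
        root = sorted(toy.ligand.torsion_tree.root_atoms)
        centroid = base[root].mean(axis=0)
        g.orientation = np.array([0.0, 0.0, 0.0, 1.0])  # 180 deg about z
        rot = build_pose(toy.ligand, g, toy.box).coords
        rel_base, rel_rot = base - centroid, rot - centroid
        np.testing.assert_allclose(rel_rot[:, 0], -rel_base[:, 0], atol=1e-9)
        np.testing.assert_allclose(rel_rot[:, 1], -rel_base[:, 1], atol=1e-9)
        np.testing.assert_allclose(rel_rot[:, 2], rel_base[:, 2], atol=1e-9)

    @pytest.mark.parametrize("which", [0, 1])
    def test_torsion_perturbation_is_branch_local(self, toy, which):
        g0 = _identity_genotype(toy)
        g1 = _identity_genotype(toy)
        g1.torsions[which] += 0.7
        a = build_pose(toy.ligand, g0, toy.box).coords
        b = build_pose(toy.ligand, g1, toy.box).coords
        moved = np.where(np.linalg.norm(a - b, axis=1) > 1e-9)[0]
        branch = toy.ligand.torsion_tree.branches[which]
        assert set(moved) <= set(branch.moved)
        assert len(moved) > 0

    def test_rigid_group_distances_preserved(self, toy, rng):
        """Any translation+orientation with zero torsions preserves all
        interatomic distances (the whole ligand is one rigid body)."""
        ref = toy.ligand.reference_coords
        d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        for _ in range(5):
            g = random_genotype(toy.ligand.n_torsions, toy.box, rng)
            g.torsions[:] = 0.0
            pose = build_pose(toy.ligand, g, toy.box).coords
            d = np.linalg.norm(pose[:, None] - pose[None, :], axis=-1)
            np.testing.assert_allclose(d, d_ref, atol=1e-9)

    def test_torsion_count_mismatch_rejected(self, toy):
        g = Genotype(np.zeros(3), IDQ, np.zeros(toy.ligand.n_torsions + 1))
        with pytest.raises(ValueError, match="torsions"):
            build_pose(toy.ligand, g, toy.box)


class TestRmsd:
    def test_identical_poses_zero(self, rng):
        a = rng.normal(size=(8, 3))
        assert rmsd(a, a.copy()) == 0.0

    def test_uniform_translation_is_its_norm(self, rng):
        a = rng.normal(size=(5, 3))
        assert rmsd(a, a + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_single_displaced_atom(self):
        a = np.zeros((2, 3))
        b = a.copy()
        b[0, 0] = 2.0
        assert rmsd(a, b) == pytest.approx(np.sqrt(2.0))

    def test_heavy_only_excludes_hydrogens(self):
        a = np.zeros((2, 3))
        b = a.copy()
        b[1] = [10.0, 0.0, 0.0]  # hydrogen atom displaced
        assert rmsd(a, b, atom_types=["C", "HD"], heavy_only=True) == 0.0
        assert rmsd(a, b, atom_types=["C", "HD"], heavy_only=False) > 0

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_pseudometric_on_random_triples(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 6, 3))
            assert rmsd(a, b) == pytest.approx(rmsd(b, a), rel=1e-12)
            assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-12


class TestRandomGenotype:
    def test_sampling_distributions(self, toy, rng):
        n = 2000
        samples = [random_genotype(toy.ligand.n_torsions, toy.box, rng)
                   for _ in range(n)]
        trans = np.array([g.translation for g in samples])
        assert np.all(np.abs(trans) <= toy.box.half_extent + 1e-12)
        quats = np.array([g.orientation for g in samples])
        np.testing.assert_allclose(np.linalg.norm(quats, axis=1), 1.0, atol=1e-9)
        # uniform-on-sphere null: each component has mean 0, var 1/4
        z = np.abs(quats.mean(axis=0)) / (0.5 / np.sqrt(n))
        assert np.all(z < 4.0)
        tors = np.array([g.torsions for g in samples])
        assert np.all((tors > -np.pi) & (tors <= np.pi))


class TestRepair:
    def test_idempotent_and_identity_on_valid(self, toy, rng):
        g = random_genotype(toy.ligand.n_torsions, toy.box, rng)
        r1 = repair_genotype(g, toy.box)
        r2 = repair_genotype(r1, toy.box)
        np.testing.assert_allclose(r1.to_vector(), g.to_vector(), atol=1e-12)
        np.testing.assert_allclose(r1.to_vector(), r2.to_vector(), atol=1e-15)

    def test_translation_clamped_to_box(self, toy):
        g = toy.planted_genotype.copy()
        g.translation = toy.box.half_extent + 1.0
        out = repair_genotype(g, toy.box)
        np.testing.assert_allclose(out.translation, toy.box.half_extent)

    def test_torsion_wrap_boundary_maps_to_plus_pi(self, toy):
        vec = toy.planted_genotype.to_vector()
        vec[7:] = 3 * np.pi
        out = repair_vector(vec, toy.box)
        np.testing.assert_allclose(out[7:], np.pi, atol=1e-12)

    def test_quaternion_renormalized(self, toy):
        vec = toy.planted_genotype.to_vector()
        vec[3:7] = [2.0, 0.0, 0.0, 0.0]
        out = repair_vector(vec, toy.box)
        np.testing.assert_allclose(out[3:7], [1, 0, 0, 0], atol=1e-15)
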