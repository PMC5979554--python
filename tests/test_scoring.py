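"""Scoring function: per-term behavior, oracle equivalence, invariances.

The independent oracle is a deliberately naive double loop over atom pairs
written directly from the term formulas, kept free of the vectorized
implementation's code paths.
"""

import math

import numpy as np
import pytest

from adhdock.conformation import Genotype, build_pose, random_genotype
from adhdock.fixtures import make_toy_complex
from adhdock.model_io import Atom, load_forcefield
from adhdock.scoring import (EnergyModel, binding_energy, internal_energy,
                             intermolecular_energy, moving_pairs, pair_energy)


def _atom(atype="C", q=0.0, coords=(0, 0, 0), s=0.0, v=0.0):
    return Atom(serial=1, name="X", autodock_type=atype,
                coords=np.array(coords, float), partial_charge=q,
                solvation_volume=v, solvation_param=s)


# ---------------------------------------------------------------------------
# naive oracle

def naive_pair(ai, aj, r, table):
    a, b = table.vdw_coeffs(ai.autodock_type, aj.autodock_type)
    vdw = table.w_vdw * (a / r**12 - b / r**6)
    c, d = table.hbond_coeffs(ai.autodock_type, aj.autodock_type)
    hb = table.w_hbond * (c / r**12 - d / r**10)
    el = (table.w_elec * table.COULOMB * ai.partial_charge * aj.partial_charge
          / (table.epsilon(r) * r))
    ds = (table.w_sol * (ai.solvation_param * aj.solvation_volume
                         + aj.solvation_param * ai.solvation_volume)
          * math.exp(-r * r / (2 * table.sigma**2)))
    return vdw + hb + el + ds


def naive_binding_energy(receptor, ligand, genotype, box, table):
    table.assign(receptor.atoms)
    table.assign(ligand.atoms)
    pose = build_pose(ligand, genotype, box).coords
    total = 0.0
    for i, ra in enumerate(receptor.atoms):
        for j, la in enumerate(ligand.atoms):
            r = float(np.linalg.norm(receptor.coords[i] - pose[j]))
            total += naive_pair(ra, la, r, table)
    pairs = naive_moving_pairs(ligand)
    for coords, sign in ((pose, +1.0), (ligand.reference_coords, -1.0)):
        for i, j in pairs:
            r = float(np.linalg.norm(coords[i] - coords[j]))
            total += sign * naive_pair(ligand.atoms[i], ligand.atoms[j], r, table)
    total += table.w_conf * ligand.n_torsions
    return total


def naive_moving_pairs(ligand):
    """Graph-distance oracle: adjacency power walk instead of BFS."""
    n = len(ligand)
    adj = np.zeros((n, n), dtype=bool)
    for i, j in ligand.bonds:
        adj[i, j] = adj[j, i] = True
    dist = np.full((n, n), 99)
    np.fill_diagonal(dist, 0)
    reach = np.eye(n, dtype=bool)
    frontier = adj.copy()
    for k in range(1, n):
        new = frontier & ~reach
        dist[new & (dist == 99)] = k
        reach |= frontier
        frontier = (frontier.astype(int) @ adj.astype(int)) > 0
    group = ligand.torsion_tree.group_index(n)
    return [(i, j) for i in range(n) for j in range(i + 1, n)
            if group[i] != group[j] and dist[i, j] > 3]


# ---------------------------------------------------------------------------

class TestPairEnergy:
    def test_zero_charge_zeroes_elec(self, table):
        e = pair_energy(_atom(q=0.0), _atom(q=1.5), 3.0, table)
        assert e.elec == 0.0

    def test_vdw_minimum_analytic(self, table):
        # unit weights and A=1, B=2: minimum at r = (2A/B)^(1/6) = 1, depth -1
        a, b = 1.0, 2.0
        r = (2 * a / b) ** (1 / 6)
        assert a / r**12 - b / r**6 == pytest.approx(-(b * b) / (4 * a), rel=1e-12)
        # and through the production path for a real pair
        ti, tj = "C", "N"
        A, B = table.vdw_coeffs(ti, tj)
        r_min = (2 * A / B) ** (1 / 6)
        e_min = pair_energy(_atom(ti), _atom(tj), r_min, table).vdw
        e_near = pair_energy(_atom(ti), _atom(tj), r_min * 1.01, table).vdw
        assert e_min == pytest.approx(-table.w_vdw * B * B / (4 * A), rel=1e-12)
        assert e_min < e_near

    def test_desolvation_gaussian_at_sigma(self, table):
        ai = _atom(s=0.01, v=10.0)
        aj = _atom(s=0.02, v=20.0)
        e = pair_energy(ai, aj, table.sigma, table)
        expect = table.w_sol * (0.01 * 20.0 + 0.02 * 10.0) * math.exp(-0.5)
        assert e.desolv == pytest.approx(expect, rel=1e-12)
        far = pair_energy(ai, aj, 80.0, table)
        assert abs(far.desolv) < 1e-12

    def test_symmetry_over_random_parameters(self, table, rng):
        types = table.known_types()
        for _ in range(25):
            ti, tj = rng.choice(types, size=2)
            ai = _atom(ti, q=rng.normal(), s=rng.random(), v=10 * rng.random())
            aj = _atom(tj, q=rng.normal(), s=rng.random(), v=10 * rng.random())
            r = 1.5 + 5 * rng.random()
            assert pair_energy(ai, aj, r, table) == pair_energy(aj, ai, r, table)

    def test_coincident_atoms_rejected(self, table):
        with pytest.raises(ValueError, match="coincident"):
            pair_energy(_atom(), _atom(), 0.0, table)


class TestIntermolecular:
    def test_vanishes_at_large_separation(self, toy, table):
        pose = toy.ligand.reference_coords + np.array([500.0, 0.0, 0.0])
        eb = intermolecular_energy(toy.receptor, pose, toy.ligand, table)
        for term in (eb.vdw, eb.hbond, eb.elec, eb.desolv):
            assert abs(term) < 1e-3

    def test_elec_linear_in_ligand_charges(self, toy, table):
        pose = toy.planted_pose()
        eb1 = intermolecular_energy(toy.receptor, pose, toy.ligand, table)
        doubled = make_toy_complex(7)  # independent copy to mutate
        for atom in doubled.ligand.atoms:
            atom.partial_charge *= 2.0
        eb2 = intermolecular_energy(doubled.receptor, pose, doubled.ligand, table)
        assert eb2.elec == pytest.approx(2.0 * eb1.elec, rel=1e-9)
        assert eb2.vdw == pytest.approx(eb1.vdw, rel=1e-9)
        assert eb2.hbond == pytest.approx(eb1.hbond, rel=1e-9)
        # desolvation shifts only through the |q|-dependent S_i term
        assert eb2.desolv != pytest.approx(eb1.desolv, rel=1e-12)


class TestInternal:
    def test_rigid_ligand_has_no_moving_pairs(self, toy_rigid, table):
        assert moving_pairs(toy_rigid.ligand) == []
        assert internal_energy(toy_rigid.ligand.reference_coords,
                               toy_rigid.ligand, table) == 0.0

    def test_pair_list_is_topological(self, table):
        toy = make_toy_complex(31, n_lig=8, n_torsions=3)
        pairs = moving_pairs(toy.ligand)
        assert pairs == naive_moving_pairs(toy.ligand)
        # independent of conformation: same list regardless of torsions
        g = toy.planted_genotype.copy()
        g.torsions[:] = 0.5
        assert moving_pairs(toy.ligand) == pairs


class TestBindingEnergy:
    def test_reference_pose_has_zero_strain(self, toy, table):
        eb = binding_energy(toy.receptor, toy.ligand, toy.planted_genotype,
                            toy.box, table)
        assert eb.internal_bound == pytest.approx(eb.internal_unbound, abs=1e-12)
        assert eb.total == pytest.approx(eb.intermolecular + eb.entropy, abs=1e-9)

    def test_rigid_ligand_no_entropy_no_internal(self, toy_rigid, table):
        eb = binding_energy(toy_rigid.receptor, toy_rigid.ligand,
                            toy_rigid.planted_genotype, toy_rigid.box, table)
        assert eb.entropy == 0.0
        assert eb.internal_bound == 0.0 and eb.internal_unbound == 0.0

    def test_breakdown_total_identity(self, toy, table, rng):
        g = random_genotype(toy.ligand.n_torsions, toy.box, rng)
        eb = binding_energy(toy.receptor, toy.ligand, g, toy.box, table)
        assert eb.total == pytest.approx(
            (eb.internal_bound - eb.internal_unbound) + eb.vdw + eb.hbond
            + eb.elec + eb.desolv + eb.entropy, abs=1e-9)

    def test_oracle_equivalence_on_random_complexes(self, table, rng):
        """Vectorized scorer == naive double loop to 1e-9 kcal/mol."""
        for k in range(20):
            n_lig = int(rng.integers(6, 9))
            toy = make_toy_complex(100 + k,
                                   n_rec=int(rng.integers(8, 40)),
                                   n_lig=n_lig,
                                   n_torsions=int(rng.integers(0, n_lig - 3)))
            g = random_genotype(toy.ligand.n_torsions, toy.box, rng)
            fast = binding_energy(toy.receptor, toy.ligand, g, toy.box, table)
            slow = naive_binding_energy(toy.receptor, toy.ligand, g, toy.box,
                                        table)
            # 1e-9 kcal/mol absolute; clashing random poses reach ~1e12
            # kcal/mol where only summation-order noise remains
            assert fast.total == pytest.approx(slow, abs=1e-9, rel=1e-12)

    def test_rigid_motion_invariance(self, toy, table, rng):
        """Rotating+translating receptor and pose together leaves every
        term unchanged (the score depends only on distances)."""
        from adhdock.conformation import quaternion_matrix
        model = EnergyModel(toy.receptor, toy.ligand, table)
        pose = toy.planted_pose()
        base = model.breakdown_from_coords(pose)
        q = rng.standard_normal(4)
        R = quaternion_matrix(q / np.linalg.norm(q))
        shift = rng.normal(size=3) * 10
        moved = make_toy_complex(7)
        for atom in moved.receptor.atoms:
            atom.coords = R @ atom.coords + shift
        model2 = EnergyModel(moved.receptor, moved.ligand, table)
        rotated = model2.breakdown_from_coords(pose @ R.T + shift)
        for key in ("vdw", "hbond", "elec", "desolv"):
            assert rotated.as_dict()[key] == pytest.approx(
                base.as_dict()[key], abs=1e-9)

    def test_term_knobs_are_independent(self, table):
        toy = make_toy_complex(17)
        for atom in toy.receptor.atoms + toy.ligand.atoms:
            atom.partial_charge = 0.0
        model = EnergyModel(toy.receptor, toy.ligand, table)
        eb = model.breakdown(toy.planted_genotype, toy.box)
        assert eb.elec == 0.0

        toy2 = make_toy_complex(17)
        model2 = EnergyModel(toy2.receptor, toy2.ligand, table)
        for arr in (model2._sv, model2._msv):
            arr[...] = 0.0
        eb2 = model2.breakdown(toy2.planted_genotype, toy2.box)
        assert eb2.desolv == 0.0
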