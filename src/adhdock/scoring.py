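"""Semi-empirical pairwise binding free-energy scoring.

The score of a pose is

    dG = (V_LL_bound - V_LL_unbound) + (V_PP_bound - V_PP_unbound)
         + (V_PL_bound - V_PL_unbound + dS_conf)

where each pairwise V sums four terms over atom pairs at distance r:

    vdW     W_vdw  * (A_ij / r^12 - B_ij / r^6)
    H-bond  W_hb   * E(t) * (C_ij / r^12 - D_ij / r^10)   (donor-acceptor pairs)
    elec    W_elec * 332.06363 * q_i q_j / (e(r) * r)
    desolv  W_sol  * (S_i V_j + S_j V_i) * exp(-r^2 / (2 sigma^2))

With a rigid receptor the P-P difference is identically zero and the unbound
P-L term vanishes (infinite separation).  The unbound ligand reference state
is the input-file conformation, so the L-L difference is the internal strain
of the docked pose.  The conformational entropy penalty is W_conf * T.

The 12-10 H-bond term here is purely distance-based (E(t) = 1): the
directional weight would need bonded-geometry inference that a pairwise
pose score does not otherwise require.

``EnergyModel`` precomputes all pair coefficients for one receptor/ligand
pair so that repeated evaluation inside the optimizers is a handful of
vectorized array operations; the module-level functions are the plain,
per-call API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .conformation import Genotype, Pose, SearchBox, build_pose
from .model_io import Atom, ForceFieldTable, Ligand, Receptor

__all__ = [
    "EnergyBreakdown",
    "PairEnergy",
    "pair_energy",
    "moving_pairs",
    "intermolecular_energy",
    "internal_energy",
    "binding_energy",
    "EnergyModel",
]


class PairEnergy(NamedTuple):
    vdw: float
    hbond: float
    elec: float
    desolv: float


@dataclass
class EnergyBreakdown:
    """Per-term energies in kcal/mol.  ``total`` is assembled as
    (internal_bound - internal_unbound) + vdw + hbond + elec + desolv
    + entropy; the receptor-receptor difference is identically zero for a
    rigid receptor and is not stored."""

    vdw: float
    hbond: float
    elec: float
    desolv: float
    internal_bound: float
    internal_unbound: float
    entropy: float

    @property
    def intermolecular(self) -> float:
        return self.vdw + self.hbond + self.elec + self.desolv

    @property
    def total(self) -> float:
        return (self.internal_bound - self.internal_unbound) + self.intermolecular \
            + self.entropy

    def as_dict(self) -> dict[str, float]:
        return {
            "vdw": self.vdw, "hbond": self.hbond, "elec": self.elec,
            "desolv": self.desolv, "internal_bound": self.internal_bound,
            "internal_unbound": self.internal_unbound, "entropy": self.entropy,
            "total": self.total,
        }


def pair_energy(atom_i: Atom, atom_j: Atom, r: float,
                table: ForceFieldTable) -> PairEnergy:
    """The four pairwise terms for one atom pair at distance ``r`` (A)."""
    if r <= 0:
        raise ValueError("coincident atoms: pair distance must be positive")
    a, b = table.vdw_coeffs(atom_i.autodock_type, atom_j.autodock_type)
    vdw = table.w_vdw * (a / r**12 - b / r**6)
    c, d = table.hbond_coeffs(atom_i.autodock_type, atom_j.autodock_type)
    hbond = table.w_hbond * (c / r**12 - d / r**10) if c or d else 0.0
    qq = atom_i.partial_charge * atom_j.partial_charge  # product first: exact i<->j symmetry
    elec = table.w_elec * table.COULOMB * qq / (table.epsilon(r) * r)
    desolv = (table.w_sol
              * (atom_i.solvation_param * atom_j.solvation_volume
                 + atom_j.solvation_param * atom_i.solvation_volume)
              * np.exp(-r * r / (2.0 * table.sigma**2)))
    return PairEnergy(float(vdw), float(hbond), float(elec), float(desolv))


def moving_pairs(ligand: Ligand) -> list[tuple[int, int]]:
    """Ligand atom pairs that contribute internal energy: pairs in different
    rigid groups separated by more than three bonds, each counted once.
    Topology only — the list does not depend on the genotype."""
    n = len(ligand)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in ligand.bonds:
        adj[i].append(j)
        adj[j].append(i)
    # BFS bond distances (small molecules: O(n^2) is fine)
    INF = n + 10
    dist = np.full((n, n), INF, dtype=int)
    for s in range(n):
        dist[s, s] = 0
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[s, v] == INF:
                        dist[s, v] = dist[s, u] + 1
                        nxt.append(v)
            queue = nxt
    group = ligand.torsion_tree.group_index(n)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if group[i] != group[j] and dist[i, j] > 3:
                pairs.append((i, j))
    return pairs


def intermolecular_energy(receptor: Receptor, pose: Pose | np.ndarray,
                          ligand: Ligand, table: ForceFieldTable) -> EnergyBreakdown:
    """Receptor-ligand interaction terms (bound P-L) for one pose; the
    internal and entropy fields of the returned breakdown are zero."""
    model = EnergyModel(receptor, ligand, table)
    coords = pose.coords if isinstance(pose, Pose) else np.asarray(pose, float)
    vdw, hb, el, ds = model.intermolecular_terms(coords)
    return EnergyBreakdown(vdw, hb, el, ds, 0.0, 0.0, 0.0)


def internal_energy(pose: Pose | np.ndarray, ligand: Ligand,
                    table: ForceFieldTable) -> float:
    """Ligand-ligand pairwise energy over the moving pairs (all four terms)."""
    model = EnergyModel.__new__(EnergyModel)
    model._setup_ligand_only(ligand, table)
    coords = pose.coords if isinstance(pose, Pose) else np.asarray(pose, float)
    return model.internal(coords)


def binding_energy(receptor: Receptor, ligand: Ligand, genotype: Genotype,
                   box: SearchBox, table: ForceFieldTable) -> EnergyBreakdown:
    """Full free-energy breakdown of the pose encoded by ``genotype``."""
    return EnergyModel(receptor, ligand, table).breakdown(genotype, box)


class EnergyModel:
    """Precomputed pairwise scorer for one receptor/ligand/force-field
    combination.

    Parameters
    ----------
    cutoff : float or None
        Optional interaction cutoff (A).  None (default) sums every pair
        exactly, which keeps the scorer equal to a naive double loop.
    """

    def __init__(self, receptor: Receptor, ligand: Ligand,
                 table: ForceFieldTable, cutoff: float | None = None) -> None:
        self.receptor = receptor
        self.table = table
        self.cutoff = cutoff
        table.assign(receptor.atoms)
        self._setup_ligand_only(ligand, table)
        rt, lt = receptor.types, ligand.types
        nr, nl = len(rt), len(lt)
        self._rc = receptor.coords
        A = np.empty((nr, nl)); B = np.empty((nr, nl))
        C = np.zeros((nr, nl)); D = np.zeros((nr, nl))
        for i, ti in enumerate(rt):
            for j, tj in enumerate(lt):
                A[i, j], B[i, j] = table.vdw_coeffs(ti, tj)
                C[i, j], D[i, j] = table.hbond_coeffs(ti, tj)
        self._A, self._B, self._C, self._D = A, B, C, D
        qr = np.array([a.partial_charge for a in receptor.atoms])
        ql = np.array([a.partial_charge for a in ligand.atoms])
        self._qq = table.COULOMB * np.outer(qr, ql)
        sr = np.array([a.solvation_param for a in receptor.atoms])
        vr = np.array([a.solvation_volume for a in receptor.atoms])
        sl = np.array([a.solvation_param for a in ligand.atoms])
        vl = np.array([a.solvation_volume for a in ligand.atoms])
        self._sv = np.outer(sr, vl) + np.outer(vr, sl)

    def _setup_ligand_only(self, ligand: Ligand, table: ForceFieldTable) -> None:
        self.ligand = ligand
        self.table = table
        table.assign(ligand.atoms)
        pairs = moving_pairs(ligand)
        self._mp = (np.array([p[0] for p in pairs], dtype=int),
                    np.array([p[1] for p in pairs], dtype=int))
        lt = ligand.types
        mA = np.empty(len(pairs)); mB = np.empty(len(pairs))
        mC = np.zeros(len(pairs)); mD = np.zeros(len(pairs))
        for k, (i, j) in enumerate(pairs):
            mA[k], mB[k] = table.vdw_coeffs(lt[i], lt[j])
            mC[k], mD[k] = table.hbond_coeffs(lt[i], lt[j])
        self._mA, self._mB, self._mC, self._mD = mA, mB, mC, mD
        q = ligand.charges
        s = np.array([a.solvation_param for a in ligand.atoms])
        v = np.array([a.solvation_volume for a in ligand.atoms])
        i, j = self._mp
        self._mqq = table.COULOMB * q[i] * q[j]
        self._msv = s[i] * v[j] + s[j] * v[i]
        self._internal_unbound = self.internal(ligand.reference_coords)
        self._entropy = table.w_conf * ligand.n_torsions

    # -- term evaluation ---------------------------------------------------

    def _terms(self, r, A, B, C, D, qq, sv):
        t = self.table
        if np.any(r <= 0):
            raise ValueError("coincident atoms: pair distance must be positive")
        inv_r6 = r**-6
        vdw = t.w_vdw * (A * inv_r6 * inv_r6 - B * inv_r6)
        hb = t.w_hbond * (C * inv_r6 * inv_r6 - D * inv_r6 * r**-4)
        el = t.w_elec * qq / (t.epsilon(r) * r)
        ds = t.w_sol * sv * np.exp(-r * r / (2.0 * t.sigma**2))
        if self.cutoff is not None:
            far = r > self.cutoff
            for term in (vdw, hb, el, ds):
                term[far] = 0.0
        return vdw, hb, el, ds

    def intermolecular_terms(self, coords: np.ndarray) -> tuple[float, float, float, float]:
        diff = self._rc[:, None, :] - coords[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        vdw, hb, el, ds = self._terms(r, self._A, self._B, self._C, self._D,
                                      self._qq, self._sv)
        return float(vdw.sum()), float(hb.sum()), float(el.sum()), float(ds.sum())

    def internal(self, coords: np.ndarray) -> float:
        i, j = self._mp
        if len(i) == 0:
            return 0.0
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        vdw, hb, el, ds = self._terms(r, self._mA, self._mB, self._mC, self._mD,
                                      self._mqq, self._msv)
        return float(vdw.sum() + hb.sum() + el.sum() + ds.sum())

    # -- pose-level API ----------------------------------------------------

    def breakdown_from_coords(self, coords: np.ndarray) -> EnergyBreakdown:
        vdw, hb, el, ds = self.intermolecular_terms(coords)
        return EnergyBreakdown(vdw, hb, el, ds, self.internal(coords),
                               self._internal_unbound, self._entropy)

    def breakdown(self, genotype: Genotype, box: SearchBox) -> EnergyBreakdown:
        pose = build_pose(self.ligand, genotype, box)
        return self.breakdown_from_coords(pose.coords)

    def score_genotype(self, genotype: Genotype, box: SearchBox) -> float:
        return self.breakdown(genotype, box).total

    def score_vector(self, vec: np.ndarray, box: SearchBox) -> float:
        g = Genotype.from_vector(vec, self.ligand.n_torsions)
        return self.score_genotype(g, box)
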