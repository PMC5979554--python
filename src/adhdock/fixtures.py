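"""Synthetic receptor-ligand systems with planted poses, plus brute-force
oracles and analytic benchmark landscapes.

The generated complex is a zigzag chain ligand cradled in a contoured
open groove: one half-ring (180 degrees, opening upward) of receptor atoms
arcs under each ligand atom at that pair's van-der-Waals equilibrium
distance, two cap atoms close the groove ends, and a linear charge ramp
along the groove axis is complementary to the ligand's own ramp.  The open
top lets randomly placed ligands slide into the groove (a closed cage would
have no reachable funnel), the per-atom contouring penalizes any
displacement or twist, and the charge ramp uniquely pins the chain
direction — a flipped or axially shifted chain anti-aligns the ramp
everywhere.  The planted genotype therefore sits in a unique, funnel-shaped
energy minimum, which is exactly the property a pose-recovery benchmark
needs.  (A plain hemispherical cup would leave the pose rotationally
degenerate about the pocket axis.)

All fixtures run through the production scoring path with the builtin
force-field table; nothing is special-cased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .conformation import Genotype, SearchBox, build_pose
from .model_io import (Atom, Branch, ForceFieldTable, Ligand, Receptor,
                       TorsionTree, load_forcefield, write_pdbqt_ligand,
                       write_pdbqt_receptor)
from .scoring import EnergyModel

__all__ = [
    "ToyComplex",
    "make_toy_complex",
    "toy_suite",
    "translation_grid_oracle",
    "analytic_landscape",
    "AnalyticProblem",
]

_BOND_STEP = 1.4   # chain step along the pocket axis, A
_ZIGZAG = 0.30     # chain zigzag amplitude, A
_ARC_DEG = 180.0   # angular span of the pocket rings (opening faces +z)
_LIG_TYPES = ("C", "OA", "C", "N")
_REC_TYPES = ("C", "N", "C", "OA", "HD", "C")
_CHARGE = 0.45     # magnitude of the ligand charge ramp endpoint, e


@dataclass
class ToyComplex:
    name: str
    receptor: Receptor
    ligand: Ligand
    planted_genotype: Genotype
    box: SearchBox

    def planted_pose(self) -> np.ndarray:
        return build_pose(self.ligand, self.planted_genotype, self.box).coords

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rec = out_dir / f"{self.name}_receptor.pdbqt"
        lig = out_dir / f"{self.name}_ligand.pdbqt"
        write_pdbqt_receptor(self.receptor, rec)
        write_pdbqt_ligand(self.ligand, lig)
        return rec, lig


def _chain_coords(n_lig: int) -> np.ndarray:
    i = np.arange(n_lig)
    x = _BOND_STEP * (i - (n_lig - 1) / 2.0)
    y = _ZIGZAG * (-1.0) ** i
    return np.column_stack([x, y, np.zeros(n_lig)])


def make_toy_complex(seed: int, n_rec: int = 38, n_lig: int = 6,
                     n_torsions: int = 2, out_dir: str | Path | None = None,
                     name: str | None = None) -> ToyComplex:
    """Build a deterministic toy complex with a planted low-energy pose.

    ``n_torsions`` rotatable bonds are laid out as a linear torsion tree at
    the chain tail (root = the first ``n_lig - n_torsions`` atoms).  The
    planted genotype is the identity (zero torsions, identity orientation)
    with the translation that reproduces the reference coordinates, so the
    planted pose equals the reference pose around which the pocket was
    built.  When ``out_dir`` is given, receptor and ligand PDBQT files are
    written there (same seed => byte-identical files).
    """
    if n_rec < 6 or n_lig < 3 or n_torsions < 0:
        raise ValueError("need n_rec >= 6, n_lig >= 3, n_torsions >= 0")
    # root needs >= 3 atoms; each branch must move an off-axis atom, so the
    # last rotatable bond sits one atom before the chain end
    root_size = n_lig if n_torsions == 0 else n_lig - n_torsions - 1
    if root_size < 3:
        raise ValueError("chain too short for the requested torsion count "
                         "(need n_lig >= n_torsions + 4)")
    rng = np.random.default_rng(seed)
    name = name or f"toy{seed}t{n_torsions}"
    table = load_forcefield("ad4")

    # ligand: zigzag chain, linear charge ramp +q .. -q along x
    coords = _chain_coords(n_lig)
    charges = _CHARGE * (1.0 - 2.0 * np.arange(n_lig) / (n_lig - 1))
    lig_types = [_LIG_TYPES[i % len(_LIG_TYPES)] for i in range(n_lig)]
    lig_atoms = [
        Atom(serial=i + 1, name=f"{lig_types[i]}{i + 1}",
             autodock_type=lig_types[i],
             coords=coords[i], partial_charge=float(charges[i]))
        for i in range(n_lig)
    ]
    branches = [
        Branch(axis=(root_size - 1 + t, root_size + t),
               moved=frozenset(range(root_size + t, n_lig)),
               parent=None if t == 0 else t - 1)
        for t in range(n_torsions)
    ]
    tree = TorsionTree(root_atoms=frozenset(range(root_size)), branches=branches)
    ligand = Ligand(atoms=lig_atoms, torsion_tree=tree, torsdof=n_torsions)

    # receptor: a staggered open half-ring under each ligand atom, at the
    # type pair's vdW equilibrium distance, plus two axial end caps
    arc = math.radians(_ARC_DEG)
    n_ring_atoms = n_rec - 2
    counts = np.full(n_lig, n_ring_atoms // n_lig)
    counts[: n_ring_atoms - counts.sum()] += 1
    rec_coords, rec_charges, rec_types = [], [], []
    ridx = 0
    for i in range(n_lig):
        for k in range(counts[i]):
            ang = -arc / 2.0 + arc * (k + 0.5) / counts[i]
            rtype = _REC_TYPES[ridx % len(_REC_TYPES)]
            ridx += 1
            req = table.types[rtype].radius + table.types[lig_types[i]].radius
            offset = np.array([0.0, req * math.sin(ang), -req * math.cos(ang)])
            rec_coords.append(coords[i] + offset)
            rec_charges.append(-charges[i])
            rec_types.append(rtype)
    span = _BOND_STEP * (n_lig - 1) / 2.0
    for sign, end in ((-1.0, 0), (1.0, n_lig - 1)):
        rtype = _REC_TYPES[ridx % len(_REC_TYPES)]
        ridx += 1
        req = table.types[rtype].radius + table.types[lig_types[end]].radius
        rec_coords.append(coords[end] + np.array([sign * req, 0.0, 0.0]))
        rec_charges.append(-charges[end])
        rec_types.append(rtype)
    rec_coords = np.array(rec_coords) + rng.uniform(-0.05, 0.05, (n_rec, 3))
    rec_atoms = [
        Atom(serial=i + 1, name=f"{rec_types[i]}{i + 1}",
             autodock_type=rec_types[i],
             coords=rec_coords[i], partial_charge=float(rec_charges[i]))
        for i in range(n_rec)
    ]
    receptor = Receptor(rec_atoms)

    box = SearchBox(center=np.zeros(3),
                    half_extent=np.array([span + 2.5, 4.0, 4.0]))
    root_centroid = coords[:root_size].mean(axis=0)
    planted = Genotype(translation=root_centroid - box.center,
                       orientation=np.array([1.0, 0.0, 0.0, 0.0]),
                       torsions=np.zeros(n_torsions))

    toy = ToyComplex(name=name, receptor=receptor, ligand=ligand,
                     planted_genotype=planted, box=box)
    if out_dir is not None:
        toy.write(out_dir)
    return toy


def toy_suite(seed: int = 0) -> list[ToyComplex]:
    """The five-complex benchmark suite: torsion counts 0..4, ligand sizes
    6-8 atoms, receptors 38-50 atoms."""
    specs = [(0, 6, 38), (1, 6, 38), (2, 7, 44), (3, 7, 44), (4, 8, 50)]
    return [
        make_toy_complex(seed * 1000 + t, n_rec=n_rec, n_lig=n_lig,
                         n_torsions=t, name=f"toyT{t}")
        for t, n_lig, n_rec in specs
    ]


def translation_grid_oracle(toy: ToyComplex, spacing: float = 0.5,
                            table: ForceFieldTable | None = None,
                            max_points: int = 1_000_000,
                            ) -> tuple[float, np.ndarray]:
    """Exhaustive minimum of the binding energy over a translation lattice
    spanning the box, with orientation and torsions fixed at the planted
    genotype.  Independent optimum estimate for acceptance testing.

    Returns (minimum energy, argmin translation)."""
    if spacing > 0.5:
        raise ValueError("oracle spacing must be <= 0.5 A")
    table = table if table is not None else load_forcefield("ad4")
    model = EnergyModel(toy.receptor, toy.ligand, table)

    axes = []
    for h in toy.box.half_extent:
        k = int(math.floor(h / spacing))
        axes.append(spacing * np.arange(-k, k + 1))
    n_pts = axes[0].size * axes[1].size * axes[2].size
    if n_pts > max_points:
        raise ValueError(f"grid too large: {n_pts} points > {max_points}")
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    base_g = toy.planted_genotype.copy()
    base_g.translation = np.zeros(3)
    base = build_pose(toy.ligand, base_g, toy.box).coords  # translation-free pose
    const = (model.internal(base) - model._internal_unbound + model._entropy)

    rc = toy.receptor.coords
    best_e, best_t = np.inf, grid[0]
    chunk = 256
    for s in range(0, len(grid), chunk):
        t = grid[s:s + chunk]
        pose = base[None, :, :] + t[:, None, :]
        diff = rc[None, :, None, :] - pose[:, None, :, :]
        r = np.sqrt(np.einsum("pijk,pijk->pij", diff, diff))
        vdw, hb, el, ds = model._terms(r, model._A, model._B, model._C,
                                       model._D, model._qq, model._sv)
        totals = (vdw + hb + el + ds).sum(axis=(1, 2)) + const
        i = int(np.argmin(totals))
        if totals[i] < best_e:
            best_e, best_t = float(totals[i]), t[i].copy()
    return best_e, best_t


def analytic_landscape(name: str, dim: int) -> Callable[[np.ndarray], float]:
    """Closed-form benchmark objective over raw gene vectors with global
    minimum 0 at the origin: ``sphere`` or ``rastrigin``."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if name == "sphere":
        return lambda v: float(np.sum(np.asarray(v, float) ** 2))
    if name == "rastrigin":
        def rastrigin(v: np.ndarray) -> float:
            v = np.asarray(v, float)
            return float(10.0 * dim + np.sum(v * v - 10.0 * np.cos(2 * np.pi * v)))
        return rastrigin
    raise ValueError(f"unknown landscape {name!r}; choose sphere or rastrigin")


class AnalyticProblem:
    """Benchmark objective as an optimizer problem: clamp-to-bounds repair,
    uniform sampling in [-bound, bound]^dim."""

    def __init__(self, name: str, dim: int, bound: float = 5.12) -> None:
        self.fn = analytic_landscape(name, dim)
        self.dim = dim
        self.bound = bound

    def score(self, vector: np.ndarray) -> float:
        return self.fn(vector)

    def repair(self, vector: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(vector, float), -self.bound, self.bound)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-self.bound, self.bound, size=self.dim)
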