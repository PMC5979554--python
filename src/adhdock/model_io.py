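"""PDBQT input/output, ligand torsion trees, and force-field parameter tables.

The PDBQT dialect is AutoDock's extension of PDB: each ATOM/HETATM record
carries a partial charge (Q) and an AutoDock atom type (T) in the two trailing
fields, and a flexible ligand additionally carries ROOT/ENDROOT and nested
BRANCH/ENDBRANCH blocks that define its rigid root and rotatable bonds.

Two parsing modes are supported.  The default, tolerant mode reads coordinates
from the fixed PDB columns (31-54) and the charge/type from the last two
whitespace-delimited fields, which survives the column drift common in
real-world files.  ``strict_columns=True`` insists on the canonical charge
(67-76) and type (78-79) columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "Receptor",
    "Branch",
    "TorsionTree",
    "Ligand",
    "ForceFieldTable",
    "PDBQTError",
    "ForceFieldError",
    "read_pdbqt_receptor",
    "read_pdbqt_ligand",
    "write_pdbqt_receptor",
    "write_pdbqt_ligand",
    "load_forcefield",
    "infer_bonds",
]


class PDBQTError(ValueError):
    """Raised on malformed PDBQT input."""


class ForceFieldError(ValueError):
    """Raised on missing or inconsistent force-field parameters."""


@dataclass
class Atom:
    """One atom: coordinates in Angstrom, partial charge in electrons.

    ``solvation_volume`` (V_i, A^3) and ``solvation_param`` (S_i,
    dimensionless) are the desolvation-term parameters; they are filled in
    from a :class:`ForceFieldTable` via :meth:`ForceFieldTable.assign`.
    """

    serial: int
    name: str
    autodock_type: str
    coords: np.ndarray
    partial_charge: float
    solvation_volume: float = 0.0
    solvation_param: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise PDBQTError(f"atom {self.serial}: non-finite or malformed coordinates")


@dataclass
class Receptor:
    """A rigid receptor: an ordered atom collection with no internal DOFs."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise PDBQTError("empty receptor")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def types(self) -> list[str]:
        return [a.autodock_type for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Branch:
    """One rotatable bond: axis (parent_atom, child_atom) plus the atom
    indices it moves (the child-axis atom and everything distal, including
    nested branches).  ``parent`` indexes the enclosing branch, or None when
    the branch hangs off the rigid root."""

    axis: tuple[int, int]
    moved: frozenset[int]
    parent: int | None = None


@dataclass
class TorsionTree:
    root_atoms: frozenset[int]
    branches: list[Branch]

    def rigid_groups(self) -> list[frozenset[int]]:
        """Partition of atom indices into rigid groups: the root, then one
        group per branch (its moved set minus all nested branches')."""
        groups = [set(self.root_atoms)]
        for i, br in enumerate(self.branches):
            g = set(br.moved)
            for other in self.branches:
                if other is not br and other.moved < br.moved:
                    g -= other.moved
            groups.append(g)
        return [frozenset(g) for g in groups]

    def group_index(self, n_atoms: int) -> np.ndarray:
        idx = np.full(n_atoms, -1, dtype=int)
        for gi, group in enumerate(self.rigid_groups()):
            for a in group:
                idx[a] = gi
        return idx


@dataclass
class Ligand:
    """A flexible ligand: atoms, their input-file (reference) coordinates,
    and the torsion tree. ``n_torsions`` is T, the number of rotatable bonds."""

    atoms: list[Atom]
    torsion_tree: TorsionTree
    torsdof: int | None = None
    bonds: list[tuple[int, int]] = field(default_factory=list)
    reference_coords: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise PDBQTError("empty ligand")
        if self.reference_coords is None:
            self.reference_coords = np.array([a.coords for a in self.atoms])
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if not self.bonds:
            self.bonds = infer_bonds(self.reference_coords, self.types)
        self._check_tree()

    def _check_tree(self) -> None:
        tree = self.torsion_tree
        n = len(self.atoms)
        covered: set[int] = set()
        for g in tree.rigid_groups():
            if covered & g:
                raise PDBQTError("torsion tree rigid groups overlap")
            covered |= g
        if covered != set(range(n)):
            raise PDBQTError("torsion tree does not cover every atom exactly once")

    @property
    def n_torsions(self) -> int:
        return len(self.torsion_tree.branches)

    @property
    def types(self) -> list[str]:
        return [a.autodock_type for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask over atoms excluding hydrogens (types H, HD, HS)."""
        return np.array([not t.upper().startswith("H") for t in self.types])

    def __len__(self) -> int:
        return len(self.atoms)


# --------------------------------------------------------------------------
# bond inference

_COVALENT_RADII = {"H": 0.37, "C": 0.77, "A": 0.77, "N": 0.75, "O": 0.73, "S": 1.02}


def _covalent_radius(autodock_type: str) -> float:
    return _COVALENT_RADII.get(autodock_type[0].upper(), 0.77)


def infer_bonds(coords: np.ndarray, types: list[str]) -> list[tuple[int, int]]:
    """Distance-based covalent bond detection: i-j bonded when
    r_ij <= 1.3 * (cov_i + cov_j).  Adequate for prepared small molecules."""
    coords = np.asarray(coords, float)
    n = len(coords)
    radii = np.array([_covalent_radius(t) for t in types])
    bonds = []
    for i in range(n):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        cut = 1.3 * (radii[i] + radii[i + 1 :])
        for off in np.nonzero(d <= cut)[0]:
            bonds.append((i, int(i + 1 + off)))
    return bonds


# --------------------------------------------------------------------------
# PDBQT parsing

def _parse_atom_line(line: str, lineno: int, strict_columns: bool) -> Atom:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBQTError(f"line {lineno}: malformed coordinate columns") from exc
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = lineno
    name = line[12:16].strip() or "X"
    if strict_columns:
        try:
            charge = float(line[66:76])
            atype = line[77:79].strip()
        except (ValueError, IndexError) as exc:
            raise PDBQTError(f"line {lineno}: malformed charge/type columns") from exc
    else:
        fields = line.split()
        if len(fields) < 2:
            raise PDBQTError(f"line {lineno}: too few fields for charge/type")
        try:
            charge = float(fields[-2])
        except ValueError as exc:
            raise PDBQTError(f"line {lineno}: unreadable partial charge") from exc
        atype = fields[-1]
    if not atype:
        raise PDBQTError(f"line {lineno}: missing atom type")
    return Atom(serial=serial, name=name, autodock_type=atype,
                coords=np.array([x, y, z]), partial_charge=charge)


def read_pdbqt_receptor(path: str | Path, strict_columns: bool = False,
                        table: "ForceFieldTable | None" = None) -> Receptor:
    """Read a rigid receptor: every ATOM/HETATM record of the first model,
    in file order.  REMARK/MODEL wrappers are ignored; parsing stops at
    ENDMDL.  When ``table`` is given, atom types are validated against it and
    solvation parameters are assigned."""
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                atoms.append(_parse_atom_line(line, lineno, strict_columns))
            elif rec == "ENDMDL":
                break
    if not atoms:
        raise PDBQTError(f"empty receptor: no ATOM/HETATM records in {path}")
    receptor = Receptor(atoms)
    if table is not None:
        table.assign(receptor.atoms)
    return receptor


def read_pdbqt_ligand(path: str | Path, strict_columns: bool = False,
                      table: "ForceFieldTable | None" = None) -> Ligand:
    """Read a flexible ligand with its ROOT/BRANCH torsion tree.

    Atoms are indexed 0-based in file order; BRANCH axis atoms are resolved
    through their serial numbers.  n_torsions equals the number of BRANCH
    records."""
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    root_atoms: set[int] = set()
    branches: list[Branch] = []
    # stack entries: (branch_index | None for root, axis serials, moved set)
    stack: list[tuple[int | None, tuple[int, int] | None, set[int]]] = []
    in_root = False
    seen_root = False
    torsdof: int | None = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split(None, 1)[0] if line.strip() else ""
            if rec in ("ATOM", "HETATM"):
                atom = _parse_atom_line(line, lineno, strict_columns)
                idx = len(atoms)
                atoms.append(atom)
                serial_to_index.setdefault(atom.serial, idx)
                if stack:
                    for _, _, moved in stack:
                        moved.add(idx)
                elif in_root:
                    root_atoms.add(idx)
                else:
                    root_atoms.add(idx)  # atoms outside any block: rigid
            elif rec == "ROOT":
                in_root = True
                seen_root = True
            elif rec == "ENDROOT":
                in_root = False
            elif rec == "BRANCH":
                parts = line.split()
                if len(parts) < 3:
                    raise PDBQTError(f"line {lineno}: BRANCH needs two atom serials")
                a_serial, b_serial = int(parts[1]), int(parts[2])
                parent = stack[-1][0] if stack else None
                branch_index = len(branches)
                branches.append(Branch(axis=(a_serial, b_serial),
                                       moved=frozenset(), parent=parent))
                stack.append((branch_index, (a_serial, b_serial), set()))
            elif rec == "ENDBRANCH":
                if not stack:
                    raise PDBQTError(f"line {lineno}: ENDBRANCH without open BRANCH")
                branch_index, axis, moved = stack.pop()
                assert branch_index is not None and axis is not None
                a_serial, b_serial = axis
                for s in (a_serial, b_serial):
                    if s not in serial_to_index:
                        raise PDBQTError(
                            f"line {lineno}: branch axis atom serial {s} not found")
                branches[branch_index] = Branch(
                    axis=(serial_to_index[a_serial], serial_to_index[b_serial]),
                    moved=frozenset(moved),
                    parent=branches[branch_index].parent,
                )
            elif rec == "TORSDOF":
                torsdof = int(line.split()[1])
            elif rec == "ENDMDL":
                break

    if stack:
        raise PDBQTError("unmatched BRANCH nesting: file ended with open BRANCH blocks")
    if not atoms:
        raise PDBQTError(f"empty ligand: no ATOM/HETATM records in {path}")
    if not seen_root and branches:
        raise PDBQTError("BRANCH records without a ROOT block")

    tree = TorsionTree(root_atoms=frozenset(root_atoms), branches=branches)
    ligand = Ligand(atoms=atoms, torsion_tree=tree, torsdof=torsdof)
    if table is not None:
        table.assign(ligand.atoms)
    return ligand


# --------------------------------------------------------------------------
# PDBQT writing

def _format_atom(atom: Atom, serial: int) -> str:
    name = atom.name[:4]
    return (f"ATOM  {serial:>5d} {name:<4s} LIG A   1    "
            f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}    {atom.partial_charge:6.3f} "
            f"{atom.autodock_type:<2s}")


def write_pdbqt_receptor(receptor: Receptor, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, atom in enumerate(receptor.atoms, start=1):
            fh.write(_format_atom(atom, i) + "\n")
        fh.write("TER\n")


def write_pdbqt_ligand(ligand: Ligand, path: str | Path) -> None:
    """Write a ligand with its nested ROOT/BRANCH blocks reconstructed.

    Atoms keep their 0-based order (re-serialized from 1); each branch block
    lists the branch's own rigid-group atoms before its child branches."""
    tree = ligand.torsion_tree
    groups = tree.rigid_groups()  # [root, branch0, branch1, ...]
    children: dict[int | None, list[int]] = {}
    for bi, br in enumerate(tree.branches):
        children.setdefault(br.parent, []).append(bi)

    lines: list[str] = []

    def serial(idx: int) -> int:
        return idx + 1

    def emit_branch(bi: int) -> None:
        br = tree.branches[bi]
        a, b = br.axis
        lines.append(f"BRANCH {serial(a):>3d} {serial(b):>3d}")
        for idx in sorted(groups[bi + 1]):
            lines.append(_format_atom(ligand.atoms[idx], serial(idx)))
        for child in children.get(bi, []):
            emit_branch(child)
        lines.append(f"ENDBRANCH {serial(a):>3d} {serial(b):>3d}")

    lines.append("ROOT")
    for idx in sorted(tree.root_atoms):
        lines.append(_format_atom(ligand.atoms[idx], serial(idx)))
    lines.append("ENDROOT")
    for bi in children.get(None, []):
        emit_branch(bi)
    torsdof = ligand.torsdof if ligand.torsdof is not None else ligand.n_torsions
    lines.append(f"TORSDOF {torsdof}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# force field

@dataclass(frozen=True)
class TypeParams:
    radius: float          # per-type vdW radius, A (pair distance = r_i + r_j)
    well_depth: float      # kcal/mol
    solvation_param: float
    volume: float          # A^3
    hbond: int             # 0 none, 1 donor H, 2 acceptor
    hb_radius: float = 0.0
    hb_depth: float = 0.0


class ForceFieldTable:
    """Per-type parameters plus global weights of the pairwise free-energy
    model.  Pair coefficients follow the Lorentz/geometric combination:

        R_ij = r_i + r_j,  eps_ij = sqrt(eps_i eps_j)
        A_ij = eps_ij R_ij^12,   B_ij = 2 eps_ij R_ij^6          (12-6)
        C_ij = 5 eps_hb R_hb^12, D_ij = 6 eps_hb R_hb^10         (12-10)

    so the 12-6 minimum sits at R_ij with depth eps_ij, and the 12-10
    minimum at R_hb with depth eps_hb (taken from the acceptor type).
    The dielectric e(r) is the Mehler-Solmajer sigmoid by default; set
    ``dielectric`` to a positive number for a constant-dielectric model.
    """

    MEHLER_A = -8.5525
    MEHLER_LAMBDA = 0.003627
    MEHLER_K = 7.7839
    MEHLER_EPS0 = 78.4
    COULOMB = 332.06363  # (e^2/A) -> kcal/mol

    def __init__(self, types: dict[str, TypeParams], weights: dict[str, float],
                 sigma: float = 3.5, qsolpar: float = 0.01097,
                 dielectric: float | str = "mehler") -> None:
        if sigma <= 0:
            raise ForceFieldError("desolvation width sigma must be positive")
        self.types = dict(types)
        self.w_vdw = weights["vdw"]
        self.w_hbond = weights["hbond"]
        self.w_elec = weights["elec"]
        self.w_sol = weights["sol"]
        self.w_conf = weights["conf"]
        self.sigma = sigma
        self.qsolpar = qsolpar
        self.dielectric = dielectric

    def known_types(self) -> list[str]:
        return sorted(self.types)

    def _get(self, t: str) -> TypeParams:
        try:
            return self.types[t]
        except KeyError:
            raise ForceFieldError(
                f"unknown atom type {t!r}; known types: {', '.join(self.known_types())}"
            ) from None

    def vdw_coeffs(self, ti: str, tj: str) -> tuple[float, float]:
        """(A_ij, B_ij) of the 12-6 dispersion/repulsion term."""
        pi, pj = self._get(ti), self._get(tj)
        rij = pi.radius + pj.radius
        eps = math.sqrt(pi.well_depth * pj.well_depth)
        return eps * rij**12, 2.0 * eps * rij**6

    def is_hbond_pair(self, ti: str, tj: str) -> bool:
        pi, pj = self._get(ti), self._get(tj)
        return (pi.hbond == 1 and pj.hbond == 2) or (pi.hbond == 2 and pj.hbond == 1)

    def hbond_coeffs(self, ti: str, tj: str) -> tuple[float, float]:
        """(C_ij, D_ij) of the 12-10 hydrogen-bond term; (0, 0) for pairs
        that are not donor-acceptor."""
        if not self.is_hbond_pair(ti, tj):
            return 0.0, 0.0
        pi, pj = self._get(ti), self._get(tj)
        acc = pi if pi.hbond == 2 else pj
        return 5.0 * acc.hb_depth * acc.hb_radius**12, 6.0 * acc.hb_depth * acc.hb_radius**10

    def epsilon(self, r):
        """Distance-dependent dielectric e(r); vectorized over r."""
        if self.dielectric != "mehler":
            return np.full_like(np.asarray(r, float), float(self.dielectric)) \
                if np.ndim(r) else float(self.dielectric)
        r = np.asarray(r, float)
        B = self.MEHLER_EPS0 - self.MEHLER_A
        out = self.MEHLER_A + B / (1.0 + self.MEHLER_K
                                   * np.exp(-self.MEHLER_LAMBDA * B * r))
        return out if out.ndim else float(out)

    def assign(self, atoms: list[Atom]) -> None:
        """Populate solvation_volume and solvation_param from the table.

        S_i = S_type + qsolpar * |q_i|, the charge-dependent atomic solvation
        parameter of the free-energy model."""
        for atom in atoms:
            p = self._get(atom.autodock_type)
            atom.solvation_volume = p.volume
            atom.solvation_param = p.solvation_param + self.qsolpar * abs(atom.partial_charge)


def load_forcefield(source: str | Path = "ad4") -> ForceFieldTable:
    """Load a force-field table from a parameter file, or the builtin
    AutoDock-4.2-default table via the name ``"ad4"``."""
    if source == "ad4":
        text = resources.files("adhdock.data").joinpath("ad4_parameters.dat").read_text()
    else:
        text = Path(source).read_text()
    types: dict[str, TypeParams] = {}
    weights: dict[str, float] = {}
    sigma, qsolpar = 3.5, 0.01097
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "weight":
            weights[parts[1]] = float(parts[2])
        elif parts[0] == "sigma":
            sigma = float(parts[1])
        elif parts[0] == "qsolpar":
            qsolpar = float(parts[1])
        else:
            if len(parts) < 6:
                raise ForceFieldError(f"malformed type record: {line!r}")
            hb_r = float(parts[6]) if len(parts) > 6 else 0.0
            hb_d = float(parts[7]) if len(parts) > 7 else 0.0
            types[parts[0]] = TypeParams(
                radius=float(parts[1]), well_depth=float(parts[2]),
                solvation_param=float(parts[3]), volume=float(parts[4]),
                hbond=int(parts[5]), hb_radius=hb_r, hb_depth=hb_d)
    missing = {"vdw", "hbond", "elec", "sol", "conf"} - set(weights)
    if missing:
        raise ForceFieldError(f"missing term weights: {sorted(missing)}")
    return ForceFieldTable(types, weights, sigma=sigma, qsolpar=qsolpar)
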