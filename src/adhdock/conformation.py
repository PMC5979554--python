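"""Genotype <-> pose kinematics.

A docking genotype has 3 translation genes (Angstrom, relative to the search
box center), a 4-component orientation quaternion (w, x, y, z), and T torsion
angles in radians, one per rotatable bond, wrapped to (-pi, pi].  The
phenotype (pose) is built from the ligand's reference coordinates by applying
torsions branch-by-branch (parents before children), then rotating the whole
ligand about its rigid-root centroid, then translating so the root centroid
lands at ``box.center + translation``.

Optimizers treat the genotype as a raw real vector of length 7 + T
(translation, quaternion, torsions, in that order); ``repair_vector`` restores
validity after vector arithmetic (clamp, renormalize, wrap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import Ligand

__all__ = [
    "Genotype",
    "SearchBox",
    "Pose",
    "normalize_orientation",
    "build_pose",
    "rmsd",
    "random_genotype",
    "repair_genotype",
    "repair_vector",
    "quaternion_matrix",
]


@dataclass
class SearchBox:
    """Axis-aligned search box: center and half extents, Angstrom."""

    center: np.ndarray
    half_extent: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.half_extent = np.asarray(self.half_extent, float)
        if np.any(self.half_extent <= 0):
            raise ValueError("box half extents must be strictly positive")

    def contains(self, point: np.ndarray) -> bool:
        d = np.abs(np.asarray(point, float) - self.center)
        return bool(np.all(d <= self.half_extent + 1e-12))


@dataclass
class Genotype:
    translation: np.ndarray   # (3,) A
    orientation: np.ndarray   # (4,) quaternion w,x,y,z
    torsions: np.ndarray      # (T,) rad

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, float).reshape(3)
        self.orientation = np.asarray(self.orientation, float).reshape(4)
        self.torsions = np.atleast_1d(np.asarray(self.torsions, float))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.orientation, self.torsions])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_torsions: int) -> "Genotype":
        vec = np.asarray(vec, float)
        if vec.shape != (7 + n_torsions,):
            raise ValueError(f"genotype vector must have length {7 + n_torsions}")
        return cls(vec[:3], vec[3:7], vec[7:])

    def copy(self) -> "Genotype":
        return Genotype(self.translation.copy(), self.orientation.copy(),
                        self.torsions.copy())


@dataclass
class Pose:
    """Ligand Cartesian coordinates, same atom order as the Ligand."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)


def normalize_orientation(genotype: Genotype) -> Genotype:
    """Return a copy whose quaternion has unit norm (direction preserved)."""
    q = genotype.orientation
    norm = float(np.linalg.norm(q))
    if norm <= 1e-300:
        raise ValueError("degenerate orientation: zero quaternion")
    out = genotype.copy()
    out.orientation = q / norm
    return out


def quaternion_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a (w, x, y, z) quaternion (normalized internally)."""
    w, x, y, z = np.asarray(q, float) / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _axis_rotation(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                   angle: float) -> np.ndarray:
    """Rodrigues rotation of ``points`` about the line through ``origin``
    with direction ``axis`` by ``angle`` radians."""
    u = axis / np.linalg.norm(axis)
    p = points - origin
    c, s = np.cos(angle), np.sin(angle)
    cross = np.empty_like(p)  # u x p, written out (np.cross is slow here)
    cross[:, 0] = u[1] * p[:, 2] - u[2] * p[:, 1]
    cross[:, 1] = u[2] * p[:, 0] - u[0] * p[:, 2]
    cross[:, 2] = u[0] * p[:, 1] - u[1] * p[:, 0]
    rotated = p * c + cross * s + np.outer(p @ u, u) * (1 - c)
    return rotated + origin


def build_pose(ligand: Ligand, genotype: Genotype, box: SearchBox) -> Pose:
    """Map a genotype to ligand coordinates.

    Order of operations: torsions (internal, parents before children), then
    the global quaternion rotation about the rigid-root centroid, then
    translation of the root centroid to ``box.center + translation``.
    """
    if len(genotype.torsions) != ligand.n_torsions:
        raise ValueError(
            f"genotype has {len(genotype.torsions)} torsions, "
            f"ligand needs {ligand.n_torsions}")
    coords = ligand.reference_coords.copy()
    tree = ligand.torsion_tree
    for bi, branch in enumerate(tree.branches):  # file order is parent-first
        angle = float(genotype.torsions[bi])
        if angle == 0.0 or not branch.moved:
            continue
        a, b = branch.axis
        moved = sorted(branch.moved)
        coords[moved] = _axis_rotation(coords[moved], coords[a],
                                       coords[b] - coords[a], angle)
    root = sorted(tree.root_atoms)
    centroid = coords[root].mean(axis=0)
    R = quaternion_matrix(genotype.orientation)
    coords = (coords - centroid) @ R.T + box.center + genotype.translation
    return Pose(coords)


def rmsd(pose_a: Pose | np.ndarray, pose_b: Pose | np.ndarray,
         atom_types: list[str] | None = None, heavy_only: bool = True) -> float:
    """Index-matched RMSD between two poses, Angstrom.

    No superposition and no symmetry correction: atom i is compared with
    atom i.  With ``heavy_only`` (the default when types are available),
    hydrogens (types starting with H) are excluded.
    """
    a = pose_a.coords if isinstance(pose_a, Pose) else np.asarray(pose_a, float)
    b = pose_b.coords if isinstance(pose_b, Pose) else np.asarray(pose_b, float)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    if heavy_only and atom_types is not None:
        mask = np.array([not t.upper().startswith("H") for t in atom_types])
        if not mask.any():
            raise ValueError("no heavy atoms to compare")
        a, b = a[mask], b[mask]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def random_genotype(n_torsions: int, box: SearchBox,
                    rng: np.random.Generator) -> Genotype:
    """Uniform random genotype: translation uniform in the box, orientation
    uniform on the unit 3-sphere (normalized Gaussian 4-vector), torsions
    uniform in (-pi, pi]."""
    t = rng.uniform(-box.half_extent, box.half_extent)
    q = rng.standard_normal(4)
    norm = np.linalg.norm(q)
    while norm < 1e-12:  # astronomically rare; keeps the sampler total
        q = rng.standard_normal(4)
        norm = np.linalg.norm(q)
    tor = _wrap_angles(rng.uniform(-np.pi, np.pi, size=n_torsions))
    return Genotype(t, q / norm, tor)


def _wrap_angles(angles: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]; the boundary maps to +pi."""
    wrapped = np.remainder(-np.asarray(angles, float) + np.pi, 2 * np.pi)
    return -(wrapped - np.pi)


def repair_genotype(genotype: Genotype, box: SearchBox) -> Genotype:
    """Clamp translation into the box, renormalize the quaternion, wrap
    torsions to (-pi, pi].  Idempotent; a numerically zero quaternion is
    reset to identity."""
    out = genotype.copy()
    out.translation = np.clip(out.translation, -box.half_extent, box.half_extent)
    norm = float(np.linalg.norm(out.orientation))
    out.orientation = (np.array([1.0, 0.0, 0.0, 0.0]) if norm < 1e-12
                       else out.orientation / norm)
    out.torsions = _wrap_angles(out.torsions)
    return out


def repair_vector(vec: np.ndarray, box: SearchBox) -> np.ndarray:
    """Vector-space form of :func:`repair_genotype` for the optimizers."""
    vec = np.asarray(vec, float).copy()
    vec[:3] = np.clip(vec[:3], -box.half_extent, box.half_extent)
    norm = float(np.linalg.norm(vec[3:7]))
    if norm < 1e-12:
        vec[3:7] = (1.0, 0.0, 0.0, 0.0)
    else:
        vec[3:7] /= norm
    vec[7:] = _wrap_angles(vec[7:])
    return vec
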