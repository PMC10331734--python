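"""Internal-coordinate measurement and rigid-body superposition.

Distances in Angstrom, angles in degrees.  Dihedrals follow the right-hand
(IUPAC) sign convention about the j-k axis and lie in (-180, 180]; impropers
are the dihedral i-j-k-l with the *third* atom central (AMBER convention),
so a planar trigonal center reads 180 degrees.

Superposition is the least-squares optimal proper rotation (Kabsch, via
SVD with determinant sign correction): reflections are never returned, so
molecular chirality is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_model import Structure

__all__ = [
    "GeometryError",
    "Superposition",
    "bond_length",
    "bond_angle",
    "dihedral",
    "improper",
    "kabsch_superpose",
    "rmsd_after_superposition",
    "charge_mue",
]


class GeometryError(ValueError):
    """Degenerate geometry (collinear arms, too few atoms, ...)."""


def _coords(structure: Structure, frame: int, *idx: int) -> list[np.ndarray]:
    if len(set(idx)) != len(idx):
        raise ValueError(f"indices must be distinct, got {idx}")
    xyz = structure.coords(frame)
    for i in idx:
        if not 0 <= i < structure.n_atoms:
            raise IndexError(f"atom index {i} out of range")
    return [xyz[i] for i in idx]


def bond_length(structure: Structure, i: int, j: int, frame: int = 0) -> float:
    a, b = _coords(structure, frame, i, j)
    return float(np.linalg.norm(a - b))


def bond_angle(structure: Structure, i: int, j: int, k: int, frame: int = 0) -> float:
    """Angle i-j-k at vertex j, degrees."""
    a, b, c = _coords(structure, frame, i, j, k)
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("zero-length angle arm")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(structure: Structure, i: int, j: int, k: int, l: int,
             frame: int = 0) -> float:
    """Torsion angle about the j-k bond, degrees in (-180, 180]."""
    p0, p1, p2, p3 = _coords(structure, frame, i, j, k, l)
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or norm_b2 < 1e-12:
        raise GeometryError("collinear atoms: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / norm_b2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def improper(structure: Structure, i: int, j: int, k: int, l: int,
             frame: int = 0) -> float:
    """Out-of-plane (improper) dihedral i-j-k-l with k the central atom.

    Computed as the torsion about the j-k axis; a planar arrangement
    gives 180 degrees.
    """
    return dihedral(structure, i, j, k, l, frame)


@dataclass
class Superposition:
    """Optimal rigid transform ``mov -> ref`` over ``atom_subset``."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, A
    rmsd: float  # A, over the subset after transform
    atom_subset: tuple[int, ...]

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(ref: Structure, mov: Structure,
                     subset: list[int] | None = None,
                     ref_frame: int = 0, mov_frame: int = 0) -> Superposition:
    """Least-squares optimal proper rigid alignment of ``mov`` onto ``ref``.

    Needs >= 3 non-collinear subset atoms; raises :class:`GeometryError`
    otherwise.  RMSD is computed over the subset after transformation.
    """
    if subset is None:
        if ref.n_atoms != mov.n_atoms:
            raise ValueError("structures differ in atom count; give a subset map")
        subset = list(range(ref.n_atoms))
    subset = list(subset)
    if len(subset) < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    a = ref.coords(ref_frame)[subset]
    b = mov.coords(mov_frame)[subset]

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity check: rank of the centered reference cloud
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2 or \
            np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) atom subset")

    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd,
                         atom_subset=tuple(subset))


def rmsd_after_superposition(ref: Structure, mov: Structure,
                             align_subset: list[int],
                             rmsd_subset: list[int] | None = None,
                             ref_frame: int = 0, mov_frame: int = 0) -> float:
    """RMSD over ``rmsd_subset`` after aligning on ``align_subset``.

    The alignment atoms and the scored atoms need not coincide (align on
    the conjugated rings, score over all heavy atoms, for instance).
    """
    sup = kabsch_superpose(ref, mov, align_subset, ref_frame, mov_frame)
    if rmsd_subset is None:
        rmsd_subset = list(range(ref.n_atoms))
    a = ref.coords(ref_frame)[list(rmsd_subset)]
    b = sup.apply(mov.coords(mov_frame)[list(rmsd_subset)])
    return float(np.sqrt(np.mean(np.sum((b - a) ** 2, axis=1))))


def charge_mue(q_a, q_b) -> float:
    """Mean unsigned error between two charge sets (elementary charge)."""
    qa = np.asarray(q_a, dtype=float)
    qb = np.asarray(q_b, dtype=float)
    if qa.shape != qb.shape:
        raise ValueError(f"charge lists differ in length: {qa.shape} vs {qb.shape}")
    if qa.size == 0:
        raise ValueError("empty charge lists")
    return float(np.mean(np.abs(qa - qb)))
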