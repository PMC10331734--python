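"""Deterministic, seedable fixture generators.

Every generator is a pure function of its inputs and a seed: the same seed
reproduces bit-identical output.  The fixtures emulate the statistical and
geometric structure the analysis modules assume — ESP grids generated from
known point charges (so charge recovery can be tested against the
generating truth), small capped-residue topologies with rotationally
equivalent hydrogens, jittered geometries, and stationary autocorrelated
angle series standing in for MD fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_model import Atom, Structure
from .resp import EspGrid, esp_from_point_charges

__all__ = [
    "FixtureSpec",
    "gen_esp_fixture",
    "gen_capped_topology",
    "gen_ou_angle_series",
    "gen_perturbed_structure",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the ESP-grid fixture generator.

    Shell radii default to 1.4-2.0x the per-atom nominal radius, echoing
    the standard ESP-grid practice of sampling several scaled van der
    Waals surfaces.
    """

    seed: int = 0
    grid_shells: tuple[float, ...] = (1.4, 1.6, 1.8, 2.0)
    points_per_shell: int = 40
    noise_sd: float = 0.0
    nominal_radius: float = 2.5  # Bohr
    autocorrelation: float = 0.0

    def __post_init__(self) -> None:
        if any(m <= 1.0 for m in self.grid_shells):
            raise ValueError("shell radius multipliers must be > 1")
        if not 0.0 <= self.autocorrelation < 1.0:
            raise ValueError("autocorrelation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_esp_fixture(charges, positions, spec: FixtureSpec) -> EspGrid:
    """ESP grid generated from known point charges.

    Grid points sit on shells at ``spec.grid_shells`` multiples of the
    nominal radius around each atom (uniform random directions, seeded);
    points that land within the nominal radius of any other atom are
    dropped.  Potentials are the exact Coulomb sums, plus optional
    Gaussian noise of SD ``spec.noise_sd``.  Positions in Bohr.
    """
    rng = np.random.default_rng(spec.seed)
    charges = np.asarray(charges, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    pts: list[np.ndarray] = []
    for i, center in enumerate(positions):
        for mult in spec.grid_shells:
            dirs = _uniform_directions(rng, spec.points_per_shell)
            shell = center + dirs * mult * spec.nominal_radius
            dist = np.linalg.norm(
                shell[:, None, :] - positions[None, :, :], axis=2
            )
            keep = np.all(dist >= spec.nominal_radius * 0.999, axis=1)
            # own-shell distances equal mult*nominal > nominal, so every
            # point survives unless it dips inside another atom's sphere
            pts.append(shell[keep])
    grid_points = np.vstack(pts)
    potentials = esp_from_point_charges(charges, positions, grid_points)
    if spec.noise_sd > 0:
        potentials = potentials + rng.normal(0.0, spec.noise_sd,
                                             size=potentials.shape)
    return EspGrid(atom_positions=positions, grid_points=grid_points,
                   potentials=potentials)


def gen_capped_topology(n_sidechain_atoms: int = 1,
                        with_amide_h: bool = True,
                        seed: int = 0) -> Structure:
    """ACE/NME-capped residue fragment with full role/terminal annotations.

    Layout: ACE cap (methyl CAY/HY1-3, carbonyl CY=OY), central fragment
    (amide N1 with optional H1, alpha CA1/HA1, a methylene CB1/HB1-2 plus
    ``n_sidechain_atoms - 1`` bare chain carbons, C-terminal carbonyl
    C3=O3), NME cap (NT/HNT, methyl CAT/HT1-3).  Coordinates are a jittered
    extended chain — chemically plausible connectivity, not an optimized
    geometry.  Different seeds move the coordinates, never the topology.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    pos = np.zeros(3)
    step = np.array([1.45, 0.0, 0.0])

    def add(name: str, element: str, role: str, flag: str = "none",
            offset: np.ndarray | None = None) -> int:
        nonlocal pos
        if offset is None:
            pos = pos + step + rng.normal(0.0, 0.12, 3)
            where = pos
        else:
            where = pos + offset + rng.normal(0.0, 0.08, 3)
        atoms.append(Atom(name=name, element=element, position=where.copy(),
                          role=role, terminal_flag=flag))
        return len(atoms) - 1

    up = np.array([0.0, 1.05, 0.0])
    down = np.array([0.0, -1.05, 0.0])
    out = np.array([0.0, 0.0, 1.05])

    # ACE cap
    cay = add("CAY", "C", "cap_ACE")
    for k, off in enumerate((up, down, out), start=1):
        h = add(f"HY{k}", "H", "cap_ACE", offset=off)
        bonds.append((cay, h))
    cy = add("CY", "C", "cap_ACE")
    bonds.append((cay, cy))
    oy = add("OY", "O", "cap_ACE", offset=up)
    bonds.append((cy, oy))

    # central fragment
    n1 = add("N1", "N", "chromophore", flag="amide_N")
    bonds.append((cy, n1))
    if with_amide_h:
        h1 = add("H1", "H", "chromophore", flag="amide_H", offset=down)
        bonds.append((n1, h1))
    ca1 = add("CA1", "C", "chromophore")
    bonds.append((n1, ca1))
    ha1 = add("HA1", "H", "chromophore", offset=up)
    bonds.append((ca1, ha1))
    prev = ca1
    for s in range(n_sidechain_atoms):
        cb = add(f"CB{s + 1}", "C", "chromophore",
                 offset=out * (s + 1) + up * 0.3)
        bonds.append((prev if s == 0 else prev, cb))
        if s == 0:
            for k, off in enumerate((up, down), start=1):
                hb = add(f"HB{k}", "H", "chromophore", offset=out + off)
                bonds.append((cb, hb))
        prev = cb
    c3 = add("C3", "C", "chromophore", flag="carbonyl_C")
    bonds.append((ca1, c3))
    o3 = add("O3", "O", "chromophore", flag="carbonyl_O", offset=up)
    bonds.append((c3, o3))

    # NME cap
    nt = add("NT", "N", "cap_NME")
    bonds.append((c3, nt))
    hnt = add("HNT", "H", "cap_NME", offset=down)
    bonds.append((nt, hnt))
    cat = add("CAT", "C", "cap_NME")
    bonds.append((nt, cat))
    for k, off in enumerate((up, down, out), start=1):
        ht = add(f"HT{k}", "H", "cap_NME", offset=off)
        bonds.append((cat, ht))

    return Structure(atoms=atoms, bonds=bonds)


def gen_ou_angle_series(center: float, sigma: float, autocorrelation: float,
                        n: int, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series with marginal mean ``center`` and SD
    ``sigma`` (degrees) — a stand-in for MD angle fluctuations."""
    if not 0.0 <= autocorrelation < 1.0:
        raise ValueError("autocorrelation must be in [0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if sigma == 0.0:
        return np.full(n, float(center))
    phi = autocorrelation
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return center + x


def gen_perturbed_structure(base: Structure, displacement_sd: float,
                            seed: int = 0) -> Structure:
    """Copy of ``base`` with seeded isotropic Gaussian coordinate jitter
    (every frame perturbed independently); SD 0 returns an exact copy."""
    if displacement_sd < 0:
        raise ValueError("displacement_sd must be >= 0")
    rng = np.random.default_rng(seed)
    new = base.copy()
    if displacement_sd > 0:
        new.frames = new.frames + rng.normal(0.0, displacement_sd,
                                             size=new.frames.shape)
        for i, atom in enumerate(new.atoms):
            atom.position = new.frames[0, i].copy()
    return new
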