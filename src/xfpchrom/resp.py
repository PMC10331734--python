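"""Constrained two-stage restrained-ESP (RESP) charge fitting.

Atom-centered point charges are fit to reproduce a molecular electrostatic
potential sampled on a grid, minimizing

    chi^2 = sum_k (V_k - sum_i q_i / r_ik)^2
            + sum_i a * (sqrt(q_i^2 + b^2) - b)

(atomic units throughout) subject to linear constraints: total charge,
fixed single-atom charges, group charge sums, and equivalence classes.
The hyperbolic restraint pulls charges toward zero; because its strength
depends on q it is applied by iterating linear solves of the restrained
normal equations with Lagrange-multiplier constraint rows until the
charges stop moving.

Three constraint schemes of increasing strictness are provided:

``free_fit``
    only rotational equivalence of methyl/methylene hydrogens plus the
    total molecular charge — the best possible fixed-charge reproduction
    of the ESP.
``cap_fix``
    additionally forces the ACE and NME capping groups each to zero total
    charge, so the caps can be removed leaving an integer-charge residue.
``amide_fix``
    additionally pins the terminal amide N/H and carbonyl C/O to the
    neutral-consensus backbone charges of the Cornell-family force fields,
    for consistency with every other residue in a protein.  When the
    chromophore has no hydrogen on its amino terminus (the DsRed/mCherry
    case, whose ring nitrogen is proline-like), the nitrogen is left free
    and the carbonyl C and O of the adjacent ACE cap are fixed instead.

Standard two-stage fitting: stage 1 fits all atoms under a weak restraint
with the scheme's fix/group-sum constraints; stage 2 refits only methyl
and methylene carbons and their (equivalenced) hydrogens under a stronger
restraint with everything else frozen at stage-1 values.

The statsmodels-style surface is :class:`RespModel` (``fit()`` returns a
:class:`RespResult` with a ``summary()`` table); the functional surface
(:func:`fit_two_stage`, :func:`solve_stage`) is equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_model import Structure

__all__ = [
    "BOHR_PER_ANGSTROM",
    "CORNELL_PROLINE_N",
    "PUBLISHED_PROLINE_LIKE_N",
    "DEFAULT_TERMINAL_CHARGES",
    "RespError",
    "EspGrid",
    "ChargeConstraint",
    "ConstraintScheme",
    "RespConfig",
    "RespResult",
    "RespModel",
    "esp_from_point_charges",
    "relative_rms_fit",
    "solve_stage",
    "fit_two_stage",
    "scheme_free_fit",
    "scheme_cap_fix",
    "scheme_amide_fix",
    "methyl_methylene_groups",
    "read_esp_file",
    "write_esp_file",
    "read_plain_grid",
    "write_charge_table",
    "load_scheme_file",
]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

# Cornell-family neutral-consensus backbone charges (ff14SB amino-acid and
# ACE-cap library values, elementary charge).  Configuration data from the
# force-field files; exposed so users can substitute their own.
DEFAULT_TERMINAL_CHARGES = {
    "N": -0.4157,
    "H": 0.2719,
    "C": 0.5973,
    "O": -0.5679,
    "cap_C": 0.5972,  # ACE carbonyl carbon
    "cap_O": -0.5679,  # ACE carbonyl oxygen
}

# Cornell charge of the proline backbone nitrogen (the reference point for
# proline-like chromophore nitrogens that carry no amide hydrogen).
CORNELL_PROLINE_N = -0.2548

# Published amide-fix charges of the proline-like N-terminal nitrogen in the
# two chromophores that lack an amide hydrogen (validation reference only;
# never used as input to a fit).
PUBLISHED_PROLINE_LIKE_N = {"DsRed": -0.292329, "mCherry": -0.283649}


class RespError(ValueError):
    """Invalid grid/constraints or a failed fit."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class EspGrid:
    """ESP sample: atom positions and grid points in Bohr, potentials in
    hartree/e."""

    atom_positions: np.ndarray  # (n_atoms, 3), Bohr
    grid_points: np.ndarray  # (n_points, 3), Bohr
    potentials: np.ndarray  # (n_points,), atomic units

    def __post_init__(self) -> None:
        self.atom_positions = np.asarray(self.atom_positions, dtype=float)
        self.grid_points = np.asarray(self.grid_points, dtype=float)
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.atom_positions.ndim != 2 or self.atom_positions.shape[1] != 3:
            raise RespError("atom_positions must be (n_atoms, 3)")
        if self.grid_points.ndim != 2 or self.grid_points.shape[1] != 3:
            raise RespError("grid_points must be (n_points, 3)")
        if self.potentials.shape != (self.grid_points.shape[0],):
            raise RespError("one potential required per grid point")
        d = self._distances()
        if d.size and d.min() <= 1e-6:
            raise RespError(
                f"grid point coincides with an atom (min distance {d.min():.2e} Bohr)"
            )

    def _distances(self) -> np.ndarray:
        diff = self.grid_points[:, None, :] - self.atom_positions[None, :, :]
        return np.linalg.norm(diff, axis=2)  # (n_points, n_atoms)

    @property
    def n_atoms(self) -> int:
        return self.atom_positions.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid_points.shape[0]

    def design_matrix(self) -> np.ndarray:
        """Coulomb design matrix A with A[k, i] = 1 / r_ik (atomic units)."""
        return 1.0 / self._distances()


@dataclass(frozen=True)
class ChargeConstraint:
    """fix: one atom pinned to ``value``; group_sum: listed atoms sum to
    ``value``; equivalence: listed atoms share one charge."""

    kind: str  # fix | group_sum | equivalence
    atoms: tuple[int, ...]
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fix", "group_sum", "equivalence"):
            raise RespError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "fix" and len(self.atoms) != 1:
            raise RespError("fix constraint takes exactly one atom")
        if self.kind == "group_sum" and len(self.atoms) < 1:
            raise RespError("group_sum constraint needs at least one atom")
        if self.kind == "equivalence" and len(self.atoms) < 2:
            raise RespError("equivalence constraint needs at least two atoms")
        if self.kind in ("fix", "group_sum") and self.value is None:
            raise RespError(f"{self.kind} constraint needs a value")


@dataclass
class ConstraintScheme:
    name: str  # free_fit | cap_fix | amide_fix
    constraints: list[ChargeConstraint]
    total_charge: int

    def __post_init__(self) -> None:
        fixed: dict[int, float] = {}
        for c in self.constraints:
            if c.kind == "fix":
                (i,) = c.atoms
                if i in fixed and fixed[i] != c.value:
                    raise RespError(
                        f"atom {i} fixed to both {fixed[i]} and {c.value}"
                    )
                fixed[i] = float(c.value)  # type: ignore[arg-type]

    def fixed_atoms(self) -> dict[int, float]:
        return {
            c.atoms[0]: float(c.value)  # type: ignore[arg-type]
            for c in self.constraints if c.kind == "fix"
        }


@dataclass
class RespConfig:
    restraint_a_stage1: float = 0.0005  # au
    restraint_a_stage2: float = 0.001  # au
    restraint_b: float = 0.1  # au
    restrain_hydrogens: bool = False
    convergence_tol: float = 1e-6  # e
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.restraint_a_stage1 < 0 or self.restraint_a_stage2 < 0:
            raise RespError("restraint a must be >= 0")
        if not self.restraint_b > 0:
            raise RespError("restraint b must be > 0")
        if not self.convergence_tol > 0:
            raise RespError("convergence tolerance must be > 0")


@dataclass
class RespResult:
    """Converged charges plus fit diagnostics."""

    charges: np.ndarray  # e, per atom
    relative_rms_fit: float
    stage1_charges: np.ndarray
    iterations_used: int
    scheme: str
    atom_names: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"RESP fit ({self.scheme})",
            f"  atoms: {len(self.charges)}   iterations: {self.iterations_used}",
            f"  relative RMS fit: {self.relative_rms_fit:.6f}",
            f"  total charge: {self.charges.sum():+.6f} e",
            "",
            f"  {'atom':<8s}{'stage 1 (e)':>14s}{'final (e)':>14s}",
        ]
        for i, q in enumerate(self.charges):
            name = self.atom_names[i] if i < len(self.atom_names) else str(i + 1)
            lines.append(f"  {name:<8s}{self.stage1_charges[i]:>14.6f}{q:>14.6f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Forward model and fit quality
# ---------------------------------------------------------------------------

def esp_from_point_charges(charges, atom_positions, grid_points) -> np.ndarray:
    """Coulomb potential V_k = sum_i q_i / r_ik, atomic units."""
    charges = np.asarray(charges, dtype=float)
    grid = EspGrid(
        atom_positions=atom_positions,
        grid_points=grid_points,
        potentials=np.zeros(np.asarray(grid_points).shape[0]),
    )
    if charges.shape != (grid.n_atoms,):
        raise RespError("one charge required per atom")
    return grid.design_matrix() @ charges


def relative_rms_fit(grid: EspGrid, charges) -> float:
    """sqrt( sum (V - V_model)^2 / sum V^2 ); 0 for a perfect fit."""
    charges = np.asarray(charges, dtype=float)
    if charges.shape != (grid.n_atoms,):
        raise RespError("one charge required per atom")
    denom = float(np.sum(grid.potentials**2))
    if denom == 0.0:
        raise RespError("all reference potentials are zero")
    model = grid.design_matrix() @ charges
    return float(np.sqrt(np.sum((grid.potentials - model) ** 2) / denom))


# ---------------------------------------------------------------------------
# Constrained restrained least squares
# ---------------------------------------------------------------------------

def solve_stage(grid: EspGrid,
                constraints: list[ChargeConstraint],
                restraint_a: float,
                restraint_b: float,
                total_charge: float,
                frozen: dict[int, float] | None = None,
                restrained: list[int] | None = None,
                config: RespConfig | None = None) -> tuple[np.ndarray, int]:
    """One RESP stage: iterated restrained normal equations with constraint
    rows.  Returns (charges for all atoms, iterations used).

    ``frozen`` maps atom index -> held charge (moved to the right-hand
    side); ``restrained`` lists atom indices the hyperbolic restraint acts
    on (default: all non-frozen atoms).
    """
    config = config or RespConfig()
    n = grid.n_atoms
    frozen = dict(frozen or {})
    for i in frozen:
        if not 0 <= i < n:
            raise RespError(f"frozen atom index {i} out of range")
    free = [i for i in range(n) if i not in frozen]
    if not free:
        raise RespError("no free atoms to fit")
    col = {atom: k for k, atom in enumerate(free)}
    nf = len(free)

    a_full = grid.design_matrix()
    v_adj = grid.potentials.copy()
    if frozen:
        fro_idx = sorted(frozen)
        v_adj -= a_full[:, fro_idx] @ np.array([frozen[i] for i in fro_idx])
    a_free = a_full[:, free]
    ata = a_free.T @ a_free
    atb = a_free.T @ v_adj

    # constraint rows over free atoms (frozen contributions on the RHS)
    rows: list[np.ndarray] = []
    rhs: list[float] = []

    def add_row(vec: np.ndarray, val: float) -> None:
        rows.append(vec)
        rhs.append(val)

    total_row = np.ones(nf)
    add_row(total_row, total_charge - sum(frozen.values()))
    for c in constraints:
        if c.kind == "fix":
            (i,) = c.atoms
            if i in frozen:
                continue  # already held
            vec = np.zeros(nf)
            vec[col[i]] = 1.0
            add_row(vec, float(c.value))  # type: ignore[arg-type]
        elif c.kind == "group_sum":
            vec = np.zeros(nf)
            val = float(c.value)  # type: ignore[arg-type]
            nonfrozen = 0
            for i in c.atoms:
                if i in frozen:
                    val -= frozen[i]
                else:
                    vec[col[i]] = 1.0
                    nonfrozen += 1
            if nonfrozen:
                add_row(vec, val)
        elif c.kind == "equivalence":
            members = [i for i in c.atoms if i not in frozen]
            if len(members) != len(c.atoms) and members:
                raise RespError(
                    "equivalence class mixes frozen and free atoms: "
                    f"{c.atoms}"
                )
            for a, b in zip(members, members[1:]):
                vec = np.zeros(nf)
                vec[col[a]] = 1.0
                vec[col[b]] = -1.0
                add_row(vec, 0.0)

    cmat = np.vstack(rows)
    dvec = np.asarray(rhs)
    ncon = cmat.shape[0]

    if restrained is None:
        restrained_cols = list(range(nf))
    else:
        restrained_cols = [col[i] for i in restrained if i in col]

    q = np.zeros(nf)
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        diag = np.zeros(nf)
        if restraint_a > 0 and restrained_cols:
            rc = np.asarray(restrained_cols)
            diag[rc] = restraint_a / np.sqrt(q[rc] ** 2 + restraint_b**2)
        kkt = np.zeros((nf + ncon, nf + ncon))
        kkt[:nf, :nf] = ata + np.diag(diag)
        kkt[:nf, nf:] = cmat.T
        kkt[nf:, :nf] = cmat
        full_rhs = np.concatenate([atb, dvec])
        try:
            sol = np.linalg.solve(kkt, full_rhs)
        except np.linalg.LinAlgError as exc:
            raise RespError(f"singular constrained system: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise RespError("singular constrained system (non-finite solution)")
        q_new = sol[:nf]
        delta = float(np.max(np.abs(q_new - q)))
        q = q_new
        if delta < config.convergence_tol:
            break
    else:
        raise RespError(
            f"RESP stage did not converge in {config.max_iterations} "
            f"iterations (last max |dq| = {delta:.3e} e)"
        )

    out = np.empty(n)
    for i, v in frozen.items():
        out[i] = v
    for i, k in col.items():
        out[i] = q[k]
    return out, iterations


# ---------------------------------------------------------------------------
# Topology helpers
# ---------------------------------------------------------------------------

def methyl_methylene_groups(topology: Structure) -> list[tuple[int, list[int]]]:
    """(carbon index, [hydrogen indices]) for every CH3/CH2 group."""
    groups = []
    for i, atom in enumerate(topology.atoms):
        if atom.element.upper() != "C":
            continue
        hydrogens = [
            j for j in topology.neighbors(i)
            if topology.atoms[j].element.upper() == "H"
        ]
        if len(hydrogens) in (2, 3):
            groups.append((i, sorted(hydrogens)))
    return groups


def _cap_atoms(topology: Structure, role: str) -> list[int]:
    return [i for i, a in enumerate(topology.atoms) if a.role == role]


def _terminal_atoms(topology: Structure) -> dict[str, int]:
    found: dict[str, int] = {}
    for i, a in enumerate(topology.atoms):
        if a.terminal_flag != "none":
            if a.terminal_flag in found:
                raise RespError(
                    f"terminal_flag {a.terminal_flag} set on more than one atom"
                )
            found[a.terminal_flag] = i
    return found


def _hydrogen_equivalences(topology: Structure,
                           equivalence_within_caps: bool = True
                           ) -> list[ChargeConstraint]:
    out = []
    for carbon, hydrogens in methyl_methylene_groups(topology):
        in_cap = topology.atoms[carbon].role != "chromophore"
        if in_cap and not equivalence_within_caps:
            continue
        out.append(ChargeConstraint("equivalence", tuple(hydrogens)))
    return out


# ---------------------------------------------------------------------------
# Constraint schemes
# ---------------------------------------------------------------------------

def scheme_free_fit(topology: Structure, total_charge: int,
                    equivalence_within_caps: bool = True) -> ConstraintScheme:
    """Rotational hydrogen equivalence + total charge only."""
    return ConstraintScheme(
        name="free_fit",
        constraints=_hydrogen_equivalences(topology, equivalence_within_caps),
        total_charge=total_charge,
    )


def scheme_cap_fix(topology: Structure, total_charge: int,
                   equivalence_within_caps: bool = True) -> ConstraintScheme:
    """free_fit plus zero total charge on each capping group."""
    ace = _cap_atoms(topology, "cap_ACE")
    nme = _cap_atoms(topology, "cap_NME")
    missing = [r for r, atoms in (("cap_ACE", ace), ("cap_NME", nme)) if not atoms]
    if missing:
        raise RespError(f"topology has no atoms annotated with role {missing}")
    constraints = _hydrogen_equivalences(topology, equivalence_within_caps)
    constraints.append(ChargeConstraint("group_sum", tuple(ace), 0.0))
    constraints.append(ChargeConstraint("group_sum", tuple(nme), 0.0))
    return ConstraintScheme(name="cap_fix", constraints=constraints,
                            total_charge=total_charge)


def scheme_amide_fix(topology: Structure, total_charge: int,
                     terminal_reference_charges: dict[str, float] | None = None,
                     equivalence_within_caps: bool = True) -> ConstraintScheme:
    """cap_fix plus fixed terminal amide/carbonyl charges.

    With an amide hydrogen present, the amide N, amide H, carbonyl C and
    carbonyl O are pinned to the neutral-consensus reference charges.
    Without one (proline-like N terminus), the N stays free and the
    carbonyl C/O of the adjacent ACE cap are pinned instead.
    """
    ref = dict(DEFAULT_TERMINAL_CHARGES)
    if terminal_reference_charges:
        ref.update(terminal_reference_charges)
    base = scheme_cap_fix(topology, total_charge, equivalence_within_caps)
    terminals = _terminal_atoms(topology)
    for flag in ("amide_N", "carbonyl_C", "carbonyl_O"):
        if flag not in terminals:
            raise RespError(
                f"amide_fix needs a terminal_flag {flag} atom; absent flags: "
                f"{sorted(set(['amide_N', 'carbonyl_C', 'carbonyl_O']) - set(terminals))}"
            )
    constraints = list(base.constraints)
    constraints.append(
        ChargeConstraint("fix", (terminals["carbonyl_C"],), ref["C"])
    )
    constraints.append(
        ChargeConstraint("fix", (terminals["carbonyl_O"],), ref["O"])
    )
    if "amide_H" in terminals:
        constraints.append(
            ChargeConstraint("fix", (terminals["amide_N"],), ref["N"])
        )
        constraints.append(
            ChargeConstraint("fix", (terminals["amide_H"],), ref["H"])
        )
    else:
        # proline-like N: fix the ACE cap carbonyl C and O instead
        ace = _cap_atoms(topology, "cap_ACE")
        cap_c = cap_o = None
        for i in ace:
            if topology.atoms[i].element.upper() != "C":
                continue
            for j in topology.neighbors(i):
                if j in ace and topology.atoms[j].element.upper() == "O":
                    cap_c, cap_o = i, j
                    break
            if cap_c is not None:
                break
        if cap_c is None or cap_o is None:
            raise RespError(
                "no amide_H and no identifiable ACE carbonyl C=O; cannot "
                "build the proline-like amide_fix variant"
            )
        constraints.append(ChargeConstraint("fix", (cap_c,), ref["cap_C"]))
        constraints.append(ChargeConstraint("fix", (cap_o,), ref["cap_O"]))
    return ConstraintScheme(name="amide_fix", constraints=constraints,
                            total_charge=total_charge)


# ---------------------------------------------------------------------------
# Two-stage fit
# ---------------------------------------------------------------------------

def fit_two_stage(grid: EspGrid, topology: Structure,
                  scheme: ConstraintScheme,
                  config: RespConfig | None = None) -> RespResult:
    """Standard two-stage RESP under the given constraint scheme."""
    config = config or RespConfig()
    if grid.n_atoms != topology.n_atoms:
        raise RespError(
            f"grid has {grid.n_atoms} atoms but topology has {topology.n_atoms}"
        )
    heavy = [i for i, a in enumerate(topology.atoms)
             if a.element.upper() != "H"]
    restrained1 = None if config.restrain_hydrogens else heavy

    stage1_constraints = [c for c in scheme.constraints
                          if c.kind != "equivalence"]
    q1, it1 = solve_stage(
        grid, stage1_constraints, config.restraint_a_stage1,
        config.restraint_b, scheme.total_charge,
        frozen=None, restrained=restrained1, config=config,
    )

    groups = methyl_methylene_groups(topology)
    if not groups:
        charges, iterations = q1, it1
    else:
        stage2_atoms = sorted(
            {c for c, hs in groups} | {h for _, hs in groups for h in hs}
        )
        stage2_set = set(stage2_atoms)
        frozen = {i: float(q1[i]) for i in range(topology.n_atoms)
                  if i not in stage2_set}
        # refit constraints: keep fix/group_sum rows touching stage-2 atoms,
        # plus hydrogen equivalences within stage 2
        stage2_constraints = []
        for c in scheme.constraints:
            if c.kind == "equivalence":
                if set(c.atoms) <= stage2_set:
                    stage2_constraints.append(c)
            elif any(i in stage2_set for i in c.atoms):
                stage2_constraints.append(c)
        restrained2 = (stage2_atoms if config.restrain_hydrogens
                       else [i for i in stage2_atoms if i in set(heavy)])
        charges, it2 = solve_stage(
            grid, stage2_constraints, config.restraint_a_stage2,
            config.restraint_b, scheme.total_charge,
            frozen=frozen, restrained=restrained2, config=config,
        )
        iterations = it1 + it2

    return RespResult(
        charges=np.asarray(charges),
        relative_rms_fit=relative_rms_fit(grid, charges),
        stage1_charges=np.asarray(q1),
        iterations_used=iterations,
        scheme=scheme.name,
        atom_names=[a.name for a in topology.atoms],
    )


class RespModel:
    """Model-object wrapper: data in the constructor, ``fit()`` for results.

    >>> model = RespModel(grid, topology, scheme)
    >>> result = model.fit()
    >>> print(result.summary())
    """

    def __init__(self, grid: EspGrid, topology: Structure,
                 scheme: ConstraintScheme | str = "free_fit",
                 config: RespConfig | None = None,
                 total_charge: int | None = None):
        self.grid = grid
        self.topology = topology
        self.config = config or RespConfig()
        if isinstance(scheme, str):
            if total_charge is None:
                raise RespError("total_charge required when naming a scheme")
            builders = {
                "free_fit": scheme_free_fit,
                "cap_fix": scheme_cap_fix,
                "amide_fix": scheme_amide_fix,
            }
            if scheme not in builders:
                raise RespError(f"unknown scheme {scheme!r}")
            scheme = builders[scheme](topology, total_charge)
        self.scheme = scheme

    def fit(self) -> RespResult:
        return fit_two_stage(self.grid, self.topology, self.scheme, self.config)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_esp_file(grid: EspGrid) -> str:
    """Classic RESP ESP layout: counts; atom coords; then V x y z lines.
    All values in atomic units (Bohr, hartree/e)."""
    out = [f"{grid.n_atoms:5d}{grid.n_points:6d}"]
    for x, y, z in grid.atom_positions:
        out.append(f"{'':16s}{x:16.7E}{y:16.7E}{z:16.7E}")
    for v, (x, y, z) in zip(grid.potentials, grid.grid_points):
        out.append(f"{v:16.7E}{x:16.7E}{y:16.7E}{z:16.7E}")
    return "\n".join(out) + "\n"


def read_esp_file(text: str) -> EspGrid:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise RespError("empty ESP file")
    head = lines[0].split()
    if len(head) < 2:
        raise RespError("ESP header must give atom and point counts")
    try:
        n_atoms, n_points = int(head[0]), int(head[1])
    except ValueError as exc:
        raise RespError("non-integer counts in ESP header") from exc
    if len(lines) != 1 + n_atoms + n_points:
        raise RespError(
            f"ESP file has {len(lines) - 1} data lines; header promises "
            f"{n_atoms} + {n_points}"
        )
    atoms = []
    for lineno, ln in enumerate(lines[1 : 1 + n_atoms], start=2):
        vals = [float(v) for v in ln.replace("D", "E").split()]
        if len(vals) < 3:
            raise RespError(f"line {lineno}: expected 3 atom coordinates")
        atoms.append(vals[-3:])
    points, pots = [], []
    for lineno, ln in enumerate(lines[1 + n_atoms :], start=2 + n_atoms):
        vals = [float(v) for v in ln.replace("D", "E").split()]
        if len(vals) != 4:
            raise RespError(f"line {lineno}: expected 'V x y z'")
        pots.append(vals[0])
        points.append(vals[1:])
    return EspGrid(atom_positions=np.array(atoms), grid_points=np.array(points),
                   potentials=np.array(pots))


def read_plain_grid(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Plain whitespace grid: 'x y z V' per line, atomic units only.
    Returns (points (n,3) Bohr, potentials (n,))."""
    points, pots = [], []
    for lineno, ln in enumerate(text.splitlines(), start=1):
        body = ln.split("#", 1)[0].strip()
        if not body:
            continue
        vals = body.split()
        if len(vals) != 4:
            raise RespError(f"line {lineno}: expected 'x y z V'")
        try:
            nums = [float(v) for v in vals]
        except ValueError as exc:
            raise RespError(f"line {lineno}: non-numeric field") from exc
        points.append(nums[:3])
        pots.append(nums[3])
    if not points:
        raise RespError("empty grid file")
    return np.array(points), np.array(pots)


def write_charge_table(result: RespResult) -> str:
    """Two-column charge table (atom name, charge to 6 decimals)."""
    lines = []
    for i, q in enumerate(result.charges):
        name = (result.atom_names[i] if i < len(result.atom_names)
                else f"A{i + 1}")
        lines.append(f"{name:<8s}{q:>12.6f}")
    return "\n".join(lines) + "\n"


def load_scheme_file(text: str, topology: Structure,
                     total_charge: int) -> ConstraintScheme:
    """Constraint-scheme file: 'fix ATOM value | sum ATOM... value |
    equiv ATOM...' per line, atoms referenced by name."""
    constraints: list[ChargeConstraint] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        kw = parts[0].lower()
        try:
            if kw == "fix":
                if len(parts) != 3:
                    raise RespError("fix needs 'fix ATOM value'")
                constraints.append(ChargeConstraint(
                    "fix", (topology.index_of(parts[1]),), float(parts[2])))
            elif kw == "sum":
                if len(parts) < 3:
                    raise RespError("sum needs 'sum ATOM... value'")
                idx = tuple(topology.index_of(n) for n in parts[1:-1])
                constraints.append(
                    ChargeConstraint("group_sum", idx, float(parts[-1])))
            elif kw == "equiv":
                if len(parts) < 3:
                    raise RespError("equiv needs 'equiv ATOM ATOM...'")
                idx = tuple(topology.index_of(n) for n in parts[1:])
                constraints.append(ChargeConstraint("equivalence", idx))
            else:
                raise RespError(f"unknown keyword {kw!r}")
        except (KeyError, ValueError, RespError) as exc:
            raise RespError(f"line {lineno}: {exc}") from exc
    return ConstraintScheme(name="custom", constraints=constraints,
                            total_charge=total_charge)
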