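"""Core molecular data model, chromophore registry, and structure readers.

The central container is :class:`Structure`: an ordered list of atoms, an
optional bond list (pairs of 0-based indices), and one or more coordinate
frames in Angstrom.  PDB input maps each MODEL block to one frame; XYZ input
maps each repeated block to one frame.

Atom *roles* (chromophore / cap_ACE / cap_NME) and *terminal flags*
(amide_N, amide_H, carbonyl_C, carbonyl_O) drive the charge-fitting
constraint schemes.  They are never inferred from geometry: they come either
from a plain-text annotation file or from the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ROLES",
    "TERMINAL_FLAGS",
    "Atom",
    "Structure",
    "ChromophoreSpec",
    "ParseError",
    "chromophore_registry",
    "registry_lookup",
    "load_pdb",
    "write_pdb",
    "load_xyz_frames",
    "write_xyz_frames",
    "load_annotations",
    "apply_annotations",
]

ROLES = ("chromophore", "cap_ACE", "cap_NME")
TERMINAL_FLAGS = ("none", "amide_N", "amide_H", "carbonyl_C", "carbonyl_O")

_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "SE", "BR", "I", "FE", "ZN", "MN",
    "CU", "CO", "NI", "MO", "CD",
}


class ParseError(ValueError):
    """Malformed structure or annotation file."""


@dataclass
class Atom:
    """One atom: PDB-style name, element, force-field type, position (A)."""

    name: str
    element: str
    position: np.ndarray
    atom_type: str = ""
    charge: float | None = None
    role: str = "chromophore"
    terminal_flag: str = "none"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite position")
        if self.element.upper() not in _ELEMENTS:
            raise ValueError(f"atom {self.name}: unknown element {self.element!r}")
        if self.role not in ROLES:
            raise ValueError(f"atom {self.name}: unknown role {self.role!r}")
        if self.terminal_flag not in TERMINAL_FLAGS:
            raise ValueError(
                f"atom {self.name}: unknown terminal_flag {self.terminal_flag!r}"
            )


@dataclass
class Structure:
    """Ordered atoms + bonds (0-based index pairs) + coordinate frames (A).

    ``frames`` has shape (n_frames, n_atoms, 3); ``atoms[i].position`` mirrors
    frame 0 for convenience.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if self.frames is None:
            self.frames = np.asarray(
                [[a.position for a in self.atoms]], dtype=float
            )
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n, 3):
            raise ValueError(
                f"frames must have shape (n_frames, {n}, 3), got {self.frames.shape}"
            )
        seen = set()
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) index out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-bond on atom index {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def coords(self, frame: int = 0) -> np.ndarray:
        return self.frames[frame]

    def index_of(self, name: str) -> int:
        """Index of the (unique) atom with this name."""
        hits = [i for i, a in enumerate(self.atoms) if a.name == name]
        if not hits:
            raise KeyError(f"no atom named {name!r}")
        if len(hits) > 1:
            raise KeyError(f"atom name {name!r} is not unique")
        return hits[0]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            frames=self.frames.copy(),
        )


@dataclass(frozen=True)
class ChromophoreSpec:
    """Registry entry for one parameterized chromophore."""

    protein_name: str
    tripeptide: str  # three one-letter residue codes, e.g. "TYG"
    tripeptide_names: str  # e.g. "Thr-Tyr-Gly"
    pdb_chromophore_code: str
    reference_pdb_id: str
    net_charge: int

    def __post_init__(self) -> None:
        if self.net_charge not in (-1, 0):
            raise ValueError(f"net_charge must be -1 or 0, got {self.net_charge}")
        if not (3 <= len(self.pdb_chromophore_code) <= 4):
            raise ValueError("chromophore code must be 3-4 characters")
        if len(self.tripeptide) != 3:
            raise ValueError("tripeptide must be 3 one-letter codes")


def chromophore_registry() -> list[ChromophoreSpec]:
    """The seven parameterized chromophores.

    Six fluorescent proteins; EBFP appears twice because its chromophore
    histidine was parameterized in both neutral tautomers (HID and HIE).
    """
    from . import _tables

    return [
        ChromophoreSpec(
            protein_name=name,
            tripeptide=tri,
            tripeptide_names=_tables.TRIPEPTIDE_NAMES[name],
            pdb_chromophore_code=code,
            reference_pdb_id=ref,
            net_charge=q,
        )
        for name, tri, code, ref, q in _tables.REGISTRY_ROWS
    ]


def registry_lookup(protein_name: str) -> ChromophoreSpec:
    """Case-insensitive lookup by protein name (e.g. "EGFP", "EBFP-HID")."""
    entries = chromophore_registry()
    key = protein_name.strip().lower()
    for spec in entries:
        if spec.protein_name.lower() == key:
            return spec
    variants = [s.protein_name for s in entries if s.protein_name.lower().startswith(key)]
    if variants:
        raise KeyError(
            f"{protein_name!r} is ambiguous; did you mean one of {variants}?"
        )
    raise KeyError(
        f"unknown chromophore {protein_name!r}; known: "
        + ", ".join(s.protein_name for s in entries)
    )


# ---------------------------------------------------------------------------
# PDB I/O (ATOM/HETATM/MODEL/ENDMDL/CONECT subset)
# ---------------------------------------------------------------------------

def _guess_element(name: str, field77: str) -> str:
    if field77.strip():
        return field77.strip().capitalize()
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in _ELEMENTS and stripped[:2].isalpha():
        # two-letter elements only when the name starts in column 13 (rare
        # for organics); single letter is the right guess for C/N/O/H/S
        if stripped[:2].upper() in {"CL", "BR", "FE", "ZN", "MG", "NA", "SE"}:
            return stripped[:2].capitalize()
    return stripped[0].upper()


def load_pdb(text: str) -> Structure:
    """Parse a PDB-dialect string into a Structure.

    One frame per MODEL block (single frame when no MODEL records).  CONECT
    records become bonds (serial numbers mapped to 0-based indices).
    Coordinates are taken verbatim in Angstrom.
    """
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    frames: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    bonds: set[tuple[int, int]] = set()
    in_model = False
    saw_model = False
    first_pass = True

    def close_frame(lineno: int) -> None:
        nonlocal current, first_pass
        if not current:
            return
        if frames and len(current) != len(frames[0]):
            raise ParseError(
                f"line {lineno}: MODEL with {len(current)} atoms after "
                f"{len(frames[0])}"
            )
        frames.append(current)
        current = []
        first_pass = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
        elif rec == "ENDMDL":
            in_model = False
            close_frame(lineno)
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(
                    f"line {lineno}: truncated {rec} record (need columns 31-54 "
                    "for coordinates)"
                )
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed {rec} record: {exc}") from exc
            pos = np.array([x, y, z])
            if first_pass:
                element = _guess_element(line[12:16], line[76:78] if len(line) >= 78 else "")
                atoms.append(Atom(name=name, element=element, position=pos))
                serial_to_index[serial] = len(atoms) - 1
            current.append(pos)
        elif rec == "CONECT":
            fields = line.split()[1:]
            try:
                serials = [int(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed CONECT record") from exc
            if not serials:
                continue
            base = serials[0]
            for other in serials[1:]:
                if base in serial_to_index and other in serial_to_index:
                    i, j = serial_to_index[base], serial_to_index[other]
                    if i != j:
                        bonds.add((min(i, j), max(i, j)))
        # TER/END/REMARK/etc. ignored

    if current:
        close_frame(len(text.splitlines()))
    if saw_model and in_model:
        raise ParseError("unterminated MODEL block (missing ENDMDL)")
    if not atoms:
        raise ParseError("no ATOM/HETATM records found")
    return Structure(
        atoms=atoms,
        bonds=sorted(bonds),
        frames=np.asarray(frames, dtype=float),
    )


def write_pdb(structure: Structure, record: str = "HETATM") -> str:
    """Serialize to PDB text, one MODEL block per frame, CONECT for bonds."""
    lines: list[str] = []
    multi = structure.n_frames > 1
    for f in range(structure.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        for i, atom in enumerate(structure.atoms):
            x, y, z = structure.frames[f, i]
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"{record:<6s}{i + 1:5d} {name:<4s} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{atom.element.upper():>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    for i, j in sorted(structure.bonds):
        lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Multi-frame XYZ I/O
# ---------------------------------------------------------------------------

def load_xyz_frames(text: str) -> Structure:
    """Parse standard (possibly multi-frame) XYZ text; no bonds."""
    lines = text.splitlines()
    pos = 0
    frames: list[list[np.ndarray]] = []
    atoms: list[Atom] | None = None
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_idx += 1
        try:
            count = int(lines[pos].split()[0])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"frame {frame_idx}: expected atom count, got {lines[pos]!r}"
            ) from exc
        if atoms is not None and count != len(atoms):
            raise ParseError(
                f"frame {frame_idx}: atom count {count} differs from "
                f"frame 1 count {len(atoms)}"
            )
        if pos + 1 + count + 1 > len(lines) + 1:
            raise ParseError(f"frame {frame_idx}: truncated block")
        block = lines[pos + 2 : pos + 2 + count]
        if len(block) < count:
            raise ParseError(f"frame {frame_idx}: truncated block")
        coords: list[np.ndarray] = []
        names: list[tuple[str, str]] = []
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(
                    f"frame {frame_idx}: atom line {k + 1} has {len(parts)} fields"
                )
            try:
                xyz = np.array([float(v) for v in parts[1:4]])
            except ValueError as exc:
                raise ParseError(
                    f"frame {frame_idx}: non-numeric coordinate on atom line {k + 1}"
                ) from exc
            names.append((parts[0], parts[0]))
            coords.append(xyz)
        if atoms is None:
            atoms = [
                Atom(name=f"{sym}{k + 1}", element=sym, position=coords[k])
                for k, (sym, _) in enumerate(names)
            ]
        frames.append(coords)
        pos += 2 + count
    if atoms is None:
        raise ParseError("empty XYZ input")
    return Structure(atoms=atoms, bonds=[], frames=np.asarray(frames, dtype=float))


def write_xyz_frames(structure: Structure, comment: str = "") -> str:
    out: list[str] = []
    for f in range(structure.n_frames):
        out.append(str(structure.n_atoms))
        out.append(comment)
        for i, atom in enumerate(structure.atoms):
            x, y, z = structure.frames[f, i]
            out.append(f"{atom.element:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Annotation files: "atom_name atom_type role terminal_flag" per line
# ---------------------------------------------------------------------------

def load_annotations(text: str) -> dict[str, tuple[str, str, str]]:
    """Parse an annotation file mapping atom name -> (type, role, flag)."""
    out: dict[str, tuple[str, str, str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 4:
            raise ParseError(
                f"line {lineno}: expected 'name type role flag', got {body!r}"
            )
        name, atype, role, flag = parts
        if role not in ROLES:
            raise ParseError(f"line {lineno}: unknown role {role!r}")
        if flag not in TERMINAL_FLAGS:
            raise ParseError(f"line {lineno}: unknown terminal_flag {flag!r}")
        if name in out:
            raise ParseError(f"line {lineno}: duplicate atom name {name!r}")
        out[name] = (atype, role, flag)
    return out


def apply_annotations(
    structure: Structure, annotations: dict[str, tuple[str, str, str]]
) -> Structure:
    """Return a copy with atom_type/role/terminal_flag set from annotations."""
    new = structure.copy()
    for atom in new.atoms:
        if atom.name in annotations:
            atype, role, flag = annotations[atom.name]
            atom.atom_type = atype
            atom.role = role
            atom.terminal_flag = flag
    return new
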