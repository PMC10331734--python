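"""Typed force-field parameter database with AMBER frcmod I/O.

The builtin document carries every bonded and nonbonded parameter the seven
chromophores need beyond a loaded Cornell-family force field (ff14SB/ff19SB):
22 bonds, 56 angles, 25 torsions (40 printed rows; sidechain torsions are
multi-term Fourier series), 13 impropers, and 10 new atom types.  Parameters
reference gaff 1.81 and ff14SB sources; values are emitted digit-for-digit
as published.

Numbers are stored as floats plus, when available, the exact printed string
(the ``fmt`` fields, excluded from equality), so write -> parse -> write is
byte-identical.

Atom types containing an uppercase letter (CX, 2C, C*, ...) belong to the
base force field the user is assumed to have loaded; only the lowercase
gaff-style types must appear in the MASS and NONBON sections.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "BondParam",
    "AngleParam",
    "TorsionTerm",
    "Torsion",
    "ImproperParam",
    "NonbondedParam",
    "FrcmodDocument",
    "FrcmodError",
    "LookupError_",
    "builtin_parameter_set",
    "write_frcmod",
    "parse_frcmod",
    "lookup",
    "canonical_pair",
    "canonical_triple",
    "canonical_quad",
]

WILDCARD = "X"


class FrcmodError(ValueError):
    """Invalid frcmod content or document invariant violation."""


class LookupError_(KeyError):
    """No parameter matches the requested type tuple."""


def _fmt(value: float, raw: str | None, default: str) -> str:
    return raw if raw is not None else format(value, default)


def canonical_pair(types: tuple[str, str]) -> tuple[str, str]:
    return min(types, tuple(reversed(types)))


def canonical_triple(types: tuple[str, str, str]) -> tuple[str, str, str]:
    return min(types, tuple(reversed(types)))


def canonical_quad(types: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    return min(types, tuple(reversed(types)))


@dataclass
class BondParam:
    types: tuple[str, str]
    k_r: float  # kcal/mol/A^2
    r_eq: float  # A
    source: str = ""
    fmt: tuple[str, str] | None = field(default=None, compare=False)

    def validate(self) -> None:
        if not self.k_r > 0:
            raise FrcmodError(f"bond {'-'.join(self.types)}: k_r must be > 0")
        if not 0.5 < self.r_eq < 3.0:
            raise FrcmodError(
                f"bond {'-'.join(self.types)}: r_eq {self.r_eq} outside (0.5, 3.0) A"
            )


@dataclass
class AngleParam:
    types: tuple[str, str, str]
    k_theta: float  # kcal/mol/rad^2
    theta_eq: float  # degrees
    source: str = ""
    fmt: tuple[str, str] | None = field(default=None, compare=False)

    def validate(self) -> None:
        if not self.k_theta > 0:
            raise FrcmodError(f"angle {'-'.join(self.types)}: k_theta must be > 0")
        if not 0 < self.theta_eq < 180:
            raise FrcmodError(
                f"angle {'-'.join(self.types)}: theta_eq {self.theta_eq} "
                "outside (0, 180) degrees"
            )


@dataclass
class TorsionTerm:
    """One Fourier component.  A negative periodicity marks a continuation
    term (AMBER convention: more components of the same torsion follow)."""

    paths_divisor: int  # AMBER IDIVF
    half_barrier: float  # V_n/2, kcal/mol
    phase: float  # degrees
    periodicity: int  # signed; |n| is the true periodicity
    source: str = ""
    fmt: tuple[str, str] | None = field(default=None, compare=False)

    def validate(self, label: str) -> None:
        if abs(self.periodicity) < 1:
            raise FrcmodError(f"torsion {label}: |periodicity| must be >= 1")
        if self.paths_divisor < 1:
            raise FrcmodError(f"torsion {label}: paths divisor must be positive")


@dataclass
class Torsion:
    """A proper torsion: one logical entry holding >= 1 Fourier terms."""

    types: tuple[str, str, str, str]
    terms: list[TorsionTerm]

    @property
    def is_wildcard(self) -> bool:
        return self.types[0] == WILDCARD or self.types[3] == WILDCARD

    def validate(self) -> None:
        label = "-".join(self.types)
        if not self.terms:
            raise FrcmodError(f"torsion {label}: no terms")
        for i, t in enumerate(self.terms):
            t.validate(label)
            is_last = i == len(self.terms) - 1
            if is_last and t.periodicity < 0:
                raise FrcmodError(f"torsion {label}: last term marked continuation")
            if not is_last and t.periodicity > 0:
                raise FrcmodError(
                    f"torsion {label}: non-final term must have negative periodicity"
                )


@dataclass
class ImproperParam:
    """Improper torsion; the third atom of ``types`` is the central atom."""

    types: tuple[str, str, str, str]
    half_barrier: float  # kcal/mol
    phase: float  # degrees
    periodicity: int
    source: str = ""
    fmt: tuple[str, str] | None = field(default=None, compare=False)

    def validate(self) -> None:
        if self.periodicity < 1:
            raise FrcmodError(
                f"improper {'-'.join(self.types)}: periodicity must be positive"
            )


@dataclass
class NonbondedParam:
    atom_type: str
    mass: float  # g/mol
    polarizability: float  # A^3
    r_star: float  # A, van der Waals radius
    epsilon: float  # kcal/mol, well depth
    fmt: tuple[str, str, str, str] | None = field(default=None, compare=False)

    def validate(self) -> None:
        for name in ("mass", "polarizability", "r_star", "epsilon"):
            if not getattr(self, name) > 0:
                raise FrcmodError(f"nonbonded {self.atom_type}: {name} must be > 0")


def _improper_key(types: tuple[str, str, str, str]) -> tuple:
    i, j, k, l = types
    return (k, tuple(sorted((i, j, l))))


@dataclass
class FrcmodDocument:
    title: str = "xfpchrom parameter set"
    bonds: list[BondParam] = field(default_factory=list)
    angles: list[AngleParam] = field(default_factory=list)
    torsions: list[Torsion] = field(default_factory=list)
    impropers: list[ImproperParam] = field(default_factory=list)
    nonbonded: list[NonbondedParam] = field(default_factory=list)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        for b in self.bonds:
            b.validate()
        for a in self.angles:
            a.validate()
        for t in self.torsions:
            t.validate()
        for im in self.impropers:
            im.validate()
        for nb in self.nonbonded:
            nb.validate()

        def check_dupes(keys: list, section: str, labels: list[str]) -> None:
            seen: dict = {}
            for key, label in zip(keys, labels):
                if key in seen:
                    raise FrcmodError(f"duplicate {section} entry {label}")
                seen[key] = label

        check_dupes(
            [canonical_pair(b.types) for b in self.bonds],
            "bond",
            ["-".join(b.types) for b in self.bonds],
        )
        check_dupes(
            [canonical_triple(a.types) for a in self.angles],
            "angle",
            ["-".join(a.types) for a in self.angles],
        )
        check_dupes(
            [canonical_quad(t.types) for t in self.torsions],
            "torsion",
            ["-".join(t.types) for t in self.torsions],
        )
        check_dupes(
            [_improper_key(im.types) for im in self.impropers],
            "improper",
            ["-".join(im.types) for im in self.impropers],
        )
        check_dupes(
            [nb.atom_type for nb in self.nonbonded],
            "nonbonded",
            [nb.atom_type for nb in self.nonbonded],
        )

        # every new (lowercase, gaff-style) type referenced in a bonded
        # section must have MASS and NONBON entries; uppercase-containing
        # types come from the loaded base force field
        referenced: set[str] = set()
        for b in self.bonds:
            referenced.update(b.types)
        for a in self.angles:
            referenced.update(a.types)
        for t in self.torsions:
            referenced.update(t.types)
        for im in self.impropers:
            referenced.update(im.types)
        new_types = {
            t for t in referenced if t != WILDCARD and t.islower()
        }
        defined = {nb.atom_type for nb in self.nonbonded}
        missing = sorted(new_types - defined)
        if missing:
            raise FrcmodError(
                "atom types referenced in bonded sections but absent from "
                f"MASS/NONBON: {', '.join(missing)}"
            )


# ---------------------------------------------------------------------------
# Builtin (published) parameter set
# ---------------------------------------------------------------------------

def builtin_parameter_set() -> FrcmodDocument:
    """The complete published chromophore parameter set as a document."""
    from . import _tables

    doc = FrcmodDocument(
        title="Fluorescent protein chromophore parameters beyond ff14SB/ff19SB"
    )
    for t1, t2, k, r, src in _tables.BOND_ROWS:
        doc.bonds.append(
            BondParam(types=(t1, t2), k_r=float(k), r_eq=float(r), source=src,
                      fmt=(k, r))
        )
    for t1, t2, t3, k, th, src in _tables.ANGLE_ROWS:
        doc.angles.append(
            AngleParam(types=(t1, t2, t3), k_theta=float(k), theta_eq=float(th),
                       source=src, fmt=(k, th))
        )
    current: Torsion | None = None
    for t1, t2, t3, t4, idivf, v, ph, pn, src in _tables.TORSION_ROWS:
        term = TorsionTerm(
            paths_divisor=int(idivf), half_barrier=float(v), phase=float(ph),
            periodicity=int(pn), source=src, fmt=(v, ph),
        )
        types = (t1, t2, t3, t4)
        if current is not None and current.types == types and \
                current.terms[-1].periodicity < 0:
            current.terms.append(term)
        else:
            current = Torsion(types=types, terms=[term])
            doc.torsions.append(current)
    for t1, t2, t3, t4, v, ph, pn, src in _tables.IMPROPER_ROWS:
        doc.impropers.append(
            ImproperParam(types=(t1, t2, t3, t4), half_barrier=float(v),
                          phase=float(ph), periodicity=int(pn), source=src,
                          fmt=(v, ph))
        )
    for atype, mass, alpha, rstar, eps in _tables.NONBONDED_ROWS:
        doc.nonbonded.append(
            NonbondedParam(atom_type=atype, mass=float(mass),
                           polarizability=float(alpha), r_star=float(rstar),
                           epsilon=float(eps), fmt=(mass, alpha, rstar, eps))
        )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _types_field(types: tuple[str, ...]) -> str:
    return "-".join(f"{t:<2s}" for t in types)


def write_frcmod(doc: FrcmodDocument) -> str:
    """Emit AMBER frcmod text (MASS/BOND/ANGLE/DIHE/IMPROPER/NONBON)."""
    doc.validate()
    out: list[str] = [doc.title, "MASS"]
    for nb in doc.nonbonded:
        mass = _fmt(nb.mass, nb.fmt[0] if nb.fmt else None, ".3f")
        alpha = _fmt(nb.polarizability, nb.fmt[1] if nb.fmt else None, ".3f")
        out.append(f"{nb.atom_type:<2s} {mass:>8s} {alpha:>8s}")
    out.append("")
    out.append("BOND")
    for b in doc.bonds:
        k = _fmt(b.k_r, b.fmt[0] if b.fmt else None, ".1f")
        r = _fmt(b.r_eq, b.fmt[1] if b.fmt else None, ".4f")
        line = f"{_types_field(b.types)} {k:>8s} {r:>9s}"
        if b.source:
            line += f"    {b.source}"
        out.append(line)
    out.append("")
    out.append("ANGLE")
    for a in doc.angles:
        k = _fmt(a.k_theta, a.fmt[0] if a.fmt else None, ".3f")
        th = _fmt(a.theta_eq, a.fmt[1] if a.fmt else None, ".3f")
        line = f"{_types_field(a.types)} {k:>8s} {th:>9s}"
        if a.source:
            line += f"    {a.source}"
        out.append(line)
    out.append("")
    out.append("DIHE")
    for t in doc.torsions:
        for term in t.terms:
            v = _fmt(term.half_barrier, term.fmt[0] if term.fmt else None, ".3f")
            ph = _fmt(term.phase, term.fmt[1] if term.fmt else None, ".1f")
            line = (
                f"{_types_field(t.types)} {term.paths_divisor:>4d} {v:>8s} "
                f"{ph:>7s} {term.periodicity:>4d}"
            )
            if term.source:
                line += f"    {term.source}"
            out.append(line)
    out.append("")
    out.append("IMPROPER")
    for im in doc.impropers:
        v = _fmt(im.half_barrier, im.fmt[0] if im.fmt else None, ".1f")
        ph = _fmt(im.phase, im.fmt[1] if im.fmt else None, ".1f")
        line = (
            f"{_types_field(im.types)} {v:>8s} {ph:>7s} {im.periodicity:>4d}"
        )
        if im.source:
            line += f"    {im.source}"
        out.append(line)
    out.append("")
    out.append("NONBON")
    for nb in doc.nonbonded:
        rstar = _fmt(nb.r_star, nb.fmt[2] if nb.fmt else None, ".4f")
        eps = _fmt(nb.epsilon, nb.fmt[3] if nb.fmt else None, ".4f")
        out.append(f"  {nb.atom_type:<2s} {rstar:>8s} {eps:>8s}")
    out.append("")
    return "\n".join(out) + "\n"


_SECTIONS = ("MASS", "BOND", "ANGLE", "DIHE", "IMPROPER", "NONBON")

# dash-joined atom-type field; types are 1-2 chars, padded types leave a
# space before the next dash (e.g. "X -cc-cd-X ")
_TYPE_FIELD = re.compile(
    r"^\s*([A-Za-z0-9*+]{1,2}\s?(?:-[A-Za-z0-9*+]{1,2}\s?)+)(.*)$"
)


def _typed_line(line: str, n: int, lineno: int) -> tuple[tuple[str, ...], list[str]]:
    """Split a bonded-section line into (atom types, remaining tokens)."""
    m = _TYPE_FIELD.match(line)
    if not m:
        raise FrcmodError(f"line {lineno}: expected {n} dash-joined atom types")
    parts = [p.strip() for p in m.group(1).split("-")]
    if len(parts) != n or any(not p for p in parts):
        raise FrcmodError(
            f"line {lineno}: expected {n} dash-joined atom types, got "
            f"{m.group(1).strip()!r}"
        )
    return tuple(parts), m.group(2).split()


def _floats(tokens: list[str], n: int, lineno: int) -> list[str]:
    if len(tokens) < n:
        raise FrcmodError(f"line {lineno}: expected {n} numeric fields")
    for tok in tokens[:n]:
        try:
            float(tok)
        except ValueError:
            raise FrcmodError(f"line {lineno}: non-numeric field {tok!r}") from None
    return tokens[:n]


def parse_frcmod(text: str) -> FrcmodDocument:
    """Parse frcmod text in the dialect emitted by :func:`write_frcmod`.

    Tolerant of extra whitespace; the MASS and NONBON sections are merged
    back into per-type :class:`NonbondedParam` entries.
    """
    lines = text.splitlines()
    if not lines:
        raise FrcmodError("empty frcmod input")
    doc = FrcmodDocument(title=lines[0].rstrip())
    section: str | None = None
    masses: dict[str, tuple[str, str]] = {}
    mass_order: list[str] = []
    nonbon: dict[str, tuple[str, str]] = {}
    open_torsion: Torsion | None = None

    for lineno, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if not stripped:
            continue
        token = stripped.split()[0]
        if stripped == token and token.isupper() and token.isalpha() and "-" not in token:
            if token not in _SECTIONS:
                raise FrcmodError(f"line {lineno}: unknown section {token!r}")
            section = token
            open_torsion = None
            continue
        if section is None:
            raise FrcmodError(f"line {lineno}: content before any section header")

        if section == "MASS":
            toks = stripped.split()
            if len(toks) < 3:
                raise FrcmodError(f"line {lineno}: MASS needs type, mass, polarizability")
            atype = toks[0]
            m, a = _floats(toks[1:], 2, lineno)
            masses[atype] = (m, a)
            mass_order.append(atype)
        elif section == "BOND":
            types, rest = _typed_line(line, 2, lineno)
            k, r = _floats(rest, 2, lineno)
            source = " ".join(rest[2:])
            doc.bonds.append(
                BondParam(types=types, k_r=float(k), r_eq=float(r),
                          source=source, fmt=(k, r))
            )
        elif section == "ANGLE":
            types, rest = _typed_line(line, 3, lineno)
            k, th = _floats(rest, 2, lineno)
            source = " ".join(rest[2:])
            doc.angles.append(
                AngleParam(types=types, k_theta=float(k), theta_eq=float(th),
                           source=source, fmt=(k, th))
            )
        elif section == "DIHE":
            types, rest = _typed_line(line, 4, lineno)
            idivf, v, ph, pn = _floats(rest, 4, lineno)
            source = " ".join(rest[4:])
            term = TorsionTerm(
                paths_divisor=int(float(idivf)), half_barrier=float(v),
                phase=float(ph), periodicity=int(float(pn)),
                source=source, fmt=(v, ph),
            )
            if open_torsion is not None and open_torsion.types == types and \
                    open_torsion.terms[-1].periodicity < 0:
                open_torsion.terms.append(term)
            else:
                if open_torsion is not None and \
                        open_torsion.terms[-1].periodicity < 0:
                    raise FrcmodError(
                        f"line {lineno}: continuation expected for torsion "
                        f"{'-'.join(open_torsion.types)}"
                    )
                open_torsion = Torsion(types=types, terms=[term])
                doc.torsions.append(open_torsion)
        elif section == "IMPROPER":
            types, rest = _typed_line(line, 4, lineno)
            v, ph, pn = _floats(rest, 3, lineno)
            source = " ".join(rest[3:])
            doc.impropers.append(
                ImproperParam(types=types, half_barrier=float(v),
                              phase=float(ph), periodicity=int(float(pn)),
                              source=source, fmt=(v, ph))
            )
        elif section == "NONBON":
            toks = stripped.split()
            if len(toks) < 3:
                raise FrcmodError(f"line {lineno}: NONBON needs type, R*, epsilon")
            atype = toks[0]
            rstar, eps = _floats(toks[1:], 2, lineno)
            nonbon[atype] = (rstar, eps)

    for atype in mass_order:
        if atype not in nonbon:
            raise FrcmodError(f"MASS entry {atype!r} has no NONBON entry")
        m, a = masses[atype]
        rstar, eps = nonbon[atype]
        doc.nonbonded.append(
            NonbondedParam(atom_type=atype, mass=float(m),
                           polarizability=float(a), r_star=float(rstar),
                           epsilon=float(eps), fmt=(m, a, rstar, eps))
        )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Lookup with AMBER matching semantics
# ---------------------------------------------------------------------------

def lookup(doc: FrcmodDocument, kind: str, type_tuple: tuple[str, ...]):
    """Find the parameter entry matching ``type_tuple``.

    Bonds and angles match under tuple reversal.  Torsion matching prefers
    fully explicit quadruples over wildcard ``X-b-c-X`` entries (forward or
    reversed).  Improper matching keeps the third (central) atom fixed and
    treats the other three as an unordered set, wildcards matching anything.
    """
    label = "-".join(type_tuple)
    if kind == "bond":
        if len(type_tuple) != 2:
            raise ValueError("bond lookup needs a 2-tuple")
        want = canonical_pair(type_tuple)  # type: ignore[arg-type]
        for b in doc.bonds:
            if canonical_pair(b.types) == want:
                return b
        raise LookupError_(f"no bond parameter for {label}")
    if kind == "angle":
        if len(type_tuple) != 3:
            raise ValueError("angle lookup needs a 3-tuple")
        want3 = canonical_triple(type_tuple)  # type: ignore[arg-type]
        for a in doc.angles:
            if canonical_triple(a.types) == want3:
                return a
        raise LookupError_(f"no angle parameter for {label}")
    if kind == "torsion":
        if len(type_tuple) != 4:
            raise ValueError("torsion lookup needs a 4-tuple")
        fwd = tuple(type_tuple)
        rev = tuple(reversed(type_tuple))
        for t in doc.torsions:  # explicit entries first
            if not t.is_wildcard and t.types in (fwd, rev):
                return t
        for t in doc.torsions:
            if t.is_wildcard:
                mid = (t.types[1], t.types[2])
                if (fwd[1], fwd[2]) == mid or (rev[1], rev[2]) == mid:
                    return t
        raise LookupError_(f"no torsion parameter for {label}")
    if kind == "improper":
        if len(type_tuple) != 4:
            raise ValueError("improper lookup needs a 4-tuple")
        central = type_tuple[2]
        others = (type_tuple[0], type_tuple[1], type_tuple[3])

        def match(entry: ImproperParam) -> bool:
            if entry.types[2] != central and entry.types[2] != WILDCARD:
                return False
            pat = (entry.types[0], entry.types[1], entry.types[3])
            for perm in itertools.permutations(others):
                if all(p == WILDCARD or p == o for p, o in zip(pat, perm)):
                    return True
            return False

        explicit = [im for im in doc.impropers if WILDCARD not in im.types]
        wild = [im for im in doc.impropers if WILDCARD in im.types]
        for im in explicit + wild:
            if match(im):
                return im
        raise LookupError_(f"no improper parameter for {label}")
    if kind == "nonbonded":
        atype = type_tuple[0] if isinstance(type_tuple, tuple) else type_tuple
        for nb in doc.nonbonded:
            if nb.atom_type == atype:
                return nb
        raise LookupError_(f"no nonbonded parameter for {atype}")
    raise ValueError(f"unknown parameter kind {kind!r}")
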