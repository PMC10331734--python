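"""Atom-type model selection by bond-length RMSD.

Candidate atom-type systems (gaff "impure aromatic" cc/cd, standard-residue
types such as CA/CA, gaff "conjugated" ce/cf) each imply a set of
equilibrium bond lengths for the named bonds of a chromophore.  Scoring a
model means measuring those bonds in a reference geometry (QM-optimized or
crystal) and taking the RMSD of model-vs-measured lengths over a chosen
bond subset; ranking sorts models by that RMSD.

Exact ties are broken by a configurable priority order.  The default
prefers cc/cd, then standard-residue types, then ce/cf — mirroring the
selection logic used for the chromophore core, where cc/cd won, while
standard types are preferred for unchanged sidechains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem_model import Structure
from .geometry import bond_length

__all__ = [
    "BondModel",
    "ModelScore",
    "measure_named_bonds",
    "model_rmsd",
    "rank_models",
    "load_bond_name_map",
    "load_bond_model",
    "DEFAULT_TIE_PRIORITY",
]

DEFAULT_TIE_PRIORITY = ("cc/cd", "standard", "ce/cf")


@dataclass(frozen=True)
class BondModel:
    """A named atom-type system: bond name -> equilibrium length (A)."""

    name: str
    assignments: dict[str, float]

    def __post_init__(self) -> None:
        for bond, length in self.assignments.items():
            if not length > 0:
                raise ValueError(f"model {self.name}: bond {bond} length <= 0")


@dataclass(frozen=True)
class ModelScore:
    model_name: str
    reference_name: str
    rmsd: float  # A
    bond_subset: str = "full conjugated set"
    tie_broken: bool = False

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


def measure_named_bonds(structure: Structure,
                        bond_name_map: dict[str, tuple[str, str]],
                        frame: int = 0) -> dict[str, float]:
    """Measure each named bond (pair of atom names) in the structure, A."""
    out: dict[str, float] = {}
    for bond, (name_i, name_j) in bond_name_map.items():
        try:
            i = structure.index_of(name_i)
            j = structure.index_of(name_j)
        except KeyError as exc:
            raise KeyError(f"bond {bond}: {exc.args[0]}") from exc
        out[bond] = bond_length(structure, i, j, frame)
    return out


def model_rmsd(model: BondModel, measured: dict[str, float],
               subset: list[str] | None = None,
               reference_name: str = "reference",
               subset_label: str = "full conjugated set") -> ModelScore:
    """RMSD (A) of model equilibrium lengths against measured lengths."""
    if subset is None:
        subset = sorted(set(model.assignments) & set(measured))
    if not subset:
        raise ValueError("empty bond subset")
    missing_model = [b for b in subset if b not in model.assignments]
    missing_meas = [b for b in subset if b not in measured]
    if missing_model:
        raise KeyError(f"model {model.name} lacks bonds: {missing_model}")
    if missing_meas:
        raise KeyError(f"measurements lack bonds: {missing_meas}")
    sq = [(model.assignments[b] - measured[b]) ** 2 for b in subset]
    return ModelScore(
        model_name=model.name,
        reference_name=reference_name,
        rmsd=math.sqrt(sum(sq) / len(sq)),
        bond_subset=subset_label,
    )


def rank_models(models: list[BondModel], measured: dict[str, float],
                subset: list[str] | None = None,
                reference_name: str = "reference",
                subset_label: str = "full conjugated set",
                tie_priority: tuple[str, ...] = DEFAULT_TIE_PRIORITY,
                tie_tol: float = 0.0) -> list[ModelScore]:
    """Score every model and return scores ascending by RMSD.

    Exact ties (|difference| <= ``tie_tol``) are ordered by ``tie_priority``
    (models absent from the priority list come last, in input order) and
    flagged via ``tie_broken``.
    """
    if len(models) < 2:
        raise ValueError("ranking needs at least 2 models")
    scores = [
        model_rmsd(m, measured, subset, reference_name, subset_label)
        for m in models
    ]

    def prio(score: ModelScore) -> int:
        try:
            return tie_priority.index(score.model_name)
        except ValueError:
            return len(tie_priority)

    order = sorted(range(len(scores)),
                   key=lambda i: (scores[i].rmsd, prio(scores[i]), i))
    ranked = [scores[i] for i in order]
    out: list[ModelScore] = []
    for pos, sc in enumerate(ranked):
        tied = any(
            abs(sc.rmsd - other.rmsd) <= tie_tol
            for k, other in enumerate(ranked) if k != pos
        )
        out.append(ModelScore(sc.model_name, sc.reference_name, sc.rmsd,
                              sc.bond_subset, tie_broken=tied))
    return out


# ---------------------------------------------------------------------------
# Plain-text formats: "bondname atom1 atom2" and "bondname length" per line
# ---------------------------------------------------------------------------

def load_bond_name_map(text: str) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 3:
            raise ValueError(
                f"line {lineno}: expected 'bondname atom1 atom2', got {body!r}"
            )
        if parts[0] in out:
            raise ValueError(f"line {lineno}: duplicate bond name {parts[0]!r}")
        out[parts[0]] = (parts[1], parts[2])
    return out


def load_bond_model(text: str, name: str) -> BondModel:
    assignments: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 2:
            raise ValueError(
                f"line {lineno}: expected 'bondname length', got {body!r}"
            )
        if parts[0] in assignments:
            raise ValueError(f"line {lineno}: duplicate bond name {parts[0]!r}")
        try:
            assignments[parts[0]] = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric length") from exc
    return BondModel(name=name, assignments=assignments)
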