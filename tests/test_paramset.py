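import numpy as np
import pytest

from xfpchrom import paramset
from xfpchrom.paramset import (
    AngleParam,
    BondParam,
    FrcmodDocument,
    FrcmodError,
    ImproperParam,
    LookupError_,
    NonbondedParam,
    Torsion,
    TorsionTerm,
    lookup,
    parse_frcmod,
    write_frcmod,
)


class TestBuiltinSet:
    def test_section_counts_match_published_tables(self, builtin_doc):
        assert len(builtin_doc.bonds) == 22
        assert len(builtin_doc.angles) == 56
        assert sum(len(t.terms) for t in builtin_doc.torsions) == 40
        assert len(builtin_doc.torsions) == 25
        assert len(builtin_doc.impropers) == 13
        assert len(builtin_doc.nonbonded) == 10

    @pytest.mark.parametrize(
        "types, k_r, r_eq",
        [
            (("cc", "cd"), 500.9, 1.3729),
            (("cd", "cd"), 419.8, 1.4278),
            (("c", "o"), 637.7, 1.2183),
            (("cf", "ne"), 564.4, 1.2964),
            (("nf", "CX"), 334.7, 1.4560),
        ],
    )
    def test_bond_spot_values(self, builtin_doc, types, k_r, r_eq):
        entry = lookup(builtin_doc, "bond", types)
        assert entry.k_r == k_r and entry.r_eq == r_eq

    @pytest.mark.parametrize(
        "types, k_theta, theta_eq",
        [
            (("cc", "nc", "cd"), 71.800, 105.490),
            (("cc", "c", "o"), 69.100, 123.930),
            (("O", "C", "ne"), 80.000, 122.900),
            (("C", "ne", "cf"), 67.700, 118.530),
        ],
    )
    def test_angle_spot_values(self, builtin_doc, types, k_theta, theta_eq):
        entry = lookup(builtin_doc, "angle", types)
        assert entry.k_theta == k_theta and entry.theta_eq == theta_eq

    def test_nonbonded_spot_values(self, builtin_doc):
        ha = lookup(builtin_doc, "nonbonded", ("ha",))
        assert ha.r_star == 1.4590 and ha.epsilon == 0.0150
        o = lookup(builtin_doc, "nonbonded", ("o",))
        assert o.r_star == 1.6612 and o.epsilon == 0.2100 and o.mass == 16.00

    def test_improper_barriers_are_carbonyl_or_sp2(self, builtin_doc):
        barriers = {im.half_barrier for im in builtin_doc.impropers}
        assert barriers == {10.5, 1.1}
        assert all(im.phase == 180.0 and im.periodicity == 2
                   for im in builtin_doc.impropers)

    def test_torsion_phases_are_planar_or_zero(self, builtin_doc):
        for t in builtin_doc.torsions:
            for term in t.terms:
                assert term.phase in (0.0, 180.0)

    def test_sidechain_torsions_are_four_component_series(self, builtin_doc):
        multi = [t for t in builtin_doc.torsions if len(t.terms) > 1]
        assert len(multi) == 5
        for t in multi:
            assert len(t.terms) == 4
            assert all(term.periodicity < 0 for term in t.terms[:-1])
            assert t.terms[-1].periodicity > 0

    def test_every_gaff_type_has_mass_and_vdw(self, builtin_doc):
        defined = {nb.atom_type for nb in builtin_doc.nonbonded}
        assert defined == {"nd", "nc", "ne", "nf", "cc", "cd", "cf", "c",
                           "ha", "o"}


class TestSerialization:
    def test_emitted_text_contains_published_bond_line(self, builtin_doc):
        text = write_frcmod(builtin_doc)
        bond_lines = [ln for ln in text.splitlines() if ln.startswith("cc-cd")]
        assert bond_lines and "500.9" in bond_lines[0] and "1.3729" in bond_lines[0]

    def test_round_trip_field_equality(self, builtin_doc):
        assert parse_frcmod(write_frcmod(builtin_doc)) == builtin_doc

    def test_round_trip_byte_identity(self, builtin_doc):
        text = write_frcmod(builtin_doc)
        assert write_frcmod(parse_frcmod(text)) == text

    def test_randomized_round_trips_are_byte_identical(self):
        rng = np.random.default_rng(2024)
        types = ["cc", "cd", "nc", "nd", "c", "o", "ha", "cf", "ne", "nf"]
        for trial in range(50):
            k = rng.integers(1, 5)
            chosen = rng.choice(types, size=k, replace=False)
            doc = FrcmodDocument(title=f"random doc {trial}")
            used = set()
            for t in chosen:
                doc.nonbonded.append(NonbondedParam(
                    atom_type=t,
                    mass=round(float(rng.uniform(1, 32)), 3),
                    polarizability=round(float(rng.uniform(0.1, 1.0)), 3),
                    r_star=round(float(rng.uniform(1.0, 2.0)), 4),
                    epsilon=round(float(rng.uniform(0.01, 0.3)), 4),
                ))
                used.add(t)
            pool = sorted(used)
            for _ in range(int(rng.integers(0, 4))):
                pair = tuple(rng.choice(pool, size=2))
                if any(paramset.canonical_pair(b.types) ==
                       paramset.canonical_pair(pair) for b in doc.bonds):
                    continue
                doc.bonds.append(BondParam(
                    types=pair, k_r=round(float(rng.uniform(100, 700)), 1),
                    r_eq=round(float(rng.uniform(0.9, 1.9)), 4)))
            if len(pool) >= 2:
                trip = (pool[0], pool[-1], pool[0])
                doc.angles.append(AngleParam(
                    types=trip, k_theta=round(float(rng.uniform(30, 90)), 3),
                    theta_eq=round(float(rng.uniform(90, 130)), 3)))
                doc.torsions.append(Torsion(
                    types=("X", pool[0], pool[-1], "X"),
                    terms=[TorsionTerm(
                        paths_divisor=int(rng.integers(1, 7)),
                        half_barrier=round(float(rng.uniform(0, 16)), 3),
                        phase=float(rng.choice([0, 180])),
                        periodicity=int(rng.integers(1, 4)))]))
            text = write_frcmod(doc)
            parsed = parse_frcmod(text)
            assert parsed == doc
            assert write_frcmod(parsed) == text

    def test_empty_document_emits_header_and_sections(self):
        text = write_frcmod(FrcmodDocument(title="empty"))
        assert text.startswith("empty\n")
        for section in ("MASS", "BOND", "ANGLE", "DIHE", "IMPROPER", "NONBON"):
            assert f"\n{section}\n" in text or text.split("\n")[1] == section
        assert parse_frcmod(text) == FrcmodDocument(title="empty")

    def test_duplicate_bond_refuses_to_write(self):
        doc = FrcmodDocument()
        doc.nonbonded.append(NonbondedParam("cc", 12.01, 0.36, 1.908, 0.086))
        doc.nonbonded.append(NonbondedParam("cd", 12.01, 0.36, 1.908, 0.086))
        doc.bonds.append(BondParam(("cc", "cd"), 500.9, 1.3729))
        doc.bonds.append(BondParam(("cd", "cc"), 400.0, 1.40))
        with pytest.raises(FrcmodError, match="cc-cd|cd-cc"):
            write_frcmod(doc)

    def test_invariant_violation_names_entry(self):
        doc = FrcmodDocument()
        doc.nonbonded.append(NonbondedParam("cc", 12.01, 0.36, 1.908, 0.086))
        doc.bonds.append(BondParam(("cc", "cc"), 500.0, 5.0))
        with pytest.raises(FrcmodError, match="cc-cc"):
            write_frcmod(doc)

    def test_missing_mass_for_referenced_type(self):
        doc = FrcmodDocument()
        doc.bonds.append(BondParam(("cc", "cd"), 500.9, 1.3729))
        with pytest.raises(FrcmodError, match="cc"):
            write_frcmod(doc)

    def test_unknown_section_rejected(self):
        with pytest.raises(FrcmodError, match="FOO"):
            parse_frcmod("title\nFOO\n")

    def test_non_numeric_field_names_line(self):
        text = "t\nMASS\ncc 12.01 0.36\n\nBOND\ncc-cc    bad    1.4000\n"
        with pytest.raises(FrcmodError, match="line 6"):
            parse_frcmod(text)

    def test_continuation_rows_parse_into_one_torsion(self):
        text = (
            "t\nMASS\ncc 12.01 0.36\n\nNONBON\n  cc 1.9080 0.0860\n\nDIHE\n"
            "cc-cc-cc-cc    1    0.112       0   -2\n"
            "cc-cc-cc-cc    1    0.406     180    1\n"
        )
        doc = parse_frcmod(text)
        assert len(doc.torsions) == 1
        assert len(doc.torsions[0].terms) == 2
        assert doc.torsions[0].terms[0].periodicity == -2


class TestLookup:
    def test_bond_reversal_symmetry_over_all_entries(self, builtin_doc):
        for b in builtin_doc.bonds:
            assert lookup(builtin_doc, "bond", tuple(reversed(b.types))) is b

    def test_angle_reversal_symmetry_over_all_entries(self, builtin_doc):
        for a in builtin_doc.angles:
            assert lookup(builtin_doc, "angle", tuple(reversed(a.types))) is a

    def test_wildcard_torsion_match(self, builtin_doc):
        t = lookup(builtin_doc, "torsion", ("ha", "cc", "cd", "N"))
        assert t.types == ("X", "cc", "cd", "X")
        term = t.terms[0]
        assert (term.paths_divisor, term.half_barrier, term.phase,
                term.periodicity) == (4, 16.0, 180.0, 2)

    def test_explicit_beats_wildcard(self, builtin_doc):
        t = lookup(builtin_doc, "torsion", ("cd", "CX", "3C", "CT"))
        assert not t.is_wildcard and len(t.terms) == 4

    def test_explicit_over_wildcard_exhaustive(self, builtin_doc):
        # every explicit quadruple that a wildcard entry also covers must
        # still resolve to the explicit entry, forward and reversed
        for t in builtin_doc.torsions:
            if t.is_wildcard:
                continue
            assert lookup(builtin_doc, "torsion", t.types) is t
            assert lookup(builtin_doc, "torsion", tuple(reversed(t.types))) is t

    def test_improper_central_atom_fixed_others_unordered(self, builtin_doc):
        entry = lookup(builtin_doc, "improper", ("CX", "c", "nd", "cd"))
        assert entry.types == ("c", "cd", "nd", "CX")
        # central atom mismatch must not match even with same neighbor set
        with pytest.raises(LookupError_):
            lookup(builtin_doc, "improper", ("c", "nd", "cd", "CX"))

    def test_improper_wildcards_match_anything(self, builtin_doc):
        entry = lookup(builtin_doc, "improper", ("cc", "nd", "c", "o"))
        assert entry.types == ("X", "X", "c", "o")
        assert entry.half_barrier == 10.5

    def test_not_found_names_the_tuple(self, builtin_doc):
        with pytest.raises(LookupError_, match="zz-zz"):
            lookup(builtin_doc, "bond", ("zz", "zz"))
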