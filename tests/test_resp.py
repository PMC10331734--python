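import numpy as np
import pytest

from conftest import constraint_satisfying_charges, generic_charges, grid_for
from xfpchrom import resp, synthetic
from xfpchrom.chem_model import Atom, Structure
from xfpchrom.resp import (
    BOHR_PER_ANGSTROM,
    ChargeConstraint,
    ConstraintScheme,
    EspGrid,
    RespConfig,
    RespError,
    RespModel,
    esp_from_point_charges,
    fit_two_stage,
    methyl_methylene_groups,
    read_esp_file,
    read_plain_grid,
    relative_rms_fit,
    scheme_amide_fix,
    scheme_cap_fix,
    scheme_free_fit,
    solve_stage,
    write_charge_table,
    write_esp_file,
)

A0 = RespConfig(restraint_a_stage1=0.0, restraint_a_stage2=0.0)


class TestForwardModel:
    def test_unit_charge_coulomb_law(self):
        v = esp_from_point_charges([1.0], [[0, 0, 0]], [[2.0, 0, 0]])
        assert v[0] == pytest.approx(0.5)

    def test_zero_charges_zero_potential(self):
        v = esp_from_point_charges([0.0, 0.0], [[0, 0, 0], [1, 0, 0]],
                                   [[3, 0, 0], [0, 3, 0]])
        np.testing.assert_array_equal(v, 0.0)

    def test_dipole_matches_direct_summation(self):
        pos = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        q = np.array([0.4, -0.4])
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=5.0, size=(30, 3)) + [0.75, 0, 0]
        v = esp_from_point_charges(q, pos, pts)
        for k, p in enumerate(pts):
            direct = sum(qi / np.linalg.norm(p - ri) for qi, ri in zip(q, pos))
            assert v[k] == pytest.approx(direct, abs=1e-12)

    def test_coincident_point_rejected(self):
        with pytest.raises(RespError, match="coincides"):
            EspGrid(atom_positions=[[0, 0, 0]], grid_points=[[0, 0, 0]],
                    potentials=[1.0])


class TestRelativeRms:
    def test_generating_charges_fit_perfectly(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        q = [0.3, -0.3]
        grid = synthetic.gen_esp_fixture(q, pos, synthetic.FixtureSpec(seed=1))
        assert relative_rms_fit(grid, q) == pytest.approx(0.0, abs=1e-12)

    def test_zero_charges_give_unity(self):
        pos = np.array([[0.0, 0, 0]])
        grid = synthetic.gen_esp_fixture([0.5], pos, synthetic.FixtureSpec(seed=2))
        assert relative_rms_fit(grid, [0.0]) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        pos = np.array([[0.0, 0, 0], [2.5, 0, 0], [0, 2.5, 0]])
        q = np.array([0.2, -0.5, 0.3])
        grid = synthetic.gen_esp_fixture(q, pos, synthetic.FixtureSpec(seed=3))
        q_pert = q + [0.05, -0.02, -0.03]
        model = grid.design_matrix() @ q_pert
        direct = np.sqrt(np.sum((grid.potentials - model) ** 2)
                         / np.sum(grid.potentials**2))
        assert relative_rms_fit(grid, q_pert) == pytest.approx(direct, abs=1e-14)

    def test_all_zero_reference_rejected(self):
        grid = EspGrid(atom_positions=[[0, 0, 0]], grid_points=[[2, 0, 0]],
                       potentials=[0.0])
        with pytest.raises(RespError, match="zero"):
            relative_rms_fit(grid, [0.0])


class TestSolveStage:
    def test_single_atom_charge_forced_by_total(self):
        grid = synthetic.gen_esp_fixture([-1.0], [[0.0, 0, 0]],
                                         synthetic.FixtureSpec(seed=4))
        q, _ = solve_stage(grid, [], 0.0, 0.1, total_charge=-1.0)
        assert q[0] == pytest.approx(-1.0, abs=1e-12)

    def test_generator_recovery_unrestrained(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(scale=3.0, size=(6, 3))
        q_true = generic_charges(6, 60)
        grid = synthetic.gen_esp_fixture(q_true, pos,
                                         synthetic.FixtureSpec(seed=6))
        q, _ = solve_stage(grid, [], 0.0, 0.1, total_charge=0.0)
        np.testing.assert_allclose(q, q_true, atol=1e-6)

    def test_equivalence_forces_equal_charges(self):
        # antisymmetric charges, symmetric positions: the equivalence
        # constraint must still yield exactly equal charges
        pos = np.array([[-1.5, 0, 0], [1.5, 0, 0]])
        grid = synthetic.gen_esp_fixture([0.4, -0.4], pos,
                                         synthetic.FixtureSpec(seed=7))
        q, _ = solve_stage(grid, [ChargeConstraint("equivalence", (0, 1))],
                           0.0, 0.1, total_charge=0.0)
        assert q[0] == pytest.approx(q[1], abs=1e-12)

    def test_fix_constraint_is_exact(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0]])
        grid = synthetic.gen_esp_fixture([0.1, 0.2, -0.3], pos,
                                         synthetic.FixtureSpec(seed=8))
        q, _ = solve_stage(grid, [ChargeConstraint("fix", (1,), 0.7)],
                           0.001, 0.1, total_charge=0.0)
        assert q[1] == pytest.approx(0.7, abs=1e-12)
        assert q.sum() == pytest.approx(0.0, abs=1e-10)

    def test_nonconvergence_reports_delta(self):
        grid = synthetic.gen_esp_fixture([0.3, -0.3],
                                         [[0.0, 0, 0], [2.0, 0, 0]],
                                         synthetic.FixtureSpec(seed=9))
        cfg = RespConfig(max_iterations=1)
        with pytest.raises(RespError, match="converge"):
            solve_stage(grid, [], 0.01, 0.1, total_charge=0.0, config=cfg)


class TestSchemes:
    def test_free_fit_one_equivalence_class_per_methyl(self):
        # minimal topology: one methyl carbon with 3 H, nothing else special
        atoms = [Atom(name="C1", element="C", position=[0, 0, 0])]
        for k, off in enumerate([[1, 0, 0], [0, 1, 0], [0, 0, 1]], start=1):
            atoms.append(Atom(name=f"H{k}", element="H", position=off))
        s = Structure(atoms=atoms, bonds=[(0, 1), (0, 2), (0, 3)])
        scheme = scheme_free_fit(s, 0)
        eq = [c for c in scheme.constraints if c.kind == "equivalence"]
        assert len(eq) == 1 and set(eq[0].atoms) == {1, 2, 3}

    def test_amide_fix_fixes_exactly_four_atoms(self, capped_topology):
        scheme = scheme_amide_fix(capped_topology, 0)
        fixed = scheme.fixed_atoms()
        assert len(fixed) == 4
        flags = {capped_topology.atoms[i].terminal_flag for i in fixed}
        assert flags == {"amide_N", "amide_H", "carbonyl_C", "carbonyl_O"}

    def test_proline_like_variant_fixes_cap_carbonyl(self, capped_topology_no_h):
        scheme = scheme_amide_fix(capped_topology_no_h, -1)
        fixed = scheme.fixed_atoms()
        names = {capped_topology_no_h.atoms[i].name for i in fixed}
        assert "CY" in names and "OY" in names  # ACE cap C=O
        n_idx = next(i for i, a in enumerate(capped_topology_no_h.atoms)
                     if a.terminal_flag == "amide_N")
        assert n_idx not in fixed  # the proline-like N stays free

    def test_cap_fix_needs_cap_annotations(self):
        atoms = [Atom(name="C1", element="C", position=[0, 0, 0]),
                 Atom(name="C2", element="C", position=[2, 0, 0]),
                 Atom(name="C3", element="C", position=[0, 2, 0])]
        s = Structure(atoms=atoms)
        with pytest.raises(RespError, match="cap_ACE"):
            scheme_cap_fix(s, 0)

    def test_conflicting_fixes_rejected(self):
        with pytest.raises(RespError, match="fixed to both"):
            ConstraintScheme("custom", [
                ChargeConstraint("fix", (0,), 0.1),
                ChargeConstraint("fix", (0,), 0.2),
            ], total_charge=0)


class TestTwoStage:
    def test_no_methyl_topology_stage2_is_noop(self):
        atoms = [Atom(name=f"C{i}", element="C", position=p)
                 for i, p in enumerate([[0, 0, 0], [2, 0, 0], [0, 2, 0]])]
        s = Structure(atoms=atoms)
        q_true = generic_charges(3, 30)
        grid = grid_for(s, q_true, seed=31)
        result = fit_two_stage(grid, s, scheme_free_fit(s, 0), A0)
        np.testing.assert_array_equal(result.charges, result.stage1_charges)
        np.testing.assert_allclose(result.charges, q_true, atol=1e-6)

    def test_cap_fix_generator_recovery(self, capped_topology):
        q_true = constraint_satisfying_charges(capped_topology, 40)
        grid = grid_for(capped_topology, q_true, seed=41)
        scheme = scheme_cap_fix(capped_topology, 0)
        result = fit_two_stage(grid, capped_topology, scheme, A0)
        np.testing.assert_allclose(result.charges, q_true, atol=1e-6)
        assert result.relative_rms_fit < 1e-8

    def test_restraint_shrinks_restrained_magnitudes(self, capped_topology):
        q_true = generic_charges(capped_topology.n_atoms, 50)
        grid = grid_for(capped_topology, q_true, seed=51)
        heavy = [i for i, a in enumerate(capped_topology.atoms)
                 if a.element.upper() != "H"]
        scheme = scheme_free_fit(capped_topology, 0)
        sums = []
        for a in (0.0, 0.001, 0.005, 0.01):
            cfg = RespConfig(restraint_a_stage1=a, restraint_a_stage2=a)
            result = fit_two_stage(grid, capped_topology, scheme, cfg)
            sums.append(np.sum(np.abs(result.charges[heavy])))
        for lo, hi in zip(sums[1:], sums[:-1]):
            assert lo <= hi + 1e-10

    def test_charge_conservation_and_constraints(self, capped_topology):
        q_true = generic_charges(capped_topology.n_atoms, 70)
        grid = grid_for(capped_topology, q_true, seed=71)
        for builder, total in [(scheme_free_fit, 0), (scheme_cap_fix, 0),
                               (scheme_amide_fix, 0)]:
            scheme = builder(capped_topology, total)
            result = fit_two_stage(grid, capped_topology, scheme, RespConfig())
            assert result.charges.sum() == pytest.approx(total, abs=1e-8)
            for c in scheme.constraints:
                if c.kind == "fix":
                    assert result.charges[c.atoms[0]] == pytest.approx(
                        c.value, abs=1e-10)
                elif c.kind == "group_sum":
                    assert result.charges[list(c.atoms)].sum() == \
                        pytest.approx(c.value, abs=1e-8)
                elif c.kind == "equivalence":
                    vals = result.charges[list(c.atoms)]
                    np.testing.assert_allclose(vals, vals[0], atol=1e-10)

    def test_model_object_surface(self, capped_topology):
        q_true = generic_charges(capped_topology.n_atoms, 80)
        grid = grid_for(capped_topology, q_true, seed=81)
        result = RespModel(grid, capped_topology, "cap_fix",
                           total_charge=0).fit()
        assert result.scheme == "cap_fix"
        text = result.summary()
        assert "relative RMS fit" in text and "CAY" in text

    def test_atom_count_mismatch_rejected(self, capped_topology):
        grid = synthetic.gen_esp_fixture([0.0], [[0.0, 0, 0]],
                                         synthetic.FixtureSpec(seed=5))
        with pytest.raises(RespError, match="atoms"):
            fit_two_stage(grid, capped_topology,
                          scheme_free_fit(capped_topology, 0))


class TestMethylDetection:
    def test_caps_and_methylene_found(self, capped_topology):
        groups = methyl_methylene_groups(capped_topology)
        sizes = sorted(len(hs) for _c, hs in groups)
        assert sizes == [2, 3, 3]  # CB1 methylene + two cap methyls


class TestFileFormats:
    def test_esp_file_round_trip(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        grid = synthetic.gen_esp_fixture([0.25, -0.25], pos,
                                         synthetic.FixtureSpec(seed=12))
        grid2 = read_esp_file(write_esp_file(grid))
        np.testing.assert_allclose(grid2.atom_positions, grid.atom_positions,
                                   rtol=1e-6)
        np.testing.assert_allclose(grid2.potentials, grid.potentials, rtol=1e-6)

    def test_esp_header_count_mismatch(self):
        with pytest.raises(RespError, match="promises"):
            read_esp_file("    1     2\n  0.0 0.0 0.0\n  0.1 2.0 0.0 0.0\n")

    def test_plain_grid(self):
        pts, v = read_plain_grid("1.0 0.0 0.0 0.5\n0.0 2.0 0.0 0.25\n")
        assert pts.shape == (2, 3) and v[1] == pytest.approx(0.25)

    def test_charge_table_precision(self, capped_topology):
        q_true = generic_charges(capped_topology.n_atoms, 90)
        grid = grid_for(capped_topology, q_true, seed=91)
        result = fit_two_stage(grid, capped_topology,
                               scheme_free_fit(capped_topology, 0), A0)
        table = write_charge_table(result)
        first = table.splitlines()[0].split()
        assert first[0] == "CAY"
        assert len(first[1].split(".")[-1]) == 6  # six decimals

    def test_reference_constants_available(self):
        assert resp.CORNELL_PROLINE_N == -0.2548
        assert resp.PUBLISHED_PROLINE_LIKE_N["DsRed"] == -0.292329
        assert resp.PUBLISHED_PROLINE_LIKE_N["mCherry"] == -0.283649

    def test_bohr_conversion_constant(self):
        assert BOHR_PER_ANGSTROM == pytest.approx(1.8897, abs=1e-3)
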