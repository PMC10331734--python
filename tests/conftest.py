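import numpy as np
import pytest

from xfpchrom import paramset, resp, synthetic


@pytest.fixture(scope="session")
def builtin_doc():
    return paramset.builtin_parameter_set()


@pytest.fixture()
def capped_topology():
    return synthetic.gen_capped_topology(2, with_amide_h=True, seed=3)


@pytest.fixture()
def capped_topology_no_h():
    return synthetic.gen_capped_topology(2, with_amide_h=False, seed=5)


def generic_charges(n: int, seed: int) -> np.ndarray:
    """Zero-sum random charges that satisfy no scheme-specific constraint."""
    rng = np.random.default_rng(seed)
    q = rng.normal(scale=0.3, size=n)
    return q - q.mean()


def constraint_satisfying_charges(topology, seed: int,
                                  total_charge: float = 0.0) -> np.ndarray:
    """Random charges adjusted to satisfy the amide_fix constraint family:
    methyl/methylene hydrogen equivalence, zero cap sums, fixed terminal
    charges, and the requested total."""
    n = topology.n_atoms
    rng = np.random.default_rng(seed)
    q = rng.normal(scale=0.25, size=n)
    for _c, hs in resp.methyl_methylene_groups(topology):
        q[hs] = q[hs].mean()
    ace = [i for i, a in enumerate(topology.atoms) if a.role == "cap_ACE"]
    nme = [i for i, a in enumerate(topology.atoms) if a.role == "cap_NME"]
    ref = resp.DEFAULT_TERMINAL_CHARGES
    flags = {a.terminal_flag: i for i, a in enumerate(topology.atoms)
             if a.terminal_flag != "none"}
    q[flags["carbonyl_C"]] = ref["C"]
    q[flags["carbonyl_O"]] = ref["O"]
    if "amide_H" in flags:
        q[flags["amide_N"]] = ref["N"]
        q[flags["amide_H"]] = ref["H"]
    else:
        # proline-like variant pins the ACE carbonyl C=O instead
        cy = topology.index_of("CY")
        oy = topology.index_of("OY")
        q[cy] = ref["cap_C"]
        q[oy] = ref["cap_O"]
    # zero each cap by adjusting its methyl carbon only, so fixed cap
    # carbonyl values and hydrogen equivalences survive
    q[topology.index_of("CAY")] -= q[ace].sum()
    q[topology.index_of("CAT")] -= q[nme].sum()
    special = set(ace) | set(nme) | set(flags.values())
    for c, hs in resp.methyl_methylene_groups(topology):
        special |= {c} | set(hs)
    free = [i for i in range(n) if i not in special]
    q[free[0]] += total_charge - q.sum()
    return q


def grid_for(topology, charges, seed: int, noise_sd: float = 0.0,
             points_per_shell: int = 40):
    """ESP grid generated from known charges at the topology's geometry."""
    pos_bohr = topology.coords(0) * resp.BOHR_PER_ANGSTROM
    spec = synthetic.FixtureSpec(seed=seed, noise_sd=noise_sd,
                                 points_per_shell=points_per_shell)
    return synthetic.gen_esp_fixture(charges, pos_bohr, spec)
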