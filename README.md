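# xfpchrom

A force-field parameterization and validation toolkit for fluorescent-protein
(FP) chromophores, for molecular-modelling researchers who simulate GFP-family
proteins with Cornell-type AMBER force fields (ff14SB/ff19SB).

The chromophores of EGFP, EBFP, ECFP, EYFP, DsRed and mCherry form by backbone
cyclization into an imidazolidinone ring conjugated to the second residue's
sidechain — bonding that no standard protein force field describes. This
package provides:

* **The chromophore parameter set** as a typed database with AMBER `frcmod`
  emission, parsing, and wildcard-aware lookup: 22 bonds, 56 angles, 25
  torsions (40 Fourier terms), 13 impropers, and 10 gaff-style atom types
  (cc/cd impure-aromatic ring and bridge, ne/cf/nf conjugated extension for
  the DsRed/mCherry core, carbonyl-like c/o for the phenolate CZ–OH),
  covering all seven chromophore variants (EBFP in both HID and HIE
  histidine tautomers).
* **Constrained two-stage RESP charge fitting.** Charges minimize
  `Σ_k (V_k − Σ_i q_i/r_ik)² + Σ_i a(√(q_i²+b²) − b)` under linear
  constraints, with three schemes: *free fit* (hydrogen rotational
  equivalence + total charge), *cap fix* (ACE/NME capping groups forced
  neutral), and *amide fix* (terminal amide N–H and carbonyl C–O pinned to
  Cornell consensus charges; the proline-like N of DsRed/mCherry handled by
  pinning the adjacent ACE carbonyl instead).
* **Atom-type model scoring** — rank candidate equilibrium-bond-length
  models (cc/cd vs. standard-residue vs. ce/cf types) against reference
  geometries by bond-length RMSD.
* **Geometry** — internal coordinates, Kabsch superposition (proper
  rotations only), structure RMSD with separate alignment/scoring subsets,
  and the mean unsigned error of charge sets.
* **Trajectory validation** — internal-coordinate distributions with
  Gaussian center/σ summaries, classical-vs-reference comparison (Δcenter,
  Δcenter/σ, width ratio), equilibration SD/slope ratios, and beta-sheet
  count slopes.
* **Seedable synthetic fixtures** for all of the above (ESP grids from
  known charges, capped topologies, AR(1) angle series, jittered
  geometries).

Quantum chemistry (geometry optimization, ESP generation) and MD engines are
deliberately out of scope: the package consumes their outputs.

## Worked example

Emit the parameter set and fit charges on a synthetic capped fragment:

```python
from xfpchrom import paramset, resp, synthetic

doc = paramset.builtin_parameter_set()
print(paramset.lookup(doc, "bond", ("cc", "cd")).r_eq)   # 1.3729 (A)
text = paramset.write_frcmod(doc)                         # AMBER frcmod text

topo = synthetic.gen_capped_topology(1, with_amide_h=True, seed=0)
pos_bohr = topo.coords(0) * resp.BOHR_PER_ANGSTROM
grid = synthetic.gen_esp_fixture(
    [0.0] * topo.n_atoms, pos_bohr, synthetic.FixtureSpec(seed=2))
# (in real use the grid comes from a QM ESP file: resp.read_esp_file)

result = resp.RespModel(grid, topo, "amide_fix", total_charge=0).fit()
print(result.summary())
```

On a grid generated from charges that satisfy the amide-fix constraints this
prints (abridged):

```
RESP fit (amide_fix)
  atoms: 21   iterations: 8
  relative RMS fit: 0.001526
  total charge: +0.000000 e

  atom       stage 1 (e)     final (e)
  CAY          -0.297473     -0.297476
  HY1          -0.014121     -0.013451
  HY2          -0.013513     -0.013451
  HY3          -0.012723     -0.013451
  ...
  N1           -0.415700     -0.415700
  H1            0.271900      0.271900
```

Reading the output: the three ACE methyl hydrogens (HY1–3) differ slightly
after stage 1 and are exactly equivalenced by the stage-2 refit; the terminal
amide pair N1/H1 sits exactly at the Cornell consensus values (−0.4157,
+0.2719 e) because the amide-fix scheme pins them; the total charge is the
requested integer to solver precision; and the relative RMS fit is the
residual of the model potential against the grid.

The same operations are available from the shell:

```sh
xfpchrom emit-frcmod --out chromophores.frcmod
xfpchrom resp-fit --esp grid.esp --topology chro.pdb --scheme amide_fix \
    --total-charge -1 --out charges.txt
xfpchrom score-types --structure ref.pdb --models models/ --bond-map bonds.txt
xfpchrom compare-structures ref.pdb opt.pdb --align-subset rings.txt
xfpchrom validate-angles --traj md.pdb --ref-traj qmmm.pdb --defs angles.defs
```

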