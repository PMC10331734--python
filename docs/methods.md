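# Methods

`xfpchrom` packages the force-field machinery needed to parameterize and
validate fluorescent-protein (FP) chromophores for Cornell-family AMBER
force fields (ff14SB/ff19SB): the published chromophore parameter set with
frcmod emission, constrained two-stage RESP charge fitting, atom-type model
scoring, rigid-body superposition, and trajectory distribution comparison.
This note records the models, the numerical choices, and what the
synthetic fixtures do and do not demonstrate.

## The parameter database

GFP-family chromophores form by backbone cyclization of three residues
into a five-membered imidazolidinone ring conjugated through a bridging
carbon to the second residue's sidechain. The resulting bonding patterns
have no counterpart in standard protein force fields, so the atoms of the
ring, the bridge, and (for deprotonated-tyrosine chromophores) the
phenolate sidechain carry gaff-style atom types: cc/cd (impure aromatic)
for the ring and bridge, ce/cf-style conjugated types (ne, cf, nf) for the
extended conjugation of the DsRed/mCherry core, and carbonyl-like c/o for
the phenolate CZ–OH bond, whose bond order is closer to a C=O than a
phenol C–OH. Everything the base force field already describes is left to
the base force field.

The builtin document carries exactly the published supplement to
ff14SB/ff19SB: 22 bond, 56 angle, 40 dihedral-row (25 logical torsions,
six of them four-component Fourier series for sidechain rotamers), 13
improper, and 10 nonbonded/mass entries, with gaff 1.81 and
ff14SB/PARM10/PARM19 provenance recorded per entry. Values are stored as
the printed strings alongside their float interpretation, so the frcmod
emitter reproduces the published table digits exactly and
`write -> parse -> write` is byte-identical.

Document validation enforces: positive force constants, physically
bounded equilibrium values, no duplicate keys after canonical tuple
ordering (a bond/angle and its reversal are one key; an improper is keyed
by its central third atom plus the unordered remaining three), AMBER
continuation structure for multi-term torsions (negative periodicity on
all but the last term), and MASS/NONBON coverage for every *new* atom
type. "New" means the lowercase gaff-style types; types containing an
uppercase letter (CX, 2C, 3C, C, N, O, H1, CC, C\*, ...) are assumed to
come from the loaded base force field, which is the design premise of the
parameter set itself.

Lookup follows AMBER matching semantics: bonds/angles match under
reversal; torsion lookup prefers fully explicit quadruples (forward or
reversed) over wildcard `X-b-c-X` entries; improper lookup keeps the
central atom fixed and treats the other three as an unordered set with
wildcards matching anything.

## RESP charge fitting

Atom-centered charges q are fit to an electrostatic potential sampled at
grid points k by minimizing

    chi^2 = sum_k (V_k - sum_i q_i / r_ik)^2
            + sum_i a (sqrt(q_i^2 + b^2) - b),

in atomic units, subject to linear equality constraints. The hyperbolic
restraint pulls charges toward zero without the discontinuity of an L1
penalty; because its curvature depends on q, the solver iterates linear
solves of the restrained normal equations — the restraint contributes
`a / sqrt(q_i^2 + b^2)` to the diagonal — with Lagrange-multiplier rows
for the constraints, until `max |dq| < 1e-6 e` (at most 200 iterations;
defaults exposed in `RespConfig`). Frozen atoms are moved to the
right-hand side and removed from the variable set.

Defaults follow the canonical two-stage RESP protocol: stage 1 fits all
atoms with `a1 = 0.0005` au and the scheme's fix/group-sum constraints;
stage 2 refits only methyl/methylene carbons and their hydrogens (found
from the bond graph: carbons bearing two or three hydrogens) with
`a2 = 0.001` au, hydrogen equivalence enforced, and everything else
frozen at stage-1 values. `b = 0.1` au; hydrogens are unrestrained. All
of these are configuration, not constants.

Three schemes of increasing strictness mirror how FP chromophore charges
are prepared for MD:

* **free_fit** — only rotational equivalence of methyl/methylene
  hydrogens plus the total molecular charge. The best fixed-charge
  representation of the ESP; the quality reference for the others.
* **cap_fix** — adds a zero-sum constraint over each of the ACE and NME
  capping groups, so the caps can be deleted leaving an integer-charge
  residue.
* **amide_fix** — additionally pins the terminal amide N/H and carbonyl
  C/O to the neutral-consensus backbone charges of the Cornell family
  (read from force-field data, `DEFAULT_TERMINAL_CHARGES`), making the
  residue's termini electrostatically consistent with its neighbors.
  When the chromophore's amino terminus carries no hydrogen (DsRed,
  mCherry — a proline-like nitrogen), there is no consensus charge for
  that N; it is left free and the carbonyl C and O of the adjacent ACE
  cap are pinned instead, giving the nitrogen a balanced environment.
  The Cornell proline N value (−0.2548 e) and the published fitted
  values for the two proline-like chromophore nitrogens are shipped as
  validation references only.

Cap methyl hydrogens are equivalenced within each cap but never across
groups; a flag (`equivalence_within_caps=False`) removes cap equivalences
entirely for users who read the cap exception more strictly.

**A note on scheme ordering.** Because the three constraint sets are
nested, the *exact* constrained least-squares solution can only get worse
(in relative RMS against the ESP) from free_fit to cap_fix to amide_fix.
That ordering is a theorem only for the unrestrained single-stage
minimizer. The restrained two-stage pipeline tracks it closely but can
violate it by a fraction of a percent, because stage 2 runs against
scheme-dependent frozen backgrounds and the restraint biases charges
toward zero — pinning an atom at a value the restraint would otherwise
shrink can *improve* the fit. Tests assert the ordering on the exact
minimizer and the constraint algebra (charge conservation to 1e-8 e,
exact fixes, uniform equivalence classes) on the full pipeline.

Relative fit quality is `sqrt(sum (V - V_model)^2 / sum V^2)`.

`RespModel(grid, topology, scheme).fit()` is the object-style surface;
it returns the same `RespResult` (charges, stage-1 charges, relative RMS,
iteration count) as the functional `fit_two_stage`, plus a `summary()`
table.

## Geometry and model scoring

Internal coordinates use the standard conventions: dihedrals follow the
right-hand rule about the central bond, in (−180°, 180°], with the same
sign viewed from either end (the sign flips under mirror reflection, not
traversal reversal); impropers are the dihedral i–j–k–l with the third
atom central, so planar trigonal centers read 180°. Superposition is the
Kabsch SVD solution with a determinant sign correction so reflections are
never returned — chirality is preserved even when a mirror image would
superpose better. Structure comparison reports RMSD over all atoms, heavy
atoms, and the alignment subset separately, because alignment on the
conjugated rings and scoring over all heavy atoms are different sets.

Atom-type model selection scores each candidate set of equilibrium bond
lengths against a measured (QM-optimized or crystal) geometry by RMSD
over a named bond subset and ranks ascending. Exact ties defer to a
configurable priority (cc/cd, then standard-residue types, then ce/cf —
matching how the chromophore core and unchanged sidechains were decided)
and are flagged. The shipped EGFP bond list covers the conjugated units
(imidazolidinone ring + carbonyl, bridge, phenolate ring, CZ–OH);
reproducing published RMSD tables additionally requires the reference
geometries, which are not printed and must be supplied by the user.

## Trajectory validation

Angle series are extracted per frame; dihedral series are re-wrapped onto
a branch centered at the circular mean so unimodal distributions
straddling ±180° stay contiguous (each value moves only by multiples of
360°). Distributions are summarized by a Gaussian fit to the histogram
(default bins: 2° for bond angles, 5° for ordinary dihedrals, 15° for the
wide ring-planarity dihedral), initialized at the sample moments, falling
back to the moments with `converged=False` if the optimizer fails.
Comparison between a classical and a reference (QM/MM) trajectory reports
the center shift, the shift in units of the reference sigma, and the
width ratio.

Equilibration is diagnosed by the ratio of the standard deviation to the
absolute OLS slope over a trailing window (conventionally > 50 for
structural RMSD, > 1000 for density/energy series); the ratio is
invariant under affine rescaling of the series, and a constant window is
flagged as infinite rather than divided through by a ~1e-16 slope.
Beta-barrel integrity uses the OLS slope of per-frame beta-sheet residue
counts in residues/μs; secondary-structure assignment itself is out of
scope — the function consumes externally produced counts.

## Synthetic fixtures

All generators are pure functions of (inputs, seed). ESP fixtures place
grid points on shells at 1.4–2.0× a nominal atomic radius (the standard
scaled-surface convention), drop points inside another atom's sphere, and
evaluate exact Coulomb potentials with optional Gaussian noise; a
noise-free grid with ≥4× more points than atoms makes charge recovery a
sharp test (recovered to ~1e-12 e in practice, asserted at 1e-6 e).
Capped topologies provide ACE/NME caps with methyls, an optional amide
hydrogen, and full role/terminal annotations — chemically plausible
connectivity over jittered chain coordinates, not optimized geometry.
Angle series are stationary AR(1) processes with the requested marginal
mean and SD.

What passing these tests shows: the solver, constraint algebra, emitters,
and estimators are correct on inputs whose ground truth is known. What
they do not show: anything about QM ESPs (real ESPs are not exactly
representable by atom-centered point charges, so real fits have
irreducible residual), about force-field accuracy against experiment, or
about MD sampling — the package deliberately contains no QM or MD engine.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
20-seed batches of 10^5-sample Gaussian recoveries, RESP fixtures of
3–25 atoms with ~160 grid points per atom, 100 random ranking fixtures,
and 50 randomized frcmod round trips. These sizes put the statistical
assertions (e.g. mean center error < 0.1° at sigma 5°) comfortably inside
their expected sampling fluctuation.

## Known limitations

* Per-atom type assignments and the 30-angle definition sets for each
  chromophore live in supplementary material that is not machine-readable
  here; the shipped EGFP annotation and bond files cover only what the
  primary text establishes, and complete files must be transcribed by the
  user.
* The frcmod parser reads the dialect this package emits (plus whitespace
  tolerance); it is not a general AMBER parm-file reader.
* ESP grids must be in atomic units; no unit sniffing is attempted.
* The Gaussian summary assumes near-unimodal distributions; strongly
  multimodal angles are better inspected as histograms.
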