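# Methods

## Structures and the tri-dimer

Input structures are PDB or mmCIF files read with gemmi.  Only protein
chains are kept; waters, heteroatoms, nucleic acids and hydrogens are
dropped.  Alternate locations resolve to the highest-occupancy conformer,
ties broken by the alphabetically first alt-loc label.  Residues with no
heavy atom are removed, and chains of one assembly may differ in length —
all metrics operate on what is present.  When a deposition contains only
the icosahedral asymmetric unit, the biological-assembly operators (BIOMT /
`pdbx_struct_assembly`) expand it; rotations are checked for orthonormality
to 1e-6.  Deposited full assemblies are preferred over expansion; a CLI
flag forces expansion.  Coordinates are Ångström internally; center-of-mass
distances are reported in nm.

The tri-dimer — one IAU (A, B, C) plus the two-fold partner of each IAU
chain — is found deterministically: the IAU is the mutually contacting
chain triple, one chain per conformer label where labels exist, whose three
internal relative rotations are all within tolerance of 120° (the
quasi-three-fold relation), preferring the triple with the largest total
inter-chain contact count and breaking ties by lexicographic chain labels.
Each flank chain is the contacting partner of an IAU chain with relative
rotation within tolerance of 180°, again by maximal contact count.  The
original study extracted tri-dimers manually; a deterministic rule replaces
that judgment call.

## Contacts

Two residues are in contact when any two of their heavy atoms lie within
4.5 Å.  Atomic contacts are found with a k-d tree and projected onto unique
residue pairs; intra-chain pairs with sequence separation below 3 are
discarded (they are covalently constrained).  The surface-complementarity
criterion of the CSU program used in earlier interface work is deliberately
not reproduced: the distance criterion is simpler, fully reproducible, and
the downstream quantities are compared against bounded ranges that tolerate
criterion differences.  The criterion is a configuration object
(`ContactParams`) so an alternative backend can be swapped in; a
`shadow` method name is reserved but not implemented.

## Interface metrics

With residue-contact counts `N_intra(x)`, `N_intra(y)`, `N_inter(xy)`:

* `R = N_inter / (0.5 (N_intra(x) + N_intra(y)))` — interface size relative
  to the average monomer core.  Undefined (error) when both intra counts
  are zero; 0 when there is no interface.
* `H` — the mean hydrophobicity factor over the `2 N_inter` residue
  incidences of the interface, one incidence per side per residue contact,
  so a residue in several contacts is counted several times.  Undefined
  when `N_inter = 0`; at the pipeline level such pairs appear as
  "no interface" rows rather than errors.

The hydrophobicity scale maps each residue to `h ∈ [0, 1]`.  The
literature source for the original factor table is not printed in the work
this package follows, so the default is the Kyte–Doolittle sidechain scale
min–max normalized to [0, 1] (ILE = 1, ARG = 0) — a standard, monotone
stand-in; the scale is a named, swappable object and all comparisons
against literature values use interval bounds rather than points.  The
non-polar set for composition summaries is
{ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, GLY}, configurable.

Fold-regime classification uses the empirical line `H/0.5 + R/1.8 = 1`
(x = R, y = H): above the line lies with two-state folding homodimers,
below with three-state; a 1e-9 tolerance defines "on the line".

## Symmetry classification

For a contacting chain pair, the Cα atoms of residues shared by author
numbering (conformers of one CP share numbering; no sequence alignment) are
superposed by least squares (Kabsch, proper rotation enforced); at least 30
shared residues are required.  The rotation angle assigns the class by the
nearest canonical angle — 180° dimerization, 120° trimerization, 72°
pentamerization, 60° hexamerization — within a tolerance, default 12°, set
by the inexactness of the quasi-axes in real capsids.  Nearest-angle
assignment matters because the 60° and 72° bands touch at that tolerance.
Contact filtering disambiguates the ~120° relations: only pairs that
physically touch are classified, so the two-steps-around-a-six-fold pairs
never appear.  Classes are symmetric in argument order.

## The Cα structure-based model

Each residue becomes one bead at its Cα (mass 1).  Reduced units: energies
in ε = 1, lengths in Å, k_B = 1, time in τ = √(mÅ²/ε).  The potential is
the canonical Cα Gō form:

| term | form | constant |
|---|---|---|
| bond | k_b (r − r0)² | k_b = 100 ε/Å² |
| angle | k_a (θ − θ0)² | k_a = 20 ε/rad² |
| dihedral | k_d[1 − cos(φ−φ0)] + (k_d/2)[1 − cos 3(φ−φ0)] | k_d = 1 ε |
| native contact | ε[5(σij/r)¹² − 6(σij/r)¹⁰] | σij = native distance |
| non-native | ε(σ_rep/r)¹², force-shifted, cut at r_c | σ_rep = 4 Å, r_c = 7 Å |

Native contacts are the residue contacts of the input structure (intra-chain
additionally requiring sequence separation ≥ 4 so they do not overlap the
bonded terms); for CA-only inputs a CA–CA cutoff around 8 Å is the
appropriate contact criterion.  Bead pairs already within r_c in the native
structure are part of the native environment and carry no repulsion; with
the force-shifted truncation this makes the native configuration an exact
stationary point of the potential (verified to < 1e-6 ε/Å), at the cost of
leaving those few pairs sterically unprotected — harmless for folded-basin
sampling, which is the only regime in scope.

Dynamics use the BAOAB Langevin splitting, timestep 0.0005 τ, friction
1 τ⁻¹, seed mandatory; with friction 0 the integrator reduces to velocity
Verlet (energy drift ~1e-4 ε per 1e5 steps, used as a correctness check).
The folded-basin sampling temperature defaults to 0.5 ε/k_B — about half
the folding temperature of typical Cα Gō proteins at ε = 1.  An
`estimate_folding_temperature` helper (heat-capacity peak on a short
temperature scan) is provided for calibrating other systems, but the
pipeline does not run it by default: a per-run scan would multiply the cost
several-fold without changing folded-basin statistics.

The COM distance between the two chains (equal bead masses) is computed per
saved frame in nm and histogrammed with 0.01 nm bins anchored at 0.00 nm;
the first 10 % of frames are discarded as burn-in.  Default production runs
in this repository use 2–6 × 10⁵ steps saving every 500 — problem sizes
chosen so the whole suite completes in minutes while the mean is converged
and the sd stable to within a few percent (the mean is structure-dominated;
the sd is temperature- and length-sensitive and is treated as an ordering
observable, not a point estimate).

## Synthetic data

The synthetic T=3 lattice places copies of a placeholder chain at 180
positions: a template triple (A, B, C) transformed by the 60 proper
rotations of the icosahedral group (generated by closure from a five-fold
and a two-fold rotation).  The unit-sphere template positions and the B/C
template orientations are frozen design constants obtained from a one-off
numerical optimization: positions maximize the separation between the eight
designed neighbour distance types and the closest spurious pair
(designed 0.237–0.272, spurious 0.440 in circumradius units, a 1.6× gap);
orientations minimize the squared deviations of the six quasi-symmetry
angles (three trimer 120°, the A–B dimer 180°, two hexamer 60°) with
sub-degree residuals.  The exact-symmetry relations (C–C dimer at 180°,
pentamer neighbours at 72°) hold automatically by group theory.  Two
distinct hexamer pair orbits are designed — around each quasi-six-fold ring
the B and C chains of six different IAUs alternate — which is what puts two
hexamerization interfaces into one tri-dimer.

Each placeholder chain is a 30-residue Fibonacci-sphere shell (radius 7 Å,
one Cα per residue) plus five "arm" residues of three atoms whose tips
reach 1.75 Å short of each designed pair midpoint, so designed pairs touch
at 3.5 Å (inside the 4.5 Å cutoff, outside clash range) and nothing else
comes near contact.  A deterministic per-conformer distortion (default
0.25 Å) makes the quasi-axes measurably inexact, as in real capsids.
Default circumradius 72 Å keeps designed neighbours at 17–20 Å separation.
These chains exercise geometry, classification and counting; they are not
folded proteins, carry no realistic composition by default, and say nothing
about energetics — which is why the simulator is tested on separately
generated minimal dimers (parallel vs hinged helix pairs with broad vs
narrow planted interfaces) and why passing lattice tests demonstrates the
machinery, not biological accuracy, on real capsids.

Toy contact dimers place residue "homes" on a wide grid and realize each
planted residue contact with a dedicated satellite-atom pair 4 Å apart in
its own pocket, so the contact map reproduces the planted counts exactly
and composition is fully controllable.

## Numerical choices and degenerate inputs

Ties in IAU selection break lexicographically; empty chains in contact
queries warn and return empty rather than raising; interfaces with no
contacts are reported as rows, not errors; rotation axes near 0°/180° fall
back to an eigendecomposition; simulations abort with an instability error
if any coordinate exceeds 1e6 Å.  All random number use flows through
explicit seeds; lattices and trajectories are bit-reproducible given the
seed.

## Limitations

The distance contact criterion shifts absolute R values relative to
surface-complementarity criteria by a roughly constant factor; comparisons
should stay within one criterion.  The hydrophobicity scale is a documented
stand-in for an unidentified literature table, so H values carry a
scale-choice uncertainty absorbed by interval comparisons.  The simulator
covers native-basin flexibility only — no folding thermodynamics, no
electrostatics, ions, RNA or solvent.  Analyses of deposited capsids
require the user to supply the structure files; the library performs no
network access (the CLI `fetch` helper is the only, optional, downloader).
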