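# tridimer

Coat-protein interface taxonomy and dimer flexibility for T=3 icosahedral
virus capsids.

Simple non-enveloped viruses build their capsid from 180 copies of a single
coat protein (CP) arranged with icosahedral T=3 symmetry: three
quasi-equivalent conformers (A, B, C) per icosahedral asymmetric unit (IAU),
related by exact two-, three- and five-fold axes plus approximate
("quasi") two-, three- and six-fold axes.  How such a capsid assembles and
disassembles — many viruses dissociate into CP dimers (CP2) — is thought to
be governed by the comparative strength of the different CP–CP interfaces.
`tridimer` implements the structural analysis behind that question:

* **Tri-dimer extraction** — the six-chain minimal unit (one IAU plus the
  two-fold partner of each of its chains) contains every distinct CP–CP
  interface class; it is located automatically from a deposited assembly
  (with BIOMT expansion when only the asymmetric unit is deposited).
* **Interface classification** — each contacting chain pair is assigned to
  dimerization (~180°), trimerization (~120°), pentamerization (~72°) or
  hexamerization (~60°) from the angle of the least-squares rotation
  superposing one chain onto the other.
* **Interface metrics** — with residue-level contact counts
  `N_intra(x)`, `N_intra(y)`, `N_inter(xy)` (heavy-atom 4.5 Å criterion,
  atom pairs projected onto unique residue pairs):

  ```
  R(xy) = N_inter(xy) / (0.5 (N_intra(x) + N_intra(y)))          # size
  H(xy) = Σ_incidences h_i / (2 N_inter(xy)),   h_i ∈ [0, 1]     # hydrophobicity
  ```

  A residue taking part in k inter-chain contacts contributes k incidences.
  Homodimers with high (R, H) fold two-state; the reference line
  `H/0.5 + R/1.8 = 1` separates the regimes.
* **Dimer flexibility** — a Cα-bead structure-based (Gō-type) model of a
  CP2 dimer, sampled with Langevin dynamics in the folded basin; the width
  of the inter-monomer center-of-mass (COM) distance distribution
  (0.01 nm histogram bins) ranks interface flexibility.
* **Synthetic fixtures** — an exact icosahedral T=3 lattice of 180
  placeholder chains with the full designed interface census, and toy
  dimers with planted contact counts, so every stage has ground truth
  without downloads.

## Worked example

```python
from collections import Counter
from tridimer import (ContactParams, classify_interface, extract_tridimer,
                      make_t3_lattice, relative_transform)
from tridimer.structures import _contact_graph

lattice = make_t3_lattice()          # 180 chains, 60 per conformer
td = extract_tridimer(lattice)
sub = td.as_assembly()
census = Counter()
for x, y in sorted(_contact_graph(sub, ContactParams())):
    t = relative_transform(sub.chain(x), sub.chain(y))
    census[classify_interface(t)] += 1
print(dict(census))
```

prints

```
{'pentamerization': 1, 'trimerization': 3, 'dimerization': 3, 'hexamerization': 2}
```

— the tri-dimer carries three dimerization interfaces (A–B across the
quasi-two-fold, C–C across the exact two-fold), the three trimer pairs of
the IAU, one pentamer-ring contact between the two A conformers, and two
hexamer-ring contacts (B and C chains of adjacent IAUs).  The scripts in
`examples/` walk through the metrics on a planted-contact dimer
(`R = 0.5000`, `H = 0.7000` for an all-alanine interface), this census, the
flexibility contrast between a broad- and a narrow-interface dimer
(COM-distance sd 0.016 nm vs 0.128 nm at the same temperature), and the
full pipeline on the four deposited capsids.

The command line mirrors the library: `tridimer analyze` (interface
tables), `tridimer flex` (COM distributions), `tridimer fixtures`
(synthetic data with ground-truth sidecars), `tridimer census`,
`tridimer fetch`.

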