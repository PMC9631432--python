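"""Full pipeline on deposited capsid structures (requires downloads).

Fetch the four representative T=3 capsids first (network required)::

    tridimer fetch 2MS2 1CWP 1C8N 1AUY

Then this script expands each asymmetric unit with its BIOMT operators,
extracts the tri-dimer, tabulates R / H / composition per interface class,
and simulates the CC dimer's center-of-mass distance distribution.
"""

from pathlib import Path

from tridimer import (ContactParams, RunConfig, SimParams,
                      run_flexibility, run_interface_analysis)
from tridimer.pipeline import _select_cp2
from tridimer.structures import (expand_assembly, extract_tridimer,
                                 read_biomt_operators, read_structure)

DATA = Path(__file__).resolve().parent.parent / "data" / "structures"
FAMILIES = {"2ms2": "Leviviridae", "1cwp": "Bromoviridae",
            "1c8n": "Tombusviridae", "1auy": "Tymoviridae"}

available = [p for pid in FAMILIES
             for p in [DATA / f"{pid}.cif", DATA / f"{pid}.pdb"] if p.exists()]
if not available:
    raise SystemExit(f"no structures under {DATA}; run `tridimer fetch` first")

config = RunConfig(inputs=available,
                   family_tags={p.stem: FAMILIES[p.stem] for p in available},
                   output_dir=Path("tridimer_out"))
table = run_interface_analysis(config)
print(table[["source", "family", "interface_class", "n_inter", "R", "H",
             "nonpolar_fraction", "fold_regime"]].to_string(index=False))

sim = SimParams(temperature=0.5, friction=1.0, n_steps=400_000,
                save_interval=500, seed=0)
for path in available:
    asm = read_structure(path)
    if len(asm) < 12:
        asm = expand_assembly(asm, read_biomt_operators(path))
    cc = _select_cp2(extract_tridimer(asm), "CC")
    trace, _ = run_flexibility(cc, RunConfig(sim_params=sim), ContactParams())
    print(f"{path.stem}: CC-CP2 COM mean={trace.mean:.2f} nm  "
          f"sd={trace.sd:.3f} nm  native={trace.native_value:.2f} nm")
# Expected pattern: the Leviviridae (MS2) dimerization interface has much
# larger R and H than any other interface, and its CP2 COM distribution is
# the narrowest; the Bromoviridae (CCMV) CP2 is the most flexible.
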