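"""Folded-basin flexibility of two dimers with different interface sizes.

Builds the CA structure-based model for a broad-interface (parallel
helices) and a narrow-interface (hinged) dimer, samples each with Langevin
dynamics at a folded-basin temperature, and compares the width of the
inter-monomer center-of-mass (COM) distance distributions.  A broader
distribution means a more flexible dimer interface.
"""

from tridimer import (ContactParams, RunConfig, SimParams,
                      make_sbm_test_dimer, run_flexibility)

sim = SimParams(temperature=0.5, friction=1.0, n_steps=300_000,
                save_interval=500, seed=0)
params = ContactParams(cutoff=8.0)  # CA-CA native-contact cutoff

for kind, label in (("parallel", "broad interface"),
                    ("hinge", "narrow interface")):
    trace, top = run_flexibility(make_sbm_test_dimer(kind),
                                 RunConfig(sim_params=sim), params)
    print(f"{label:17s} inter-chain contacts={top.n_inter_contacts:3d}  "
          f"COM mean={trace.mean:.3f} nm  sd={trace.sd:.3f} nm  "
          f"native={trace.native_value:.3f} nm")
# The narrow-interface dimer shows a several-fold larger COM-distance
# standard deviation: fewer native contacts across the interface leave the
# relative monomer motion less constrained.
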