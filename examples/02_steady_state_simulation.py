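"""Simulate antibody binding to both antigen strands by ODE integration.

Expands the chain rule set into its 64-state-per-strand reaction network,
integrates 100 copies of each strand against 1000 shared receptors for the
standard 10 s horizon, and reports per-strand occupancy distributions and
per-region binding probabilities.
"""

import numpy as np

from stericrules import (
    SimulationConfig,
    generate_rules,
    region_binding_probabilities,
    simulate,
    strand_size_distribution,
)
from stericrules.fixtures import default_rates, load_adjacency

rulesets = [
    generate_rules(adj, default_rates(k_f2=0.005))
    for adj in load_adjacency("native", d_c=8.0)
]
state = simulate(rulesets, SimulationConfig())
print(f"converged: {state.converged} (residual {state.residual:.2e} molecules/s)")
print(f"free receptors: {state.free_receptors}")

for strand in ("I", "II"):
    dist = strand_size_distribution(state, strand)
    print(f"\nstrand {strand} P(n bound regions): {np.round(dist, 4)}")
    probs = region_binding_probabilities(state, strand)
    print(f"per-region occupancy: "
          + ", ".join(f"{r}={p:.3f}" for r, p in probs.items()))

# Mirror-symmetric chain rules make (A,F), (B,E), (C,D) identical: the
# printed occupancies come in equal pairs.
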