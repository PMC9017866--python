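"""Simulate the FORC response of one magnetosome chain.

Builds a randomized single-stranded chain of equant magnetosomes, tracks
its local energy minimum through the full FORC protocol, and prints its
hysteresis parameters.
"""
import numpy as np

from chainforc import (ChainConfig, FieldProtocol, MAGNETITE, build_chain,
                       build_energy_model, orient_axis, simulate_forc,
                       write_forc_text)
from chainforc.variforc import (compute_forc_distribution,
                                extract_central_ridge, summary_stats)

rng = np.random.default_rng(1)
chain = build_chain(ChainConfig(n_crystals=15, seed=1))
chain = orient_axis(chain, [0.4, 0.2, 0.89], rng)  # oblique to the field
model = build_energy_model(chain, MAGNETITE)

grid = simulate_forc(model, protocol=FieldProtocol(b_sat=0.3, b_step=3e-3))
dist = compute_forc_distribution(grid)
extract_central_ridge(dist)
stats = summary_stats(grid, dist)

write_forc_text(grid, "chain_forc_grid.txt")
print(stats.as_series().to_string())
print(f"\n{len(grid.jumps)} Barkhausen jumps logged; the chain switches as "
      "one unit, so nearly all irreversible moment change sits in the "
      "central ridge (Mcr/Mforc close to 1).")
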