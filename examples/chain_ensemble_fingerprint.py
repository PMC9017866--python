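"""Magnetofossil fingerprint of a small single-stranded chain ensemble.

Simulates randomly oriented chains of equant magnetosomes with realistic
geometric scatter and extracts the diagnostic ratios.  (200+ chains at
2-3 mT steps reproduce the reference forward-model values; this example
uses 30 chains to stay quick.)
"""
from chainforc import (ChainConfig, EnsembleSampler, FieldProtocol, MAGNETITE,
                       ensemble_forc)
from chainforc.variforc import (compute_forc_distribution,
                                extract_central_ridge, summary_stats)

sampler = EnsembleSampler(base=ChainConfig())
grid = ensemble_forc(sampler, 30, MAGNETITE,
                     FieldProtocol(b_sat=0.3, b_step=3e-3), seed=11,
                     progress=True)
dist = compute_forc_distribution(grid)
extract_central_ridge(dist)
stats = summary_stats(grid, dist)

print(stats.as_series().to_string())
print("\nMrs/Ms near 0.5 with a dominant central ridge (Mcr/Mforc near 1) "
      "is the intact single-stranded chain fingerprint; flux-closure-prone "
      "architectures push Mcr/Mforc down toward 0.5.")
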