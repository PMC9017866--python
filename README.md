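# chainforc

Micromagnetic modelling of magnetosome-chain magnetic signatures — the
fingerprints by which fossil chains of bacterial magnetite
(magnetofossils) are recognized in sediments.

Magnetotactic bacteria assemble 30–70 nm single-domain magnetite crystals
into single- or multi-stranded chains.  After the cells die the chains
can survive in sediment, intact or collapsed, and their unusual
combination of magnetic properties — hysteresis squareness Mrs/Ms close
to 0.5 together with a sharp *central ridge* in first-order reversal
curve (FORC) diagrams — is a biosignature.  `chainforc` implements the
forward model behind that diagnostic:

* **Chain geometries** (`chainforc.chains`): randomized single strands,
  staggered native double strands, fold-collapsed side-by-side double
  strands, and rings, built from documented parameter distributions
  (sizes, gaps, tapering, misorientation, twist, bending).
* **Energetics** (`energy`, `demag`, `interactions`): one uniform moment
  per crystal; cubic magnetocrystalline + shape (demagnetizing tensors
  for ellipsoids and chamfered cylinders) + Zeeman + pairwise
  magnetostatic coupling, with exact point-dipole tensors for spheres and
  surface-charge quadrature for faceted crystals,

      F = Σᵢ (Fᵢᶜ + Fᵢˢ + Fᵢᶻ) + Σᵢ<ⱼ uᵢ·F₍ᵢⱼ₎·uⱼ .

* **FORC simulation** (`simulate`, `sw`): athermal local-energy-minimum
  tracking of full FORC protocols (±300 mT, millitesla steps) for single
  chains and stratified-orientation ensembles; a closed-form
  Stoner–Wohlfarth fast path for the classical uniaxial reference.
* **FORC analysis** (`variforc`): variable-smoothing estimation of
  ρ(B_c, B_u) = −½ ∂²M/∂B_r∂B, central-ridge isolation, the coercivity
  spectra f_cr / f_dcd / f_hys, and the summary ratios Mrs/Ms, Bcr/Bc,
  M_cr/M_rs, M_cr/M_forc.
* **Energy barriers** (`barriers`): string-method transition paths and
  Boltzmann factors β₀ = ΔE/kT for chain moment reversal, ring
  onion→flux-closure decay and double-strand reversal, plus the
  Néel–Arrhenius law τ = τ₀·exp(β₀) and dipolar blocking diameters.
* **Composites and RPI** (`composite`, `pipeline`, `cli`): mixtures of
  chain populations in saturation-magnetization fractions, the
  relative-paleointensity proxy formulas of the single-domain carrier
  architectures, an end-to-end configurable ensemble pipeline and a thin
  `chainforc` command-line interface.

## Worked example

```python
from chainforc import FieldProtocol, sw_forc_ensemble
from chainforc.variforc import (compute_forc_distribution,
                                extract_central_ridge, summary_stats)

grid = sw_forc_ensemble(n_particles=5000,
                        protocol=FieldProtocol(b_sat=0.3, b_step=2e-3),
                        seed=1)
dist = compute_forc_distribution(grid)
extract_central_ridge(dist)
stats = summary_stats(grid, dist)
print(f"Mrs/Ms    = {stats.squareness:.3f}")
print(f"Mcr/Mrs   = {stats.Mcr_over_Mrs:.3f}")
print(f"Mcr/Mforc = {stats.Mcr_over_Mforc:.3f}")
```

prints

```
Mrs/Ms    = 0.500
Mcr/Mrs   = 0.565
Mcr/Mforc = 0.917
```

— the Stoner–Wohlfarth reference ensemble: squareness exactly at the
random-uniaxial value 0.5, with the central ridge carrying essentially
all irreversible magnetization (M_cr/M_forc ≈ 1; the few-percent
shortfall is the documented grid-truncation residue).  Simulated
single-stranded magnetosome chains push M_cr/M_rs up to ≈ 0.70 because
in-chain coupling suppresses reversible moment rotation, while
flux-closure-prone double strands drop M_cr/M_forc toward 0.5 — the
contrast that lets mixtures of chain architectures be read off sediment
FORC data.

The `examples/` directory holds one short script per capability
(single-chain FORC, ensemble fingerprints, barriers and lifetimes,
composites and RPI proxies); each prints the quantities it computes and a
line on what they mean.  The `chainforc` CLI exposes the same pipeline
(`chainforc simulate-forc --config run.yaml`, `chainforc barriers ...`,
`chainforc analyze grid.txt`).

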