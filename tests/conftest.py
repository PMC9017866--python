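"""Shared fixtures.

The expensive simulated grids (Stoner-Wohlfarth reference ensemble and the
chain ensembles) are session scoped so the acceptance checks and the
property tests share one computation.
"""
from __future__ import annotations

import numpy as np
import pytest

from chainforc.chains import ChainConfig, ChainType, MagnetosomeType
from chainforc.constants import MAGNETITE
from chainforc.simulate import EnsembleSampler, FieldProtocol, ensemble_forc
from chainforc.sw import sw_forc_ensemble
from chainforc.variforc import (compute_forc_distribution, extract_central_ridge,
                                summary_stats)


def _analyzed(grid):
    dist = compute_forc_distribution(grid)
    extract_central_ridge(dist)
    return grid, dist, summary_stats(grid, dist)


@pytest.fixture(scope="session")
def sw_reference():
    """Athermal random-orientation Stoner-Wohlfarth FORC ensemble."""
    grid = sw_forc_ensemble(n_particles=10_000,
                            protocol=FieldProtocol(b_sat=0.3, b_step=2e-3),
                            seed=7)
    return _analyzed(grid)


def _chain_ensemble(mtype: MagnetosomeType, n_chains: int, seed: int):
    base = ChainConfig(chain_type=ChainType.SINGLE, magnetosome_type=mtype)
    sampler = EnsembleSampler(base=base)
    proto = FieldProtocol(b_sat=0.3, b_step=3e-3)
    grid = ensemble_forc(sampler, n_chains, MAGNETITE, proto, seed=seed)
    return _analyzed(grid)


@pytest.fixture(scope="session")
def equant_ensemble():
    """200 randomly oriented single-stranded chains of equant magnetosomes."""
    return _chain_ensemble(MagnetosomeType.EQUANT, 200, seed=11)


@pytest.fixture(scope="session")
def prismatic_ensemble():
    """200 randomly oriented single-stranded chains of prismatic magnetosomes."""
    return _chain_ensemble(MagnetosomeType.PRISMATIC, 200, seed=13)


@pytest.fixture(scope="session")
def squareness_by_type():
    """Mrs/Ms of the three linear architectures from major loops only,
    with the same stratified orientation sampling as the FORC ensembles."""
    import math

    from chainforc.chains import build_chain, orient_axis
    from chainforc.energy import build_energy_model
    from chainforc.simulate import sweep

    n_chains = 200
    out = {}
    for ctype in (ChainType.SINGLE, ChainType.DOUBLE_NATIVE, ChainType.DOUBLE_FOLDED):
        base = ChainConfig(chain_type=ctype, magnetosome_type=MagnetosomeType.EQUANT)
        sampler = EnsembleSampler(base=base)
        proto = FieldProtocol(b_sat=0.3, b_step=3e-3)
        mrs = 0.0
        ms = 0.0
        for i in range(n_chains):
            rng = np.random.default_rng(np.random.SeedSequence(17, spawn_key=(i,)))
            cfg = sampler.sample(rng)
            chain = build_chain(cfg, rng)
            cos_th = (i + rng.uniform()) / n_chains
            sin_th = math.sqrt(max(1.0 - cos_th * cos_th, 0.0))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            chain = orient_axis(chain, [sin_th * math.cos(phi),
                                        sin_th * math.sin(phi), cos_th], rng)
            model = build_energy_model(chain, MAGNETITE)
            b, md, _ = sweep(model, protocol=proto)
            iz = int(np.argmin(np.abs(b)))
            mrs += md[iz]
            ms += model.saturation_moment()
        out[ctype] = mrs / ms
    return out
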