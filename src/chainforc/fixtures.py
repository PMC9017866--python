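"""Small deterministic inputs for tests and worked examples.

Everything here is generated programmatically: tiny chains of each
architecture, a miniature Stoner-Wohlfarth orientation set, and analytic
FORC grids with exactly known ridge mass (built from an aligned-particle
switching-field population plus, optionally, a bilinear interaction term
whose FORC function is a known constant).
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .chains import (ChainConfig, ChainType, MagnetosomeType, build_chain,
                     chain_to_frame)
from .simulate import FieldProtocol, ForcGrid

__all__ = ["tiny_chains", "sw_orientations", "synthetic_forc_grid",
           "generate_fixtures"]


def tiny_chains(seed: int = 0) -> dict[str, "pd.DataFrame"]:
    """One small chain per configuration (both magnetosome types for the
    linear architectures, plus a ring), as serializable frames."""
    out = {}
    for mt in (MagnetosomeType.EQUANT, MagnetosomeType.PRISMATIC):
        for ct, n in ((ChainType.SINGLE, 4), (ChainType.DOUBLE_NATIVE, (2, 2)),
                      (ChainType.DOUBLE_FOLDED, (2, 2))):
            cfg = ChainConfig(chain_type=ct, magnetosome_type=mt, n_crystals=n,
                              seed=seed)
            chain = build_chain(cfg)
            out[f"{ct.value}_{mt.value}"] = chain_to_frame(chain)
    ring_cfg = ChainConfig(chain_type=ChainType.RING, n_crystals=6, size_cv=0.0,
                           tapering=0.0, misorientation_deg=0.0,
                           axis_ratio_sigma=0.0, seed=seed)
    out["ring_equant"] = chain_to_frame(build_chain(ring_cfg))
    return out


def sw_orientations(n: int = 100, seed: int = 0) -> np.ndarray:
    """Reproducible random easy-axis angles (rad) for a small SW ensemble."""
    rng = np.random.default_rng(seed)
    return np.arccos(rng.uniform(0.0, 1.0, size=n))


def synthetic_forc_grid(
    ridge_mass: float = 0.5,
    mean_switching: float = 40e-3,
    sigma_switching: float = 10e-3,
    background_slope: float = 0.0,
    protocol: FieldProtocol | None = None,
) -> ForcGrid:
    """Analytic FORC grid of aligned square-loop particles.

    The particles share the field axis; their switching fields follow a
    Gaussian (``mean_switching``, ``sigma_switching``).  For this
    population the FORC function is a pure central ridge whose integrated
    magnetization is exactly ``ridge_mass`` (in units of Ms = 1).  A
    ``background_slope`` a adds the bilinear term a*B_r*B to M, whose FORC
    function is the constant -a/2 — a known smooth background.
    """
    protocol = protocol or FieldProtocol(b_sat=0.12, b_step=2e-3)
    b = protocol.bfields
    m = len(b)
    cdf = _st.norm(mean_switching, sigma_switching).cdf
    # the integrated central ridge of an aligned square-loop population
    # equals its saturation magnetization, so Msat = ridge_mass exactly
    scale = 2.0 * ridge_mass
    Mgrid = np.full((m, m), np.nan)
    for ir in range(m):
        br = b[ir]
        bs = b[: ir + 1]
        down_frac = cdf(-br) - cdf(np.minimum(bs, -br))
        Mgrid[ir, : ir + 1] = scale * (0.5 - down_frac)
        if background_slope:
            Mgrid[ir, : ir + 1] += background_slope * br * bs
    return ForcGrid(bfields=b, Mgrid=Mgrid, Ms=ridge_mass)


def generate_fixtures(kind: str, seed: int = 0, out_dir="fixtures") -> list[Path]:
    """Write fixture files; ``kind`` in {tiny_chains, sw_ensemble,
    synthetic_forc_grid}.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "tiny_chains":
        for name, frame in tiny_chains(seed).items():
            path = out / f"chain_{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
    elif kind == "sw_ensemble":
        path = out / "sw_orientations.csv"
        pd.DataFrame({"psi_rad": sw_orientations(100, seed)}).to_csv(path, index=False)
        written.append(path)
    elif kind == "synthetic_forc_grid":
        from .simulate import write_forc_text

        grid = synthetic_forc_grid()
        path = out / "synthetic_forc_grid.txt"
        write_forc_text(grid, path)
        written.append(path)
    else:
        raise ValueError("kind must be tiny_chains, sw_ensemble or synthetic_forc_grid")
    return written
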