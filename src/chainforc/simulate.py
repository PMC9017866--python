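"""Hysteresis and FORC simulation by local-energy-minimum (LEM) tracking.

A FORC protocol starts at positive saturation, where the energy surface has
a single minimum, and follows that minimum through a deterministic sequence
of field sweeps: the descending branch down to each reversal field B_r, then
back up to saturation.  Barkhausen jumps appear when the tracked minimum
disappears; they are logged per branch.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from . import relax as _kernels
from .chains import (ChainConfig, ChainGeometry, build_chain, orient_axis,
                     randomize_orientation)
from .constants import MU0, MaterialParams
from .energy import EnergyModel, build_energy_model

__all__ = [
    "ProtocolKind",
    "FieldProtocol",
    "ForcGrid",
    "relax_state",
    "sweep",
    "simulate_forc",
    "EnsembleSampler",
    "ensemble_forc",
    "write_forc_text",
    "read_forc_text",
]


class ProtocolKind(str, Enum):
    MAJOR_LOOP = "major_loop"
    FORC = "forc"
    BACKFIELD = "backfield"


@dataclass(frozen=True)
class FieldProtocol:
    """Field program: symmetric sweeps between +/- ``b_sat`` in steps of
    ``b_step`` along ``direction``."""

    b_sat: float = 0.3
    b_step: float = 1e-3
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    kind: ProtocolKind = ProtocolKind.FORC

    def __post_init__(self) -> None:
        if self.b_sat <= 0 or self.b_step <= 0:
            raise ValueError("b_sat and b_step must be positive")

    @property
    def bfields(self) -> np.ndarray:
        """Descending field values from +b_sat to -b_sat (includes 0)."""
        m = int(round(self.b_sat / self.b_step))
        return self.b_step * np.arange(m, -m - 1, -1, dtype=float)

    @property
    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, float)
        return d / np.linalg.norm(d)


@dataclass
class ForcGrid:
    """Magnetization on the FORC lattice.

    ``Mgrid[ir, j]`` is the moment projection along the field direction of
    the curve that reversed at ``bfields[ir]``, measured at ``bfields[j]``
    (j <= ir); the diagonal is the descending branch.  Units are A m^2
    unless the grid has been normalized (then ``Ms == 1``).
    """

    bfields: np.ndarray
    Mgrid: np.ndarray
    Ms: float
    jumps: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["branch", "field_index", "b_r", "b", "dM"]))
    n_chains: int = 1

    @property
    def b_step(self) -> float:
        return float(self.bfields[0] - self.bfields[1])

    def descending_branch(self) -> np.ndarray:
        return np.diagonal(self.Mgrid).copy()

    def ascending_branch(self) -> np.ndarray:
        """Lower hysteresis branch (from -Bsat back to +Bsat), indexed like
        ``bfields`` (descending order)."""
        return self.Mgrid[-1, :].copy()

    def curve(self, ir: int) -> tuple[np.ndarray, np.ndarray]:
        """(fields ascending, M) of the FORC with reversal index ``ir``."""
        return self.bfields[: ir + 1][::-1], self.Mgrid[ir, : ir + 1][::-1]

    @property
    def zero_index(self) -> int:
        return int(np.argmin(np.abs(self.bfields)))

    @property
    def Mrs(self) -> float:
        """Saturation remanence: descending branch at B = 0."""
        return float(self.Mgrid[self.zero_index, self.zero_index])

    def backfield_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Backfield (DC demagnetization) remanence M(B_r, B=0) for B_r <= 0."""
        j0 = self.zero_index
        irs = np.arange(j0, len(self.bfields))
        return -self.bfields[irs], self.Mgrid[irs, j0]

    def coercivity(self) -> float:
        """Bc: zero crossing of the ascending major branch (positive)."""
        b = self.bfields[::-1]
        m = self.ascending_branch()[::-1]
        return _zero_crossing(b, m)

    def remanent_coercivity(self) -> float:
        """Bcr: zero crossing of the backfield curve."""
        br, m = self.backfield_curve()
        return _zero_crossing(br, m)

    def normalized(self) -> "ForcGrid":
        if self.Ms == 1.0:
            return self
        return ForcGrid(bfields=self.bfields, Mgrid=self.Mgrid / self.Ms,
                        Ms=1.0, jumps=self.jumps, n_chains=self.n_chains)


def _zero_crossing(x: np.ndarray, y: np.ndarray) -> float:
    s = np.sign(y)
    idx = np.where(np.diff(s) != 0)[0]
    if len(idx) == 0:
        return math.nan
    i = idx[0]
    x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def _default_tol(model: EnergyModel) -> float:
    # torque tolerance ~ 5e-3 kT: resolves Barkhausen jumps crisply against
    # millitesla field steps while keeping warm-started relaxations cheap
    return 1e-6 * model.energy_scale


def relax_state(model: EnergyModel, u: np.ndarray, B=(0.0, 0.0, 0.0),
                tol: float | None = None, maxit: int = 5000,
                kick: bool = False) -> tuple[np.ndarray, float]:
    """Relax a state to its local energy minimum at field ``B`` (T).

    Returns (relaxed state, energy in J).  Raises if the minimizer fails
    to reach the torque tolerance.
    """
    u = np.array(u, dtype=float)
    tol = _default_tol(model) if tol is None else tol
    E, _, ok = _kernels.relax(u, model.S, model.Rcub, model.K1V, model.K2V,
                              model.F, model.mV, np.asarray(B, float),
                              tol, maxit, kick)
    if not ok:
        raise RuntimeError("relaxation did not converge within maxit")
    return u, E


def sweep(chain_or_model, material: MaterialParams | None = None,
          protocol: FieldProtocol | None = None,
          **model_kwargs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Major hysteresis loop.  Returns (bfields descending, M_desc, M_asc)
    with both branches indexed on the descending field array."""
    model = _as_model(chain_or_model, material, **model_kwargs)
    protocol = protocol or FieldProtocol(kind=ProtocolKind.MAJOR_LOOP)
    bdir = protocol.unit_direction
    u = np.tile(bdir, (model.n, 1))
    M_desc, M_asc = _kernels.run_major_loop(
        u, model.S, model.Rcub, model.K1V, model.K2V, model.F, model.mV,
        bdir, protocol.bfields, _default_tol(model), 5000)
    return protocol.bfields, M_desc, M_asc[::-1]


def _as_model(chain_or_model, material, **kwargs) -> EnergyModel:
    if isinstance(chain_or_model, EnergyModel):
        return chain_or_model
    if material is None:
        raise ValueError("material parameters required when passing a chain")
    return build_energy_model(chain_or_model, material, **kwargs)


def simulate_forc(chain_or_model, material: MaterialParams | None = None,
                  protocol: FieldProtocol | None = None,
                  jump_threshold_frac: float = 0.01,
                  **model_kwargs) -> ForcGrid:
    """Simulate the full FORC protocol for a single chain."""
    model = _as_model(chain_or_model, material, **model_kwargs)
    protocol = protocol or FieldProtocol()
    bdir = protocol.unit_direction
    bfields = protocol.bfields
    u0 = np.tile(bdir, (model.n, 1))
    msat = model.saturation_moment()
    Mgrid, jumps, njump = _kernels.run_forc(
        u0, model.S, model.Rcub, model.K1V, model.K2V, model.F, model.mV,
        bdir, bfields, _default_tol(model), 5000, jump_threshold_frac * msat)
    ev = jumps[:njump]
    jdf = pd.DataFrame({
        "branch": ev[:, 0].astype(int),
        "field_index": ev[:, 1].astype(int),
        "b_r": np.where(ev[:, 0] >= 0, bfields[np.clip(ev[:, 0], 0, None).astype(int)], np.nan),
        "b": bfields[ev[:, 1].astype(int)],
        "dM": ev[:, 2],
    })
    return ForcGrid(bfields=bfields, Mgrid=Mgrid, Ms=msat, jumps=jdf)


# ---------------------------------------------------------------------------
# ensembles


@dataclass(frozen=True)
class EnsembleSampler:
    """Chain-to-chain randomization of the geometry control parameters.

    Per chain: the crystal count is uniform over ``n_range`` (per strand for
    double-stranded types), the gap is lognormal with median
    ``base.gap_g``, the strand lag Gaussian, the twist uniform, and the
    bending curvature uniform up to 1/(curvature_lengths x chain length).
    Crystal-level randomization (sizes, shapes, misorientation) is governed
    by the base config itself.
    """

    base: ChainConfig
    n_range: tuple[int, int] = (10, 20)
    gap_sigma_ln: float = 0.25
    lag_sigma: float = 0.1
    twist_max_deg: float = 15.0
    curvature_lengths: float = 20.0

    def sample(self, rng: np.random.Generator) -> ChainConfig:
        n_lo, n_hi = self.n_range
        n = int(rng.integers(n_lo, n_hi + 1))
        gap = float(self.base.gap_g * math.exp(rng.normal(0.0, self.gap_sigma_ln)))
        lag = float(np.clip(rng.normal(0.5, self.lag_sigma), 0.0, 0.999))
        twist = float(rng.uniform(0.0, self.twist_max_deg))
        length = n * self.base.mean_size * (1 + gap)
        curv = 1.0 / (self.curvature_lengths * length)
        if self.base.chain_type.value.startswith("double"):
            counts: int | tuple[int, int] = (n - n // 2, n // 2)
        else:
            counts = n
        return replace(self.base, n_crystals=counts, gap_g=gap, strand_lag=lag,
                       twist_deg_per_crystal=twist, bend_curvature_max=curv)


def ensemble_forc(
    config: ChainConfig | EnsembleSampler,
    n_chains: int,
    material: MaterialParams,
    protocol: FieldProtocol | None = None,
    seed: int = 0,
    jump_threshold_frac: float = 0.01,
    progress: bool = False,
    **model_kwargs,
) -> ForcGrid:
    """Average FORC response of ``n_chains`` randomly oriented chains.

    Chains are generated from independent, counter-derived substreams of
    ``seed``, so the result does not depend on evaluation order.  Chain
    axes are drawn from a stratified uniform orientation distribution
    (the polar cosine is stratified over the ensemble, the azimuth and
    roll are random), which removes most of the orientation-sampling
    variance of moderate ensembles.  The returned grid is in absolute
    moment units with ``Ms`` the summed saturation moment; jump events
    carry a ``chain`` column.
    """
    protocol = protocol or FieldProtocol()
    sampler = config if isinstance(config, EnsembleSampler) else None
    total = None
    ms_total = 0.0
    jump_frames = []
    iterator = range(n_chains)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="chains")
        except ImportError:
            pass
    for i in iterator:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        cfg = sampler.sample(rng) if sampler is not None else config
        chain = build_chain(cfg, rng)
        cos_th = (i + rng.uniform()) / n_chains
        sin_th = math.sqrt(max(1.0 - cos_th * cos_th, 0.0))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        axis = np.array([sin_th * math.cos(phi), sin_th * math.sin(phi), cos_th])
        chain = orient_axis(chain, axis, rng)
        grid = simulate_forc(chain, material, protocol,
                             jump_threshold_frac=jump_threshold_frac, **model_kwargs)
        if total is None:
            total = np.nan_to_num(grid.Mgrid, nan=0.0)
        else:
            total += np.nan_to_num(grid.Mgrid, nan=0.0)
        ms_total += grid.Ms
        if len(grid.jumps):
            jf = grid.jumps.copy()
            jf["chain"] = i
            jump_frames.append(jf)
    assert total is not None
    mask = np.triu(np.ones_like(total, dtype=bool), k=1).T  # valid j <= ir
    Mgrid = np.where(np.tril(np.ones_like(total, dtype=bool)), total, np.nan)
    del mask
    jumps = pd.concat(jump_frames, ignore_index=True) if jump_frames else pd.DataFrame(
        columns=["branch", "field_index", "b_r", "b", "dM", "chain"])
    return ForcGrid(bfields=protocol.bfields, Mgrid=Mgrid, Ms=ms_total,
                    jumps=jumps, n_chains=n_chains)


# ---------------------------------------------------------------------------
# MicroMag-style text I/O


def write_forc_text(grid: ForcGrid, path) -> None:
    """Write a FORC grid as MicroMag-style text: a small header followed by
    one ``B_r, B, M`` triple per line (fields in mT)."""
    with open(path, "w") as fh:
        fh.write("ChainFORC simulated grid\n")
        fh.write(f"Bsat[mT]={grid.bfields[0] * 1e3:.6g}\n")
        fh.write(f"Bstep[mT]={grid.b_step * 1e3:.6g}\n")
        fh.write(f"Ms={grid.Ms:.9g}\n")
        fh.write("B_r[mT],B[mT],M\n")
        m = len(grid.bfields)
        for ir in range(m):
            for j in range(ir, -1, -1):
                val = grid.Mgrid[ir, j]
                if not math.isnan(val):
                    fh.write(f"{grid.bfields[ir] * 1e3:.4f},{grid.bfields[j] * 1e3:.4f},{val:.9g}\n")
            fh.write("\n")


def read_forc_text(path) -> ForcGrid:
    """Read a grid written by :func:`write_forc_text` (or any text file of
    ``B_r, B, M`` triples in mT on a uniform lattice)."""
    rows = []
    ms = 1.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if "=" in line and not line[0].isdigit() and not line.startswith("-"):
                key, _, val = line.partition("=")
                if key == "Ms":
                    ms = float(val)
                continue
            parts = line.split(",")
            if len(parts) != 3:
                continue
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                continue
    data = np.array(rows)
    if data.size == 0:
        raise ValueError("no FORC data found")
    bvals = np.unique(np.concatenate([data[:, 0], data[:, 1]]))
    step = np.min(np.diff(bvals))
    bmax = bvals[-1]
    m = int(round(2 * bmax / step)) + 1
    bfields = (bmax - step * np.arange(m)) * 1e-3
    Mgrid = np.full((m, m), np.nan)
    ir = np.clip(np.round((bmax - data[:, 0]) / step).astype(int), 0, m - 1)
    j = np.clip(np.round((bmax - data[:, 1]) / step).astype(int), 0, m - 1)
    Mgrid[ir, j] = data[:, 2]
    return ForcGrid(bfields=bfields, Mgrid=Mgrid, Ms=ms)
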