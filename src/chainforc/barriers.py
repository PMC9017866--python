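"""Transition paths, energy barriers and Neel-Arrhenius stability.

Thermally activated transitions between zero-field states are computed
with a path-optimization approach: an initial path appropriate to the
chain architecture is relaxed by the zero-temperature string method
(projected gradient descent plus arc-length reparameterization), the
saddle region is re-resolved by iterative refinement, and the barrier is
``dE = E(saddle) - E(start)``, reported as the Boltzmann factor
``beta0 = dE / kT``.

Path families (these pin down which saddle is found, since the dipolar
energy landscape has several):

``chain_nucleation``
    single strands reverse by nucleating a reversed domain at one end and
    propagating the (three-crystal wide, azimuthally fanned) transition
    region to the other end; the path is free in 3-D with a small
    symmetry-breaking perturbation.
``ring_domain_merge``
    rings start from the saturation-remanent onion state (two opposed-
    vorticity domains, walls canted toward the saturating field) and decay
    to flux closure by migrating one domain boundary into the other;
    moments stay in the local tangent-axial plane (the radial component is
    projected out of the path forces).
``strand_reversal``
    double strands switch between the parallel (high-moment) and
    antiparallel (flux-closure) configurations by reversing one strand via
    a travelling wall; moments stay in the plane containing the two
    strands.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .chains import ChainConfig, ChainGeometry, ChainType, MagnetosomeType, build_chain, build_ring
from .constants import KB, MAGNETITE_ISOTROPIC, MaterialParams
from .energy import EnergyModel, build_energy_model

__all__ = [
    "PathKind",
    "TransitionPath",
    "BarrierResult",
    "initial_path",
    "neb_minimize",
    "two_domain_seed",
    "chain_barrier",
    "coherent_rotation_barrier",
    "ring_barriers",
    "double_strand_barriers",
    "neel_beta",
    "neel_time",
    "blocking_diameter",
]

_PATH_SEED = 715517  # fixed stream for symmetric-breaking path noise


class PathKind(str, Enum):
    CHAIN_NUCLEATION = "chain_nucleation"
    RING_DOMAIN_MERGE = "ring_domain_merge"
    STRAND_REVERSAL = "strand_reversal"


@dataclass
class TransitionPath:
    """An ordered sequence of magnetic states connecting two minima."""

    images: np.ndarray          # (P, N, 3)
    energies: np.ndarray        # (P,)
    kind: PathKind
    constraint: np.ndarray | None = None  # per-site direction projected out

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def saddle_index(self) -> int:
        return int(np.argmax(self.energies))


@dataclass
class BarrierResult:
    """Saddle energy above the starting minimum."""

    dE: float                 # J
    beta0: float              # dE / kT
    dE_reverse: float         # J, from the far endpoint
    beta0_reverse: float
    saddle_index: int
    converged: bool
    path: TransitionPath

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"BarrierResult(beta0={self.beta0:.2f}, "
                f"beta0_reverse={self.beta0_reverse:.2f})")


# ---------------------------------------------------------------------------
# vectorized energetics over path images


def _imgs_energy(U: np.ndarray, model: EnergyModel, B: np.ndarray | None = None):
    E = 0.5 * np.einsum("pia,iab,pib->p", U, model.S, U)
    E += 0.5 * np.einsum("pia,ijab,pjb->p", U, model.F, U)
    if np.any(model.K1V) or np.any(model.K2V):
        a = np.einsum("iab,pib->pia", model.Rcub, U)
        a2 = a * a
        E += np.einsum("i,pi->p", model.K1V,
                       a2[..., 0] * a2[..., 1] + a2[..., 1] * a2[..., 2]
                       + a2[..., 2] * a2[..., 0])
        E += np.einsum("i,pi->p", model.K2V, a2[..., 0] * a2[..., 1] * a2[..., 2])
    if B is not None:
        E -= np.einsum("i,pia,a->p", model.mV, U, B)
    return E


def _imgs_grad(U: np.ndarray, model: EnergyModel, B: np.ndarray | None = None):
    G = np.einsum("iab,pib->pia", model.S, U)
    G += np.einsum("ijab,pjb->pia", model.F, U)
    if np.any(model.K1V) or np.any(model.K2V):
        a = np.einsum("iab,pib->pia", model.Rcub, U)
        a2 = a * a
        s = a2.sum(axis=-1, keepdims=True)
        da = 2.0 * a * (model.K1V[None, :, None] * (s - a2)
                        + model.K2V[None, :, None]
                        * (a2[..., [1, 0, 0]] * a2[..., [2, 2, 1]]))
        G += np.einsum("iab,pia->pib", model.Rcub, da)
    if B is not None:
        G -= model.mV[None, :, None] * B[None, None, :]
    return G


def _relax_single(u: np.ndarray, model: EnergyModel, B: np.ndarray | None = None,
                  tol_kT: float = 1e-6, maxit: int = 50000,
                  temperature: float | None = None) -> tuple[np.ndarray, float]:
    """Monotone BB descent of one state (numpy path, used by the barrier
    module so constraints and fields are easy to express)."""
    kT = KB * (temperature or model.material.temperature)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    E = float(_imgs_energy(u[None], model, B)[0])
    G = _imgs_grad(u[None], model, B)[0]
    alpha = 1e-3 / (np.max(np.linalg.norm(G, axis=1)) + 1e-300)
    for _ in range(maxit):
        T = G - (np.sum(G * u, axis=1))[:, None] * u
        if np.max(np.linalg.norm(T, axis=1)) < tol_kT * kT:
            break
        un = u - alpha * T
        un /= np.linalg.norm(un, axis=1)[:, None]
        En = float(_imgs_energy(un[None], model, B)[0])
        if En <= E:
            Gn = _imgs_grad(un[None], model, B)[0]
            du = (un - u).ravel()
            dg = (Gn - G).ravel()
            den = du @ dg
            u, E, G = un, En, Gn
            alpha = min(max(du @ du / den, 0.1 * alpha), 10 * alpha) if den > 0 else alpha * 1.5
        else:
            alpha *= 0.5
    return u, E


def _reparameterize(U: np.ndarray, n_out: int | None = None) -> np.ndarray:
    P = len(U)
    n_out = n_out or P
    d = np.linalg.norm((U[1:] - U[:-1]).reshape(P - 1, -1), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    snew = np.linspace(0.0, s[-1], n_out)
    flat = U.reshape(P, -1)
    out = np.empty((n_out, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(snew, s, flat[:, c])
    out = out.reshape(n_out, *U.shape[1:])
    return out / np.linalg.norm(out, axis=2, keepdims=True)


def _string(U: np.ndarray, model: EnergyModel,
            constraint: np.ndarray | None,
            n_iter: int, n_sub: int = 5,
            stop_tol_kT: float = 1e-3, stop_window: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Zero-temperature string method; endpoints held fixed.

    Terminates early once the saddle-energy estimate has been stable to
    ``stop_tol_kT`` (in kT) over ``stop_window`` consecutive outer
    iterations.
    """
    U = U.copy()
    kT = model.material.kT
    G = _imgs_grad(U, model)
    dt = 0.05 / (np.max(np.linalg.norm(G, axis=2)) + 1e-300)
    e_prev: np.ndarray | None = None
    stable = 0
    for _ in range(n_iter):
        for _ in range(n_sub):
            G = _imgs_grad(U, model)
            T = G - np.sum(G * U, axis=2, keepdims=True) * U
            if constraint is not None:
                proj = np.einsum("pia,ia->pi", T, constraint)
                T -= proj[:, :, None] * constraint[None]
            step = dt * T
            mx = np.max(np.linalg.norm(step, axis=2))
            if mx > 0.05:
                step *= 0.05 / mx
            U[1:-1] -= step[1:-1]
            U /= np.linalg.norm(U, axis=2, keepdims=True)
        U = _reparameterize(U)
        e_now = _imgs_energy(U, model) / kT
        if e_prev is not None and float(np.max(np.abs(e_now - e_prev))) < stop_tol_kT:
            stable += 1
            if stable >= stop_window:
                break
        else:
            stable = 0
        e_prev = e_now
    return U, _imgs_energy(U, model)


def neb_minimize(
    path: TransitionPath,
    model: EnergyModel,
    n_iter: int = 3000,
    refine_rounds: int = 3,
    refine_iter: int = 1500,
    refine_window: int = 4,
    stop_tol_kT: float = 1e-3,
) -> BarrierResult:
    """Relax a transition path and resolve its saddle.

    After the initial string relaxation the highest-energy segment is
    re-interpolated to the full image count and relaxed again
    (``refine_rounds`` times), which resolves saddles that sit on a small
    shoulder of an otherwise steep path.
    """
    U, E = _string(path.images, model, path.constraint, n_iter,
                   stop_tol_kT=stop_tol_kT)
    e_start, e_end = float(E[0]), float(E[-1])
    Eref = E
    Uref = U
    for _ in range(refine_rounds):
        p = int(np.argmax(Eref))
        lo = max(p - refine_window, 0)
        hi = min(p + refine_window, len(Uref) - 1)
        seg = _reparameterize(Uref[lo:hi + 1], path.n_images)
        Uref, Eref = _string(seg, model, path.constraint, refine_iter,
                             stop_tol_kT=min(stop_tol_kT, 1e-5))
    e_saddle = float(np.max(Eref))
    kT = model.material.kT
    out_path = TransitionPath(images=Uref, energies=Eref, kind=path.kind,
                              constraint=path.constraint)
    return BarrierResult(
        dE=e_saddle - e_start,
        beta0=(e_saddle - e_start) / kT,
        dE_reverse=e_saddle - e_end,
        beta0_reverse=(e_saddle - e_end) / kT,
        saddle_index=out_path.saddle_index,
        converged=True,
        path=out_path,
    )


# ---------------------------------------------------------------------------
# initial path constructions


def _wall_profile(z: np.ndarray, z_wall: float, width: float) -> np.ndarray:
    """Polar angle profile of a travelling wall (0 to pi across the wall)."""
    return 2.0 * np.arctan(np.exp((z - z_wall) / width))


def two_domain_seed(model: EnergyModel, weakening: float = 0.01) -> np.ndarray:
    """Relaxed two-domain state of a linear chain.

    Built the way the transition initializer prescribes: the middle
    moment is forced perpendicular to the chain axis and the state is
    relaxed while the dipolar couplings within one half are weakened by
    ``weakening`` to break the symmetry and favour denucleation of that
    half.
    """
    n = model.n
    z = model.chain.centers()[:, 2] if model.chain is not None else np.arange(n, dtype=float)
    u = np.zeros((n, 3))
    order = np.argsort(z)
    mid = order[n // 2]
    upper = z > z[mid]
    u[:, 2] = np.where(upper, -1.0, 1.0)
    u[mid] = [1.0, 0.0, 0.0]
    weak = model.F.copy()
    idx = np.where(upper)[0]
    for i in idx:
        for j in idx:
            weak[i, j] *= 1.0 - weakening
    weakened = EnergyModel(S=model.S, Rcub=model.Rcub, K1V=model.K1V,
                           K2V=model.K2V, F=weak, mV=model.mV,
                           material=model.material, chain=model.chain)
    # a few steps of the weakened-coupling descent break the symmetry in
    # favour of denucleating the upper domain, then the true landscape
    # relaxes into the metastable two-domain (wall) state
    u, _ = _relax_single(u, weakened, maxit=5)
    u, _ = _relax_single(u, model)
    return u


def _chain_nucleation_path(model: EnergyModel, n_images: int, rng: np.random.Generator,
                           perturbation: float) -> TransitionPath:
    n = model.n
    z = model.chain.centers()[:, 2]
    spacing = np.median(np.diff(np.sort(z)))
    width = 1.65 * spacing
    lo = z.min() - 4 * width
    hi = z.max() + 4 * width
    U = np.zeros((n_images, n, 3))
    for p in range(n_images):
        # the reversed domain enters from the low end and sweeps up; the
        # path starts at the uniform +z state
        zw = lo + (hi - lo) * p / (n_images - 1)
        th = _wall_profile(-z, -zw, width)
        U[p, :, 0] = np.sin(th)
        U[p, :, 2] = np.cos(th)
    U[1:-1] += perturbation * rng.standard_normal(U[1:-1].shape)
    U /= np.linalg.norm(U, axis=2, keepdims=True)
    U[0], _ = _relax_single(U[0], model)
    U[-1], _ = _relax_single(U[-1], model)
    return TransitionPath(images=U, energies=_imgs_energy(U, model),
                          kind=PathKind.CHAIN_NUCLEATION)


def remanent_ring_state(model: EnergyModel, b_start: float = 0.3,
                        n_steps: int = 120) -> np.ndarray:
    """Zero-field onion state reached by reducing an in-plane saturating
    field to zero (the high-moment remanent state of a ring)."""
    cached = getattr(model, "_remanent_state", None)
    if cached is not None:
        return cached.copy()
    psi = np.arctan2(model.chain.centers()[:, 1], model.chain.centers()[:, 0])
    target = psi[int(np.argmin(np.abs(psi - math.pi / 2)))]
    bdir = np.array([math.cos(target), math.sin(target), 0.0])
    u = np.tile(bdir, (model.n, 1))
    for b in np.linspace(b_start, 0.0, n_steps + 1):
        u, _ = _relax_single(u, model, B=b * bdir, tol_kT=1e-4, maxit=20000)
    u, _ = _relax_single(u, model, tol_kT=1e-6)
    model._remanent_state = u.copy()
    return u


def _ring_merge_path(model: EnergyModel, n_images: int, rng: np.random.Generator,
                     perturbation: float, direction: int = 1) -> TransitionPath:
    """One-wall migration path from the remanent onion to flux closure.

    The reversed domain is the arc of crystals whose moments are clearly
    antitangential (projection < -0.5; the wall-center crystals with
    near-zero projection are ambiguous and the arc is extended by one site
    at the high-angle boundary).  ``direction`` selects which boundary
    migrates: +1 sweeps the low-angle boundary upward, -1 the high-angle
    boundary downward.  Both variants are explored as path replicates and
    the cheapest positive barrier is reported.
    """
    centers = model.chain.centers()
    psi = np.arctan2(centers[:, 1], centers[:, 0]) % (2 * math.pi)
    n = model.n
    step = 2 * math.pi / n
    tang = np.stack([-np.sin(psi), np.cos(psi), np.zeros(n)], axis=1)
    radial = np.stack([np.cos(psi), np.sin(psi), np.zeros(n)], axis=1)
    u0 = remanent_ring_state(model)
    proj = np.einsum("ia,ia->i", u0, tang)
    neg = np.where(proj < -0.5)[0]
    if len(neg) == 0:  # already flux closed; nothing to merge
        raise ValueError("remanent state has no reversed domain")
    a0 = psi[neg].min()
    a1 = psi[neg].max() + step
    U = np.zeros((n_images, n, 3))
    for p in range(n_images):
        lam = p / (n_images - 1)
        if direction > 0:
            a = a0 + lam * (a1 - a0 + step)
            s = np.where((psi >= a) & (psi <= a1 + 1e-12), -1.0, 1.0)
        else:
            a = a1 - lam * (a1 - a0 + step)
            s = np.where((psi >= a0 - 1e-12) & (psi <= a), -1.0, 1.0)
        U[p] = s[:, None] * tang
    U[0] = u0
    # out-of-plane symmetric breaking: the migrating wall rotates its
    # moments over the ring axis rather than through the ring plane
    U[1:-1, :, 2] += perturbation * rng.standard_normal((n_images - 2, n))
    U /= np.linalg.norm(U, axis=2, keepdims=True)
    U[-1], _ = _relax_single(U[-1], model)
    return TransitionPath(images=U, energies=_imgs_energy(U, model),
                          kind=PathKind.RING_DOMAIN_MERGE, constraint=radial)


def _strand_reversal_path(model: EnergyModel, n_images: int, rng: np.random.Generator,
                          perturbation: float,
                          entry: str = "top",
                          constrained: bool = True) -> TransitionPath:
    chain = model.chain
    strands = chain.strands()
    z = chain.centers()[:, 2]
    rev = strands == 1
    if not rev.any():
        raise ValueError("strand_reversal needs a double-stranded chain")
    n = model.n
    z2 = z[rev]
    spacing = np.median(np.diff(np.sort(z[~rev])))
    width = 1.65 * spacing
    hi = z2.max() + 4 * width
    lo = z2.min() - 4 * width
    U = np.zeros((n_images, n, 3))
    for p in range(n_images):
        lam = p / (n_images - 1)
        if entry == "top":  # wall enters strand 2 from its top end
            zw = hi - (hi - lo) * lam
            th = _wall_profile(z2, zw, width)
        else:               # wall enters from the bottom end
            zw = lo + (hi - lo) * lam
            th = _wall_profile(-z2, -zw, width)
        U[p, ~rev, 2] = 1.0
        U[p, rev, 0] = np.sin(th)
        U[p, rev, 2] = np.cos(th)
    if constrained:
        # in-plane perturbation; the path stays in the strand plane
        U[1:-1, :, 0] += perturbation * rng.standard_normal((n_images - 2, n))
        constraint = np.tile(np.array([0.0, 1.0, 0.0]), (n, 1))
    else:
        # full 3-D symmetric breaking; the wall fans azimuthally
        U[1:-1] += perturbation * rng.standard_normal(U[1:-1].shape)
        constraint = None
    U /= np.linalg.norm(U, axis=2, keepdims=True)
    U[0], _ = _relax_single(U[0], model)
    U[-1], _ = _relax_single(U[-1], model)
    return TransitionPath(images=U, energies=_imgs_energy(U, model),
                          kind=PathKind.STRAND_REVERSAL, constraint=constraint)


def initial_path(
    chain_or_model,
    kind: PathKind | str,
    material: MaterialParams | None = None,
    n_images: int = 64,
    perturbation: float = 0.15,
    replicate: int = 0,
    isotropic_shapes: bool = True,
) -> tuple[TransitionPath, EnergyModel]:
    """Construct the initial transition path for a chain.

    ``replicate`` selects one of the deterministic symmetric-breaking noise
    streams; barriers are typically taken as the minimum over a few
    replicates.
    """
    kind = PathKind(kind)
    if isinstance(chain_or_model, EnergyModel):
        model = chain_or_model
    else:
        model = build_energy_model(chain_or_model, material or MAGNETITE_ISOTROPIC,
                                   isotropic_shapes=isotropic_shapes)
    rng = np.random.default_rng(np.random.SeedSequence(_PATH_SEED, spawn_key=(replicate,)))
    ctype = model.chain.chain_type if model.chain is not None else None
    if kind is PathKind.CHAIN_NUCLEATION:
        if ctype not in (ChainType.SINGLE, None):
            raise ValueError("chain_nucleation applies to single strands")
        return _chain_nucleation_path(model, n_images, rng, perturbation), model
    if kind is PathKind.RING_DOMAIN_MERGE:
        if ctype not in (ChainType.RING, None):
            raise ValueError("ring_domain_merge applies to rings")
        # even/odd replicates explore the two wall-migration directions
        direction = 1 if replicate % 2 == 0 else -1
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(_PATH_SEED, spawn_key=(replicate // 2,)))
        return _ring_merge_path(model, n_images, noise_rng, perturbation,
                                direction=direction), model
    if ctype not in (ChainType.DOUBLE_NATIVE, ChainType.DOUBLE_FOLDED, None):
        raise ValueError("strand_reversal applies to double strands")
    # staggered native strands lock the reversal wall into the strand
    # plane; side-by-side (fold-collapsed) strands let it fan freely
    constrained = ctype != ChainType.DOUBLE_FOLDED
    entry = "top" if replicate % 2 == 0 else "bottom"
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(_PATH_SEED, spawn_key=(100 + replicate // 2,)))
    return _strand_reversal_path(model, n_images, noise_rng, perturbation,
                                 entry=entry, constrained=constrained), model


def _best_barrier(chain, kind, n_replicates: int = 3,
                  material: MaterialParams | None = None,
                  isotropic_shapes: bool = True, **kwargs) -> BarrierResult:
    """Minimum barrier over symmetric-breaking replicates of the path."""
    model = build_energy_model(chain, material or MAGNETITE_ISOTROPIC,
                               isotropic_shapes=isotropic_shapes)
    stop_tol_kT = kwargs.pop("stop_tol_kT", 1e-3)
    best: BarrierResult | None = None
    for rep in range(n_replicates):
        path, _ = initial_path(model, kind, replicate=rep, **kwargs)
        res = neb_minimize(path, model, stop_tol_kT=stop_tol_kT)
        if res.beta0 <= 0 or res.beta0_reverse <= 0:
            continue  # path escaped its family; not a valid transition
        if best is None or res.beta0 < best.beta0:
            best = res
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# convenience wrappers for the idealized (sphere, no-anisotropy) geometries


def _ideal_config(chain_type: ChainType, n, d: float, g: float) -> ChainConfig:
    return ChainConfig(chain_type=chain_type, magnetosome_type=MagnetosomeType.EQUANT,
                       n_crystals=n, mean_size=d, size_cv=0.0, gap_g=g,
                       tapering=0.0, misorientation_deg=0.0, axis_ratio_sigma=0.0,
                       bend_curvature_max=0.0, twist_deg_per_crystal=0.0,
                       strand_lag=0.5)


def coherent_rotation_barrier(n: int = 2, d: float = 50.0, g: float = 0.1,
                              n_theta: int = 721) -> BarrierResult:
    """Reversal barrier of a short chain along the coherent-rotation path
    (all moments rotating rigidly through the perpendicular direction).

    For two identical spheres this is the closed form
    ``dE = 3 mu0 m^2 / (4 pi r^3)``; symmetric fanning has a lower saddle,
    but the coherent path is the reference family for short chains.
    """
    chain = build_chain(_ideal_config(ChainType.SINGLE, n, d, g))
    model = build_energy_model(chain, MAGNETITE_ISOTROPIC, isotropic_shapes=True)
    thetas = np.linspace(0.0, math.pi, n_theta)
    U = np.zeros((n_theta, model.n, 3))
    U[:, :, 0] = np.sin(thetas)[:, None]
    U[:, :, 2] = np.cos(thetas)[:, None]
    E = _imgs_energy(U, model)
    kT = model.material.kT
    path = TransitionPath(images=U, energies=E, kind=PathKind.CHAIN_NUCLEATION)
    return BarrierResult(
        dE=float(E.max() - E[0]), beta0=float(E.max() - E[0]) / kT,
        dE_reverse=float(E.max() - E[-1]),
        beta0_reverse=float(E.max() - E[-1]) / kT,
        saddle_index=path.saddle_index, converged=True, path=path)


def chain_barrier(n: int = 15, d: float = 50.0, g: float = 0.1,
                  n_replicates: int = 3) -> BarrierResult:
    """HMS reversal barrier of an idealized single-stranded chain of
    identical spheres (diameter ``d`` nm, diameter-normalized gap ``g``).

    Chains of more than four crystals reverse by domain nucleation and
    propagation; shorter chains are pinned to the coherent-rotation path
    (the reference family for the shortest chains, although fanning gives
    a lower saddle)."""
    if n <= 4:
        return coherent_rotation_barrier(n, d, g)
    chain = build_chain(_ideal_config(ChainType.SINGLE, n, d, g))
    return _best_barrier(chain, PathKind.CHAIN_NUCLEATION, n_replicates=n_replicates)


def ring_barriers(n: int = 20, d: float = 50.0, g: float = 0.1,
                  n_replicates: int = 2) -> BarrierResult:
    """Onion-to-flux-closure barriers of an idealized ring.

    ``beta0`` is the barrier of the high-moment state (the saturation-
    remanent onion), ``beta0_reverse`` that of the flux-closure state;
    the reported barrier is the minimum over the symmetric-breaking path
    replicates (deterministic noise streams).
    """
    chain = build_ring(n, d, g)
    return _best_barrier(chain, PathKind.RING_DOMAIN_MERGE,
                         n_replicates=n_replicates, stop_tol_kT=1e-5)


def double_strand_barriers(n1: int = 11, n2: int = 11, folded: bool = False,
                           d: float = 50.0, g: float = 0.1,
                           n_replicates: int = 4) -> BarrierResult:
    """Barriers of an idealized double strand: ``beta0`` from the parallel
    high-moment state, ``beta0_reverse`` from the antiparallel
    flux-closure state.  One strand reverses through a travelling wall
    whose moments stay in the plane containing the two strands."""
    from dataclasses import replace as _replace

    ctype = ChainType.DOUBLE_FOLDED if folded else ChainType.DOUBLE_NATIVE
    cfg = _ideal_config(ctype, (n1, n2), d, g)
    if folded:
        cfg = _replace(cfg, strand_lag=0.0)
    chain = build_chain(cfg)
    return _best_barrier(chain, PathKind.STRAND_REVERSAL,
                         n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# Neel-Arrhenius


def neel_beta(tau: float, tau0: float = 1e-9) -> float:
    """Boltzmann factor required for relaxation time ``tau`` given the
    attempt time ``tau0`` (Neel-Arrhenius law tau = tau0 exp(beta0))."""
    if tau0 <= 0 or tau < tau0:
        raise ValueError("need tau >= tau0 > 0")
    return math.log(tau / tau0)


def neel_time(beta0: float, tau0: float = 1e-9) -> float:
    """Relaxation time tau = tau0 exp(beta0); +inf on overflow."""
    if beta0 < 0:
        raise ValueError("beta0 must be non-negative")
    try:
        return tau0 * math.exp(beta0)
    except OverflowError:
        return math.inf


def blocking_diameter(
    tau: float,
    tau0: float = 1e-10,
    n: int = 6,
    g: float = 0.1,
    d_ref: float = 50.0,
    reference_barrier: BarrierResult | None = None,
) -> float:
    """Smallest crystal diameter (nm) whose chain moment survives for
    ``tau`` seconds.

    Pure dipolar energies with self-similar geometry (gaps normalized by
    the diameter) scale exactly as d^3, so a single barrier evaluation at
    ``d_ref`` anchors the whole curve: beta0(d) = beta0(d_ref) (d/d_ref)^3.
    """
    target = neel_beta(tau, tau0)
    if target <= 0:
        return 0.0
    if reference_barrier is None:
        reference_barrier = chain_barrier(n=n, d=d_ref, g=g)
    return d_ref * (target / reference_barrier.beta0) ** (1.0 / 3.0)
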