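"""Total free energy of a chain's magnetic state.

The energy of moment directions ``u_1..u_N`` in field ``B`` is

    F = sum_i [ mu0 Ms^2 V_i / 2 * u_i . N_i . u_i          (shape)
              + K1 V_i (a1^2 a2^2 + a2^2 a3^2 + a3^2 a1^2)
              + K2 V_i a1^2 a2^2 a3^2                        (magnetocrystalline)
              - Ms V_i u_i . B ]                             (Zeeman)
      + sum_{i<j} u_i . F_ij . u_j                           (magnetostatic)

with ``a`` the moment direction in the cubic crystal frame and ``F_ij`` the
pairwise interaction tensors (computed once per chain).  The model is
assembled into plain arrays so the relaxation kernels can run jitted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chains import ChainGeometry
from .constants import MU0, MaterialParams
from .demag import demag_tensor_cylinder, demag_tensor_ellipsoid
from .interactions import NM, dipole_tensor, interaction_tensor_quadrature
from .shapes import ShapeKind

__all__ = ["EnergyModel", "build_energy_model", "total_energy", "energy_terms"]


@dataclass
class EnergyModel:
    """Precomputed energetics of one chain (arrays in SI units)."""

    S: np.ndarray        # (N,3,3) lab-frame shape matrices mu0 Ms^2 V N (J)
    Rcub: np.ndarray     # (N,3,3) lab->cubic rotations
    K1V: np.ndarray      # (N,) J
    K2V: np.ndarray      # (N,) J
    F: np.ndarray        # (N,N,3,3) pair tensors (J); F[j,i] = F[i,j].T
    mV: np.ndarray       # (N,) moments Ms*V (A m^2)
    material: MaterialParams
    chain: ChainGeometry | None = None

    @property
    def n(self) -> int:
        return len(self.mV)

    @property
    def energy_scale(self) -> float:
        """mu0 Ms^2 Vbar (J), the natural magnetostatic energy unit."""
        return MU0 * self.material.Ms**2 * float(np.mean(self.mV)) / self.material.Ms

    def saturation_moment(self) -> float:
        return float(self.mV.sum())


def _demag_lab(crystal) -> np.ndarray:
    s = crystal.shape
    if s.kind is ShapeKind.ELLIPSOID:
        nd = demag_tensor_ellipsoid(*s.semi_axes)
    else:
        nd = demag_tensor_cylinder(s.length, s.diameter, s.chamfer_fraction, s.ellipticity)
    R = crystal.rotation
    return R @ nd @ R.T


def build_energy_model(
    chain: ChainGeometry,
    material: MaterialParams,
    isotropic_shapes: bool = False,
    quadrature_level: int = 3,
    quadrature_cutoff: float = 1.2,
) -> EnergyModel:
    """Assemble the energy model for a chain.

    ``isotropic_shapes`` replaces every demag tensor by the spherical one
    (used in the idealized barrier calculations where crystals carry no
    anisotropy of any kind).  Faceted crystals within ``quadrature_cutoff``
    reference diameters of each other get surface-charge interaction
    tensors; all other pairs use the point-dipole form.
    """
    n = chain.n
    vols = chain.volumes() * NM**3  # m^3
    Ms = material.Ms
    S = np.empty((n, 3, 3))
    Rcub = np.empty((n, 3, 3))
    K1V = np.full(n, material.K1) * vols
    K2V = np.full(n, material.K2) * vols
    for i, c in enumerate(chain.crystals):
        if isotropic_shapes:
            # the spherical demag term 1/2 mu0 Ms^2 V u.(I/3).u is state
            # independent; drop it so energies are purely dipolar
            S[i] = 0.0
        else:
            S[i] = MU0 * Ms * Ms * vols[i] * _demag_lab(c)
        Rcub[i] = c.cubic_rotation.T
    if isotropic_shapes:
        K1V[:] = 0.0
        K2V[:] = 0.0

    F = np.zeros((n, n, 3, 3))
    centers = chain.centers()
    any_faceted = any(c.shape.kind is ShapeKind.CHAMFERED_CYLINDER for c in chain.crystals)
    ref = chain.config.reference_diameter if chain.config is not None else float(
        np.mean([c.shape.equivalent_diameter for c in chain.crystals]))
    for i in range(n):
        ci = chain.crystals[i]
        for j in range(i + 1, n):
            cj = chain.crystals[j]
            sep = float(np.linalg.norm(centers[j] - centers[i]))
            faceted = (ci.shape.kind is ShapeKind.CHAMFERED_CYLINDER
                       or cj.shape.kind is ShapeKind.CHAMFERED_CYLINDER)
            if faceted and sep < quadrature_cutoff * max(ci.shape.max_extent, cj.shape.max_extent):
                # single-level quadrature: percent-level accuracy on the
                # dominant facing-surface pairs at a fraction of the cost
                Fij = interaction_tensor_quadrature(
                    ci.shape, ci.rotation, ci.center,
                    cj.shape, cj.rotation, cj.center,
                    Ms, level=quadrature_level, extrapolate=False,
                )
            else:
                Fij = dipole_tensor(ci.center, cj.center, Ms * vols[i] / NM**3 * NM**3,
                                    Ms * vols[j] / NM**3 * NM**3)
            F[i, j] = Fij
            F[j, i] = Fij.T
    del any_faceted
    return EnergyModel(S=S, Rcub=Rcub, K1V=K1V, K2V=K2V, F=F,
                       mV=Ms * vols, material=material, chain=chain)


def energy_terms(model: EnergyModel, u: np.ndarray, B: np.ndarray) -> dict[str, float]:
    """Energy decomposition (J) for diagnostics."""
    u = np.asarray(u, float)
    B = np.asarray(B, float)
    e_shape = 0.5 * float(np.einsum("ia,iab,ib->", u, model.S, u))
    a = np.einsum("iab,ib->ia", model.Rcub, u)
    a2 = a * a
    e_cub = float(np.sum(model.K1V * (a2[:, 0] * a2[:, 1] + a2[:, 1] * a2[:, 2]
                                      + a2[:, 2] * a2[:, 0])
                         + model.K2V * a2[:, 0] * a2[:, 1] * a2[:, 2]))
    e_zee = -float(np.sum(model.mV * (u @ B)))
    e_int = 0.5 * float(np.einsum("ia,ijab,jb->", u, model.F, u))
    return {
        "shape": e_shape,
        "magnetocrystalline": e_cub,
        "zeeman": e_zee,
        "interaction": e_int,
        "total": e_shape + e_cub + e_zee + e_int,
    }


def total_energy(model: EnergyModel, u: np.ndarray, B=(0.0, 0.0, 0.0)) -> float:
    """Total free energy (J) of moment directions ``u`` (N,3) in field ``B`` (T)."""
    u = np.asarray(u, float)
    if u.shape != (model.n, 3):
        raise ValueError(f"state must have shape ({model.n}, 3)")
    norms = np.linalg.norm(u, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise ValueError("moment directions must be unit vectors")
    return energy_terms(model, u, np.asarray(B, float))["total"]
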