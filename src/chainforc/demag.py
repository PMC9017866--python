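"""Demagnetizing tensors of uniformly magnetized crystals.

Ellipsoids use the classical closed form (Carlson symmetric elliptic
integral R_D), equivalent to the standard elliptic-integral expressions for
the general triaxial case.  Cylinders use the exact axial magnetometric
factor obtained by reducing the surface-charge double integral to a
one-dimensional integral over complete elliptic integrals; chamfered ends
are handled through a numerically precomputed correction factor
interpolated from a small table (see ``scripts/gen_chamfer_table.py``).

All factors follow the SI convention ``trace(N) = 1``.
"""
from __future__ import annotations

import functools
import math
from importlib import resources

import numpy as np
from scipy import integrate, special

__all__ = [
    "demag_tensor_ellipsoid",
    "demag_tensor_cylinder",
    "cylinder_axial_factor",
]


def demag_tensor_ellipsoid(a: float, b: float, c: float) -> np.ndarray:
    """Demagnetizing tensor of a triaxial ellipsoid, diagonal in its frame.

    Parameters are the semi-axes (any consistent length unit); the returned
    3x3 tensor is dimensionless with factors ordered along (a, b, c).
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    abc = a * b * c
    na = abc / 3.0 * special.elliprd(b * b, c * c, a * a)
    nb = abc / 3.0 * special.elliprd(c * c, a * a, b * b)
    nc = abc / 3.0 * special.elliprd(a * a, b * b, c * c)
    return np.diag([na, nb, nc])


def _disk_potential(rho: float, h: float, R: float) -> float:
    """Potential (Coulomb kernel integral) of a unit-density disk of radius R
    evaluated at cylindrical position (rho, h)."""

    def integrand(rp: float) -> float:
        denom = math.sqrt((rho + rp) ** 2 + h * h)
        m = 4.0 * rho * rp / (denom * denom) if denom > 0 else 0.0
        m = min(m, 1.0 - 1e-15)
        return 4.0 * rp * special.ellipk(m) / denom

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, R, limit=200,
                                epsabs=1e-12, epsrel=1e-10)
    return val


def _disk_disk_integral(h: float, R: float) -> float:
    """Double surface integral of 1/r over two coaxial disks of radius R
    separated by h (h = 0 gives the self-integral of one disk)."""

    def outer(rho: float) -> float:
        return 2.0 * math.pi * rho * _disk_potential(rho, h, R)

    val, _ = integrate.quad(outer, 0.0, R, limit=200, epsabs=1e-10, epsrel=1e-8)
    return val


@functools.lru_cache(maxsize=512)
def cylinder_axial_factor(aspect: float) -> float:
    """Axial magnetometric demagnetizing factor of a circular cylinder.

    ``aspect`` is length/diameter.  Computed from the magnetostatic
    self-energy of the two charged end disks, which reduces to 1-D integrals
    of complete elliptic integrals (exact up to quadrature tolerance).
    """
    if aspect <= 0:
        raise ValueError("aspect ratio must be positive")
    R = 0.5
    L = aspect  # diameter = 1
    volume = math.pi * R * R * L
    i0 = _disk_disk_integral(0.0, R)
    iL = _disk_disk_integral(L, R)
    return (i0 - iL) / (2.0 * math.pi * volume)


@functools.lru_cache(maxsize=1)
def _axial_factor_spline():
    """Cubic spline of the axial factor over the practical aspect range;
    the exact quadrature is only a few hundred ms per call but is hit for
    every crystal of every randomized chain."""
    from scipy.interpolate import CubicSpline

    aspects = np.linspace(0.5, 4.0, 36)
    vals = [cylinder_axial_factor(float(a)) for a in aspects]
    return CubicSpline(aspects, vals)


def cylinder_axial_factor_fast(aspect: float) -> float:
    """Axial magnetometric factor via the precomputed spline (exact
    quadrature outside the tabulated aspect range)."""
    if 0.5 <= aspect <= 4.0:
        return float(_axial_factor_spline()(aspect))
    return cylinder_axial_factor(aspect)


@functools.lru_cache(maxsize=1)
def _chamfer_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(aspects, chamfers, ratio grid) for the chamfer correction factor
    N_axial(chamfered) / N_axial(plain), precomputed by surface-charge
    quadrature (see scripts/gen_chamfer_table.py)."""
    with resources.files("chainforc.data").joinpath("chamfer_table.csv").open() as fh:
        rows = np.loadtxt(fh, delimiter=",", skiprows=1)
    aspects = np.unique(rows[:, 0])
    chamfers = np.unique(rows[:, 1])
    grid = rows[:, 2].reshape(len(aspects), len(chamfers))
    return aspects, chamfers, grid


def _chamfer_correction(aspect: float, chamfer: float) -> float:
    aspects, chamfers, grid = _chamfer_table()
    a = float(np.clip(aspect, aspects[0], aspects[-1]))
    c = float(np.clip(chamfer, chamfers[0], chamfers[-1]))
    ia = int(np.clip(np.searchsorted(aspects, a) - 1, 0, len(aspects) - 2))
    ic = int(np.clip(np.searchsorted(chamfers, c) - 1, 0, len(chamfers) - 2))
    ta = (a - aspects[ia]) / (aspects[ia + 1] - aspects[ia])
    tc = (c - chamfers[ic]) / (chamfers[ic + 1] - chamfers[ic])
    return float(
        grid[ia, ic] * (1 - ta) * (1 - tc)
        + grid[ia + 1, ic] * ta * (1 - tc)
        + grid[ia, ic + 1] * (1 - ta) * tc
        + grid[ia + 1, ic + 1] * ta * tc
    )


def demag_tensor_cylinder(
    length: float,
    diameter: float,
    chamfer_fraction: float = 0.0,
    ellipticity: float = 1.0,
) -> np.ndarray:
    """Demagnetizing tensor of a (chamfered, slightly elliptical) cylinder.

    The tensor is diagonal in the crystal frame with the symmetry axis
    third.  A slight cross-section ellipticity redistributes the transverse
    factors according to the equivalent ellipsoid; chamfered ends scale the
    axial factor by the tabulated numeric correction.
    """
    if length <= 0 or diameter <= 0:
        raise ValueError("cylinder dimensions must be positive")
    if not (0.0 <= chamfer_fraction < 0.5):
        raise ValueError("chamfer_fraction must be in [0, 0.5)")
    nz = cylinder_axial_factor_fast(length / diameter)
    if chamfer_fraction > 0.0:
        nz *= _chamfer_correction(length / diameter, chamfer_fraction)
    nt = 1.0 - nz
    if ellipticity != 1.0:
        sa = 0.5 * diameter * ellipticity
        sb = 0.5 * diameter / ellipticity
        ne = demag_tensor_ellipsoid(sa, sb, 0.5 * length)
        split = ne[0, 0] / (ne[0, 0] + ne[1, 1])
    else:
        split = 0.5
    return np.diag([nt * split, nt * (1.0 - split), nz])
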