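"""Jitted kernels: local energy minimization and field-sweep tracking.

The magnetic state is represented by Cartesian unit moments (N, 3); the
minimizer is a monotone projected Barzilai-Borwein descent on the product
of unit spheres.  Monotonicity (steps are only accepted when the energy
does not increase) keeps the iterate inside the current energy basin, which
is what local-energy-minimum tracking through a field sweep requires.

A deterministic, tiny transverse kick is applied before each relaxation so
that states sitting exactly on unstable equilibria (e.g. a moment exactly
antiparallel to the field) destabilize at the analytic switching field
instead of never switching.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["energy_grad", "relax", "run_forc", "run_major_loop"]

_KICK = np.array([0.36, 0.48, 0.8])  # arbitrary fixed direction, |k| = 1
# large enough that a state parked on an unstable equilibrium generates a
# super-tolerance torque and destabilizes at the analytic switching field
_KICK_EPS = 1e-3


@njit(cache=True)
def energy_grad(u, S, Rcub, K1V, K2V, F, mV, B):  # pragma: no cover - jitted
    n = u.shape[0]
    G = np.zeros((n, 3))
    E = 0.0
    for i in range(n):
        # shape term 1/2 u.S.u
        sx = S[i, 0, 0] * u[i, 0] + S[i, 0, 1] * u[i, 1] + S[i, 0, 2] * u[i, 2]
        sy = S[i, 1, 0] * u[i, 0] + S[i, 1, 1] * u[i, 1] + S[i, 1, 2] * u[i, 2]
        sz = S[i, 2, 0] * u[i, 0] + S[i, 2, 1] * u[i, 1] + S[i, 2, 2] * u[i, 2]
        E += 0.5 * (u[i, 0] * sx + u[i, 1] * sy + u[i, 2] * sz)
        G[i, 0] += sx
        G[i, 1] += sy
        G[i, 2] += sz
        if K1V[i] != 0.0 or K2V[i] != 0.0:
            a0 = Rcub[i, 0, 0] * u[i, 0] + Rcub[i, 0, 1] * u[i, 1] + Rcub[i, 0, 2] * u[i, 2]
            a1 = Rcub[i, 1, 0] * u[i, 0] + Rcub[i, 1, 1] * u[i, 1] + Rcub[i, 1, 2] * u[i, 2]
            a2 = Rcub[i, 2, 0] * u[i, 0] + Rcub[i, 2, 1] * u[i, 1] + Rcub[i, 2, 2] * u[i, 2]
            q0 = a0 * a0
            q1 = a1 * a1
            q2 = a2 * a2
            E += K1V[i] * (q0 * q1 + q1 * q2 + q2 * q0) + K2V[i] * q0 * q1 * q2
            d0 = 2.0 * a0 * (K1V[i] * (q1 + q2) + K2V[i] * q1 * q2)
            d1 = 2.0 * a1 * (K1V[i] * (q0 + q2) + K2V[i] * q0 * q2)
            d2 = 2.0 * a2 * (K1V[i] * (q0 + q1) + K2V[i] * q0 * q1)
            G[i, 0] += Rcub[i, 0, 0] * d0 + Rcub[i, 1, 0] * d1 + Rcub[i, 2, 0] * d2
            G[i, 1] += Rcub[i, 0, 1] * d0 + Rcub[i, 1, 1] * d1 + Rcub[i, 2, 1] * d2
            G[i, 2] += Rcub[i, 0, 2] * d0 + Rcub[i, 1, 2] * d1 + Rcub[i, 2, 2] * d2
        E -= mV[i] * (u[i, 0] * B[0] + u[i, 1] * B[1] + u[i, 2] * B[2])
        G[i, 0] -= mV[i] * B[0]
        G[i, 1] -= mV[i] * B[1]
        G[i, 2] -= mV[i] * B[2]
    for i in range(n):
        for j in range(i + 1, n):
            fx = F[i, j, 0, 0] * u[j, 0] + F[i, j, 0, 1] * u[j, 1] + F[i, j, 0, 2] * u[j, 2]
            fy = F[i, j, 1, 0] * u[j, 0] + F[i, j, 1, 1] * u[j, 1] + F[i, j, 1, 2] * u[j, 2]
            fz = F[i, j, 2, 0] * u[j, 0] + F[i, j, 2, 1] * u[j, 1] + F[i, j, 2, 2] * u[j, 2]
            E += u[i, 0] * fx + u[i, 1] * fy + u[i, 2] * fz
            G[i, 0] += fx
            G[i, 1] += fy
            G[i, 2] += fz
            G[j, 0] += F[i, j, 0, 0] * u[i, 0] + F[i, j, 1, 0] * u[i, 1] + F[i, j, 2, 0] * u[i, 2]
            G[j, 1] += F[i, j, 0, 1] * u[i, 0] + F[i, j, 1, 1] * u[i, 1] + F[i, j, 2, 1] * u[i, 2]
            G[j, 2] += F[i, j, 0, 2] * u[i, 0] + F[i, j, 1, 2] * u[i, 1] + F[i, j, 2, 2] * u[i, 2]
    return E, G


@njit(cache=True)
def _project(u, G):  # pragma: no cover - jitted
    n = u.shape[0]
    T = np.empty((n, 3))
    tmax = 0.0
    for i in range(n):
        dot = G[i, 0] * u[i, 0] + G[i, 1] * u[i, 1] + G[i, 2] * u[i, 2]
        tx = G[i, 0] - dot * u[i, 0]
        ty = G[i, 1] - dot * u[i, 1]
        tz = G[i, 2] - dot * u[i, 2]
        T[i, 0] = tx
        T[i, 1] = ty
        T[i, 2] = tz
        tn = np.sqrt(tx * tx + ty * ty + tz * tz)
        if tn > tmax:
            tmax = tn
    return T, tmax


@njit(cache=True)
def _normalize(u):  # pragma: no cover - jitted
    for i in range(u.shape[0]):
        nrm = np.sqrt(u[i, 0] ** 2 + u[i, 1] ** 2 + u[i, 2] ** 2)
        u[i, 0] /= nrm
        u[i, 1] /= nrm
        u[i, 2] /= nrm


@njit(cache=True)
def relax(u, S, Rcub, K1V, K2V, F, mV, B, tol, maxit, kick):  # pragma: no cover
    """Monotone projected BB descent to the local minimum; in-place on u.

    ``tol`` is the torque threshold in joules; ``kick`` applies the
    symmetric-breaking transverse perturbation before descending.
    Returns (energy, iterations, converged flag).
    """
    n = u.shape[0]
    if kick:
        for i in range(n):
            dot = _KICK[0] * u[i, 0] + _KICK[1] * u[i, 1] + _KICK[2] * u[i, 2]
            u[i, 0] += _KICK_EPS * (_KICK[0] - dot * u[i, 0])
            u[i, 1] += _KICK_EPS * (_KICK[1] - dot * u[i, 1])
            u[i, 2] += _KICK_EPS * (_KICK[2] - dot * u[i, 2])
        _normalize(u)
    E, G = energy_grad(u, S, Rcub, K1V, K2V, F, mV, B)
    T, tmax = _project(u, G)
    if tmax <= tol:
        return E, 0, True
    alpha = 1e-3 / tmax
    un = np.empty_like(u)
    it = 0
    for it in range(maxit):
        # proposed step, capped at 0.2 rad per moment
        step = alpha
        if step * tmax > 0.2:
            step = 0.2 / tmax
        for i in range(n):
            un[i, 0] = u[i, 0] - step * T[i, 0]
            un[i, 1] = u[i, 1] - step * T[i, 1]
            un[i, 2] = u[i, 2] - step * T[i, 2]
        _normalize(un)
        En, Gn = energy_grad(un, S, Rcub, K1V, K2V, F, mV, B)
        if En <= E:
            num = 0.0
            den = 0.0
            for i in range(n):
                for k in range(3):
                    du = un[i, k] - u[i, k]
                    dg = Gn[i, k] - G[i, k]
                    num += du * du
                    den += du * dg
            u[:, :] = un
            E = En
            G = Gn
            T, tmax = _project(u, G)
            if tmax <= tol:
                return E, it + 1, True
            if den > 0.0:
                bb = num / den
                hi = 10.0 * alpha
                lo = 0.1 * alpha
                alpha = bb if lo < bb < hi else (hi if bb >= hi else lo)
            else:
                alpha *= 1.5
        else:
            alpha *= 0.5
    return E, it + 1, tmax <= tol


@njit(cache=True)
def run_major_loop(u, S, Rcub, K1V, K2V, F, mV, bdir, bfields, tol, maxit):
    """Descending then ascending hysteresis branch.  ``bfields`` descends
    from +Bsat to -Bsat; returns (M_desc, M_asc) projections (A m^2) with
    M_asc indexed like bfields reversed."""
    m = bfields.shape[0]
    n = u.shape[0]
    M_desc = np.empty(m)
    M_asc = np.empty(m)
    B = np.empty(3)
    for idx in range(m):
        for k in range(3):
            B[k] = bdir[k] * bfields[idx]
        relax(u, S, Rcub, K1V, K2V, F, mV, B, tol, maxit, True)
        acc = 0.0
        for i in range(n):
            acc += mV[i] * (u[i, 0] * bdir[0] + u[i, 1] * bdir[1] + u[i, 2] * bdir[2])
        M_desc[idx] = acc
    for idx in range(m):
        for k in range(3):
            B[k] = bdir[k] * bfields[m - 1 - idx]
        relax(u, S, Rcub, K1V, K2V, F, mV, B, tol, maxit, True)
        acc = 0.0
        for i in range(n):
            acc += mV[i] * (u[i, 0] * bdir[0] + u[i, 1] * bdir[1] + u[i, 2] * bdir[2])
        M_asc[idx] = acc
    return M_desc, M_asc


@njit(cache=True)
def run_forc(u0, S, Rcub, K1V, K2V, F, mV, bdir, bfields, tol, maxit, jump_thr):
    """Full FORC protocol for one chain.  ``bfields`` descends from +Bsat
    to -Bsat in uniform steps.

    Returns ``(Mgrid, jumps, njump)``: ``Mgrid[ir, j]`` is the moment
    projection (A m^2) of the curve reversing at ``bfields[ir]`` measured
    at ``bfields[j]`` (valid for j <= ir; the diagonal is the descending
    branch), and ``jumps`` rows are (branch index ir or -1 for the
    descending branch, field index j, moment change dM).
    """
    m = bfields.shape[0]
    n = u0.shape[0]
    Mgrid = np.full((m, m), np.nan)
    max_events = 8 * m
    jumps = np.zeros((max_events, 3))
    njump = 0
    B = np.empty(3)
    # descending branch, caching states
    states = np.empty((m, n, 3))
    u = u0.copy()
    prevM = 0.0
    for idx in range(m):
        for k in range(3):
            B[k] = bdir[k] * bfields[idx]
        relax(u, S, Rcub, K1V, K2V, F, mV, B, tol, maxit, True)
        acc = 0.0
        for i in range(n):
            acc += mV[i] * (u[i, 0] * bdir[0] + u[i, 1] * bdir[1] + u[i, 2] * bdir[2])
        Mgrid[idx, idx] = acc
        states[idx] = u
        if idx > 0 and abs(acc - prevM) > jump_thr and njump < max_events:
            jumps[njump, 0] = -1.0
            jumps[njump, 1] = idx
            jumps[njump, 2] = acc - prevM
            njump += 1
        prevM = acc
    # first-order reversal curves
    u_branch = np.empty((n, 3))
    for ir in range(1, m):
        u_branch[:, :] = states[ir]
        prevM = Mgrid[ir, ir]
        for j in range(ir - 1, -1, -1):
            for k in range(3):
                B[k] = bdir[k] * bfields[j]
            relax(u_branch, S, Rcub, K1V, K2V, F, mV, B, tol, maxit, True)
            acc = 0.0
            for i in range(n):
                acc += mV[i] * (u_branch[i, 0] * bdir[0] + u_branch[i, 1] * bdir[1]
                                + u_branch[i, 2] * bdir[2])
            Mgrid[ir, j] = acc
            if abs(acc - prevM) > jump_thr and njump < max_events:
                jumps[njump, 0] = ir
                jumps[njump, 1] = j
                jumps[njump, 2] = acc - prevM
                njump += 1
            prevM = acc
    return Mgrid, jumps, njump
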