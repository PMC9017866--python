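"""Pairwise magnetostatic interaction tensors.

The interaction energy of two uniformly magnetized crystals with moment
directions ``u1``, ``u2`` is the bilinear form ``E = u1 . F . u2`` with a
3x3 coefficient matrix ``F`` (J).  For spheres the point-dipole expression
is exact; near-spherical ellipsoids are treated as point dipoles as well.
For faceted prismatic crystals the coefficients are obtained by numerical
quadrature of the Coulomb kernel over both crystal surfaces (surface
magnetic charges ``sigma = Ms u.n``), with optional Richardson
extrapolation over two mesh refinement levels.

Geometry is expressed in nanometres; returned tensors are in joules.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import MU0
from .shapes import MagnetosomeShape, ShapeKind

NM = 1e-9

__all__ = [
    "dipole_tensor",
    "interaction_tensor",
    "interaction_tensor_quadrature",
    "surface_mesh",
]


def dipole_tensor(r1: np.ndarray, r2: np.ndarray, m1: float, m2: float) -> np.ndarray:
    """Point-dipole interaction tensor (J) for moments m1, m2 (A m^2) at
    positions r1, r2 (nm)."""
    d = (np.asarray(r2, dtype=float) - np.asarray(r1, dtype=float)) * NM
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("coincident crystal centers")
    n = d / r
    return MU0 * m1 * m2 / (4.0 * math.pi * r**3) * (np.eye(3) - 3.0 * np.outer(n, n))


# ---------------------------------------------------------------------------
# surface meshes


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    t = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edge_mid: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in edge_mid:
            v = verts[i] + verts[j]
            v = v / np.linalg.norm(v)
            verts.append(v)
            edge_mid[key] = len(verts) - 1
        return edge_mid[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts), np.array(new_faces, dtype=np.int64)


def _triangles_to_quadrature(verts: np.ndarray, faces: np.ndarray):
    p0, p1, p2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    centroids = (p0 + p1 + p2) / 3.0
    cross = np.cross(p1 - p0, p2 - p0)
    areas2 = np.linalg.norm(cross, axis=1)
    keep = areas2 > 1e-30
    normals = np.zeros_like(cross)
    normals[keep] = cross[keep] / areas2[keep, None]
    return centroids[keep], normals[keep], 0.5 * areas2[keep]


def _ellipsoid_mesh(shape: MagnetosomeShape, level: int):
    verts, faces = _icosahedron()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
    verts = verts * np.asarray(shape.semi_axes)[None, :]
    return _triangles_to_quadrature(verts, faces)


def _cylinder_profile(z: np.ndarray, length: float, chamfer: float) -> np.ndarray:
    """Cross-section scale factor s(z) of the chamfered cylinder."""
    half = 0.5 * length
    h = chamfer * length
    s = np.ones_like(z)
    if h > 0:
        edge = np.abs(z) > half - h
        s[edge] = 1.0 - chamfer * (np.abs(z[edge]) - (half - h)) / h
    return s


def _cylinder_mesh(shape: MagnetosomeShape, level: int):
    nphi = 24 * 2**level
    nz = 12 * 2**level
    a = 0.5 * shape.diameter * shape.ellipticity
    b = 0.5 * shape.diameter / shape.ellipticity
    half = 0.5 * shape.length
    phi = np.linspace(0.0, 2.0 * math.pi, nphi + 1)
    z = np.linspace(-half, half, nz + 1)
    s = _cylinder_profile(z, shape.length, shape.chamfer_fraction)
    # lateral surface vertices (ring index, phi index)
    ring = np.stack(
        [np.outer(s, a * np.cos(phi)), np.outer(s, b * np.sin(phi)),
         np.repeat(z[:, None], nphi + 1, axis=1)],
        axis=-1,
    )
    verts = [ring.reshape(-1, 3)]
    faces = []
    stride = nphi + 1
    for iz in range(nz):
        for ip in range(nphi):
            v00 = iz * stride + ip
            v01 = v00 + 1
            v10 = v00 + stride
            v11 = v10 + 1
            faces.append([v00, v01, v10])
            faces.append([v01, v11, v10])
    offset = (nz + 1) * stride
    # end caps: triangulated fans over concentric rings
    nr = max(3, nz // 2)
    for zc, scale, orient in ((half, s[-1], 1), (-half, s[0], -1)):
        radii = np.linspace(0.0, 1.0, nr + 1)[1:]
        verts.append(np.array([[0.0, 0.0, zc]]))
        center = offset
        offset += 1
        ring_start = []
        for r in radii:
            ring_start.append(offset)
            ringv = np.stack(
                [scale * r * a * np.cos(phi[:-1]), scale * r * b * np.sin(phi[:-1]),
                 np.full(nphi, zc)], axis=-1)
            verts.append(ringv)
            offset += nphi
        for ip in range(nphi):
            ipn = (ip + 1) % nphi
            tri = [center, ring_start[0] + ip, ring_start[0] + ipn]
            faces.append(tri if orient > 0 else tri[::-1])
        for ir in range(len(radii) - 1):
            r0, r1 = ring_start[ir], ring_start[ir + 1]
            for ip in range(nphi):
                ipn = (ip + 1) % nphi
                t1 = [r0 + ip, r1 + ip, r1 + ipn]
                t2 = [r0 + ip, r1 + ipn, r0 + ipn]
                if orient > 0:
                    faces.extend([t1, t2])
                else:
                    faces.extend([t1[::-1], t2[::-1]])
    verts = np.concatenate(verts, axis=0)
    return _triangles_to_quadrature(verts, np.array(faces, dtype=np.int64))


def surface_mesh(shape: MagnetosomeShape, level: int = 3):
    """Triangulated surface quadrature (centroids nm, outward unit normals,
    areas nm^2) of a crystal shape.  ``level`` controls refinement."""
    if shape.kind is ShapeKind.ELLIPSOID:
        return _ellipsoid_mesh(shape, level)
    return _cylinder_mesh(shape, max(0, level - 2))


@njit(cache=True, fastmath=True)
def _pair_kernel(c1, n1, a1, c2, n2, a2):  # pragma: no cover - jitted
    T = np.zeros((3, 3))
    for i in range(c1.shape[0]):
        vx = 0.0
        vy = 0.0
        vz = 0.0
        for j in range(c2.shape[0]):
            dx = c1[i, 0] - c2[j, 0]
            dy = c1[i, 1] - c2[j, 1]
            dz = c1[i, 2] - c2[j, 2]
            w = a2[j] / math.sqrt(dx * dx + dy * dy + dz * dz)
            vx += w * n2[j, 0]
            vy += w * n2[j, 1]
            vz += w * n2[j, 2]
        wa = a1[i]
        for k in range(3):
            nk = n1[i, k] * wa
            T[k, 0] += nk * vx
            T[k, 1] += nk * vy
            T[k, 2] += nk * vz
    return T


def _quadrature_once(shape1, rot1, pos1, shape2, rot2, pos2, Ms, level):
    c1, n1, a1 = surface_mesh(shape1, level)
    c2, n2, a2 = surface_mesh(shape2, level)
    c1 = c1 @ rot1.T + np.asarray(pos1)[None, :]
    n1 = n1 @ rot1.T
    c2 = c2 @ rot2.T + np.asarray(pos2)[None, :]
    n2 = n2 @ rot2.T
    T = _pair_kernel(c1, n1, a1, c2, n2, a2)
    # centroids/areas in nm: 1/r in 1/nm, areas nm^2 -> net nm^3 -> convert
    return MU0 * Ms * Ms / (4.0 * math.pi) * T * NM**3


def interaction_tensor_quadrature(
    shape1: MagnetosomeShape,
    rot1: np.ndarray,
    pos1: np.ndarray,
    shape2: MagnetosomeShape,
    rot2: np.ndarray,
    pos2: np.ndarray,
    Ms: float,
    level: int = 3,
    extrapolate: bool = True,
) -> np.ndarray:
    """Interaction tensor by surface-charge quadrature.

    ``rot`` matrices map crystal-frame vectors to the lab frame; positions
    are in nm.  With ``extrapolate`` the tensor is Richardson-extrapolated
    from refinement levels (level-1, level), cancelling the leading
    O(h^2) centroid-rule error.
    """
    fine = _quadrature_once(shape1, rot1, pos1, shape2, rot2, pos2, Ms, level)
    if not extrapolate or level < 1:
        return fine
    coarse = _quadrature_once(shape1, rot1, pos1, shape2, rot2, pos2, Ms, level - 1)
    return fine + (fine - coarse) / 3.0


def interaction_tensor(
    crystal_i,
    crystal_j,
    Ms: float,
    level: int = 3,
    extrapolate: bool = True,
) -> np.ndarray:
    """Interaction tensor for two crystals, choosing the point-dipole form
    for (near-)spherical ellipsoids and surface-charge quadrature for
    faceted shapes.  Crystals must not overlap."""
    sep = np.linalg.norm(np.asarray(crystal_j.center) - np.asarray(crystal_i.center))
    if sep < 0.5 * (crystal_i.shape.equivalent_diameter + crystal_j.shape.equivalent_diameter) * 0.8:
        raise ValueError("crystals overlap or are unphysically close")
    if (
        crystal_i.shape.kind is ShapeKind.ELLIPSOID
        and crystal_j.shape.kind is ShapeKind.ELLIPSOID
    ):
        m1 = Ms * crystal_i.shape.volume * NM**3
        m2 = Ms * crystal_j.shape.volume * NM**3
        return dipole_tensor(crystal_i.center, crystal_j.center, m1, m2)
    return interaction_tensor_quadrature(
        crystal_i.shape, crystal_i.rotation, crystal_i.center,
        crystal_j.shape, crystal_j.rotation, crystal_j.center,
        Ms, level=level, extrapolate=extrapolate,
    )
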