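"""Construction of randomized magnetosome chain geometries.

Supported chain architectures:

``single``
    a single strand of crystals along one axis, with size tapering toward
    both extremities and optional smooth bending (circular arc);
``double_native``
    two parallel strands with staggered crystals (each crystal of one
    strand faces the gap between two crystals of the other), optional
    twisting about the common axis, tapering at both chain ends;
``double_folded``
    the product of folding a single strand at a kink: two antiparallel
    strands side-to-side (no stagger), with tapering only at the free ends;
``ring``
    crystals equally spaced on a circle (flux-closure prone geometry).

Conventions: lengths in nm; the chain axis is +z before any rigid-body
randomization; center spacing along a strand is half the axial extents of
the adjacent crystals plus ``gap_g`` times the reference crystal diameter;
strands of multi-stranded chains are separated laterally by one reference
diameter times ``(1 + gap_g)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .shapes import MagnetosomeShape, ShapeKind, ellipsoid, chamfered_cylinder, sphere

__all__ = [
    "ChainType",
    "MagnetosomeType",
    "ChainConfig",
    "Crystal",
    "ChainGeometry",
    "build_chain",
    "build_single_stranded",
    "build_double_stranded_native",
    "build_fold_collapsed",
    "build_ring",
    "randomize_orientation",
    "orient_axis",
    "sample_magnetosome",
    "chain_to_frame",
    "chain_from_frame",
]

_SQRT3 = math.sqrt(3.0)
#: rotation taking the cubic [111] axis onto +z (columns: images of x, y, z)
_R111 = None


def _rot_111_to_z() -> np.ndarray:
    global _R111
    if _R111 is None:
        z = np.array([1.0, 1.0, 1.0]) / _SQRT3
        x = np.array([1.0, -1.0, 0.0]) / math.sqrt(2.0)
        y = np.cross(z, x)
        _R111 = np.stack([x, y, z], axis=0)  # maps lab->cubic? rows are new basis
    return _R111


class ChainType(str, Enum):
    SINGLE = "single"
    DOUBLE_NATIVE = "double_native"
    DOUBLE_FOLDED = "double_folded"
    RING = "ring"


class MagnetosomeType(str, Enum):
    EQUANT = "equant"
    PRISMATIC = "prismatic"


@dataclass(frozen=True)
class ChainConfig:
    """Control parameters of one chain realization.

    ``mean_size`` is the mean crystal diameter for equant magnetosomes and
    the mean crystal length for prismatic ones; ``width`` applies to
    prismatic crystals only.  ``gap_g`` is the surface-to-surface gap
    normalized by the reference diameter (crystal width).  ``tapering`` is
    the fractional size reduction reached at the outermost crystal of a
    tapered chain end, applied linearly over ``taper_span`` crystals.
    """

    chain_type: ChainType = ChainType.SINGLE
    magnetosome_type: MagnetosomeType = MagnetosomeType.EQUANT
    n_crystals: int | tuple[int, int] = 15
    mean_size: float = 50.0
    width: float = 40.0
    size_cv: float = 0.15
    gap_g: float = 0.1
    tapering: float = 0.2
    taper_span: int = 3
    misorientation_deg: float = 5.0
    axis_ratio_sigma: float = 0.04
    chamfer_fraction: float = 0.2
    bend_curvature_max: float = 0.0
    twist_deg_per_crystal: float = 0.0
    strand_lag: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_crystals
        ntot = n if isinstance(n, int) else sum(n)
        if ntot < 2:
            raise ValueError("need at least two crystals")
        if self.gap_g < 0:
            raise ValueError("gap_g must be non-negative")
        if not (0.0 <= self.tapering < 1.0):
            raise ValueError("tapering must be in [0, 1)")
        if not (0.0 <= self.strand_lag < 1.0):
            raise ValueError("strand_lag must be in [0, 1)")
        if self.mean_size <= 0 or self.width <= 0:
            raise ValueError("sizes must be positive")

    @property
    def reference_diameter(self) -> float:
        """Crystal width used to normalize gaps and lateral strand spacing."""
        if self.magnetosome_type is MagnetosomeType.EQUANT:
            return self.mean_size
        return self.width

    @property
    def strand_counts(self) -> tuple[int, int]:
        n = self.n_crystals
        if isinstance(n, int):
            if self.chain_type in (ChainType.DOUBLE_NATIVE, ChainType.DOUBLE_FOLDED):
                return (n - n // 2, n // 2)
            return (n, 0)
        return tuple(n)  # type: ignore[return-value]


@dataclass
class Crystal:
    """A single magnetosome crystal in the lab frame.

    ``rotation`` maps shape-frame vectors (symmetry axis along +z for
    elongated shapes) to the lab frame; ``cubic_rotation`` does the same
    for the cubic crystallographic axes.
    """

    center: np.ndarray
    shape: MagnetosomeShape
    rotation: np.ndarray
    cubic_rotation: np.ndarray
    strand: int = 0

    @property
    def easy_axis_set(self) -> np.ndarray:
        """The four <111> directions in the lab frame (4, 3), unit vectors."""
        dirs = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / _SQRT3
        return dirs @ self.cubic_rotation.T

    @property
    def volume(self) -> float:
        return self.shape.volume


@dataclass
class ChainGeometry:
    """A fully specified chain: ordered crystals plus metadata."""

    crystals: list[Crystal]
    chain_axis: np.ndarray
    chain_type: ChainType
    config: ChainConfig | None = None

    def __len__(self) -> int:
        return len(self.crystals)

    @property
    def n(self) -> int:
        return len(self.crystals)

    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.crystals])

    def volumes(self) -> np.ndarray:
        return np.array([c.shape.volume for c in self.crystals])

    def rotations(self) -> np.ndarray:
        return np.array([c.rotation for c in self.crystals])

    def cubic_rotations(self) -> np.ndarray:
        return np.array([c.cubic_rotation for c in self.crystals])

    def strands(self) -> np.ndarray:
        return np.array([c.strand for c in self.crystals])

    def min_surface_separation(self) -> float:
        """Conservative minimum surface-to-surface distance (nm) over all
        crystal pairs, using capsule approximations of the crystals."""
        caps = [_capsule(c) for c in self.crystals]
        best = math.inf
        for i in range(len(caps)):
            for j in range(i + 1, len(caps)):
                d = _segment_distance(*caps[i][:2], *caps[j][:2])
                best = min(best, d - caps[i][2] - caps[j][2])
        return best


def _capsule(c: Crystal) -> tuple[np.ndarray, np.ndarray, float]:
    """(endpoint a, endpoint b, radius) capsule approximation in nm."""
    if c.shape.kind is ShapeKind.ELLIPSOID:
        sa = np.asarray(c.shape.semi_axes)
        r = float(min(sa))
        longest = int(np.argmax(sa))
        h = float(sa[longest] - r)
        axis = c.rotation[:, longest]
    else:
        r = 0.5 * c.shape.diameter * max(c.shape.ellipticity, 1.0 / c.shape.ellipticity)
        h = max(0.5 * c.shape.length - r, 0.0)
        axis = c.rotation[:, 2]
    return c.center - h * axis, c.center + h * axis, r


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= 1e-30 and e <= 1e-30:
        return float(np.linalg.norm(r))
    if a <= 1e-30:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-30:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-30 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


# ---------------------------------------------------------------------------
# sampling helpers


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * s2
    return float(rng.lognormal(mu, math.sqrt(s2)))


def _axis_align_rotation(target: np.ndarray, spin: float) -> np.ndarray:
    """Rotation whose +z axis maps onto ``target`` with roll angle ``spin``."""
    z = target / np.linalg.norm(target)
    a = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(a, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    cs, sn = math.cos(spin), math.sin(spin)
    xr = cs * x + sn * y
    yr = np.cross(z, xr)
    return np.stack([xr, yr, z], axis=1)


def _perturbed_axis(axis: np.ndarray, sigma_deg: float, rng: np.random.Generator) -> np.ndarray:
    if sigma_deg <= 0:
        return axis / np.linalg.norm(axis)
    ang = abs(rng.normal(0.0, math.radians(sigma_deg)))
    azi = rng.uniform(0.0, 2.0 * math.pi)
    z = axis / np.linalg.norm(axis)
    a = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(a, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    v = math.cos(ang) * z + math.sin(ang) * (math.cos(azi) * x + math.sin(azi) * y)
    return v / np.linalg.norm(v)


def sample_magnetosome(
    config: ChainConfig,
    position_in_chain: float,
    rng: np.random.Generator,
    local_axis: np.ndarray | None = None,
    size_factor: float = 1.0,
) -> Crystal:
    """Draw one crystal: size from a lognormal distribution, shape according
    to the magnetosome type, and crystallographic orientation with one <111>
    axis within the configured misorientation of the local chain axis.

    ``position_in_chain`` is the fractional position (0..1) along the chain
    (kept for profile-dependent sampling); ``size_factor`` applies the
    tapering profile.  The crystal is returned centred at the origin.
    """
    del position_in_chain  # distributions are currently position independent
    axis = np.array([0.0, 0.0, 1.0]) if local_axis is None else np.asarray(local_axis, float)
    target = _perturbed_axis(axis, config.misorientation_deg, rng)
    spin = rng.uniform(0.0, 2.0 * math.pi)
    if config.magnetosome_type is MagnetosomeType.EQUANT:
        d = _lognormal(rng, config.mean_size, config.size_cv) * size_factor
        if config.axis_ratio_sigma > 0:
            f = np.exp(rng.normal(0.0, config.axis_ratio_sigma, size=2))
        else:
            f = np.ones(2)
        fz = 1.0 / (f[0] * f[1])
        scale = (f[0] * f[1] * fz) ** (1.0 / 3.0)  # = 1, keeps volume exact
        semi = 0.5 * d * np.array([f[0], f[1], fz]) / scale
        shape = ellipsoid(*semi)
        # crystal frame: cubic axes; align [111] with the (perturbed) axis
        cubic = _axis_align_rotation(target, spin) @ _rot_111_to_z()
        rot = cubic
    else:
        length = _lognormal(rng, config.mean_size, config.size_cv) * size_factor
        width = length * config.width / config.mean_size
        ell = float(np.exp(rng.normal(0.0, config.axis_ratio_sigma))) if config.axis_ratio_sigma > 0 else 1.0
        shape = chamfered_cylinder(length, width, config.chamfer_fraction, ell)
        rot = _axis_align_rotation(target, spin)
        cubic = rot @ _rot_111_to_z()
    return Crystal(center=np.zeros(3), shape=shape, rotation=rot, cubic_rotation=cubic)


# ---------------------------------------------------------------------------
# strand construction


def _taper_factors(n: int, tapering: float, span: int, ends: str = "both") -> np.ndarray:
    """Linear tapering profile: factor 1 - tapering at the outermost crystal,
    rising linearly to 1 over ``span`` crystals."""
    f = np.ones(n)
    if tapering <= 0 or span <= 0:
        return f
    ramp = 1.0 - tapering * (np.arange(span, 0, -1) - 0.0) / span
    m = min(span, n)
    if ends in ("both", "start"):
        f[:m] = np.minimum(f[:m], ramp[:m])
    if ends in ("both", "end"):
        f[n - m:] = np.minimum(f[n - m:], ramp[:m][::-1])
    return f


def _strand_positions(extents: Sequence[float], gap_nm: float) -> np.ndarray:
    """Axial center coordinates given crystal axial extents and a fixed gap."""
    z = np.zeros(len(extents))
    for i in range(1, len(extents)):
        z[i] = z[i - 1] + 0.5 * extents[i - 1] + 0.5 * extents[i] + gap_nm
    return z


def _bend(points: np.ndarray, curvature: float, plane_angle: float) -> np.ndarray:
    """Map straight-chain coordinates onto a circular arc of given curvature
    (1/nm).  The arc lies in the plane through the z axis at ``plane_angle``."""
    if curvature <= 0:
        return points
    R = 1.0 / curvature
    z = points[:, 2]
    x_loc = points[:, 0] * math.cos(plane_angle) + points[:, 1] * math.sin(plane_angle)
    y_loc = -points[:, 0] * math.sin(plane_angle) + points[:, 1] * math.cos(plane_angle)
    theta = z / R
    r = R - x_loc
    xb = R - r * np.cos(theta)
    zb = r * np.sin(theta)
    out = np.empty_like(points)
    out[:, 0] = xb * math.cos(plane_angle) - y_loc * math.sin(plane_angle)
    out[:, 1] = xb * math.sin(plane_angle) + y_loc * math.cos(plane_angle)
    out[:, 2] = zb
    return out


def _build_strand(
    config: ChainConfig,
    n: int,
    rng: np.random.Generator,
    taper_ends: str,
) -> list[Crystal]:
    factors = _taper_factors(n, config.tapering, config.taper_span, taper_ends)
    crystals = []
    for i in range(n):
        c = sample_magnetosome(
            config, i / max(n - 1, 1), rng, local_axis=np.array([0.0, 0.0, 1.0]),
            size_factor=factors[i],
        )
        crystals.append(c)
    extents = [c.shape.axial_extent if c.shape.kind is ShapeKind.CHAMFERED_CYLINDER
               else 2.0 * c.shape.semi_axes[2] for c in crystals]
    gap_nm = config.gap_g * config.reference_diameter
    z = _strand_positions(extents, gap_nm)
    for c, zi in zip(crystals, z):
        c.center = np.array([0.0, 0.0, zi])
    return crystals


def _apply_bend(crystals: list[Crystal], config: ChainConfig, rng: np.random.Generator) -> None:
    if config.bend_curvature_max <= 0:
        return
    curvature = rng.uniform(0.0, config.bend_curvature_max)
    plane = rng.uniform(0.0, 2.0 * math.pi)
    pts = np.array([c.center for c in crystals])
    bent = _bend(pts, curvature, plane)
    if curvature > 0:
        R = 1.0 / curvature
        for c, p_old, p_new in zip(crystals, pts, bent):
            theta = p_old[2] / R
            cs, sn = math.cos(theta), math.sin(theta)
            rotm = np.array([[cs * math.cos(plane) ** 2 + math.sin(plane) ** 2,
                              (cs - 1) * math.sin(plane) * math.cos(plane),
                              sn * math.cos(plane)],
                             [(cs - 1) * math.sin(plane) * math.cos(plane),
                              cs * math.sin(plane) ** 2 + math.cos(plane) ** 2,
                              sn * math.sin(plane)],
                             [-sn * math.cos(plane), -sn * math.sin(plane), cs]])
            c.center = p_new
            c.rotation = rotm @ c.rotation
            c.cubic_rotation = rotm @ c.cubic_rotation


_MAX_RETRIES = 8


class GeometryError(RuntimeError):
    pass


def _finalize(crystals, config, chain_type, min_sep_tol=-1e-9) -> ChainGeometry:
    chain = ChainGeometry(
        crystals=crystals,
        chain_axis=np.array([0.0, 0.0, 1.0]),
        chain_type=chain_type,
        config=config,
    )
    if chain.min_surface_separation() < min_sep_tol:
        raise GeometryError("crystal overlap after randomization")
    return chain


def build_single_stranded(config: ChainConfig, rng: np.random.Generator) -> ChainGeometry:
    if config.chain_type is not ChainType.SINGLE:
        raise ValueError("config.chain_type must be 'single'")
    for attempt in range(_MAX_RETRIES):
        sub = rng if attempt == 0 else np.random.default_rng(rng.integers(2**31))
        crystals = _build_strand(config, config.strand_counts[0], sub, taper_ends="both")
        _apply_bend(crystals, config, sub)
        try:
            return _finalize(crystals, config, ChainType.SINGLE)
        except GeometryError:
            continue
    raise GeometryError("could not generate a non-overlapping single-stranded chain")


def build_double_stranded_native(config: ChainConfig, rng: np.random.Generator) -> ChainGeometry:
    if config.chain_type is not ChainType.DOUBLE_NATIVE:
        raise ValueError("config.chain_type must be 'double_native'")
    n1, n2 = config.strand_counts
    lateral = config.reference_diameter * (1.0 + config.gap_g)
    for attempt in range(_MAX_RETRIES):
        sub = rng if attempt == 0 else np.random.default_rng(rng.integers(2**31))
        s1 = _build_strand(config, n1, sub, taper_ends="both")
        s2 = _build_strand(config, n2, sub, taper_ends="both")
        spacing = s1[1].center[2] - s1[0].center[2] if n1 > 1 else lateral
        twist = math.radians(config.twist_deg_per_crystal)
        lat = lateral
        z2 = [c.center[2] + config.strand_lag * spacing for c in s2]
        for lat_try in range(4):
            for c, z in zip(s2, z2):
                c.strand = 1
                phi = twist * (z / spacing) if spacing > 0 else 0.0
                c.center = np.array([lat * math.cos(phi), lat * math.sin(phi), z])
            # strand 1 stays on the axis; twist only winds strand 2's helix
            chain = ChainGeometry(crystals=s1 + s2, chain_axis=np.array([0.0, 0.0, 1.0]),
                                  chain_type=ChainType.DOUBLE_NATIVE, config=config)
            gap = chain.min_surface_separation()
            if gap >= -1e-9:
                return chain
            # large crystal-size draws can make diagonal neighbours touch;
            # nudge the strand outward by the deficit
            lat += -gap + 0.1
        continue
    raise GeometryError("could not generate a non-overlapping double-stranded chain")


def build_fold_collapsed(config: ChainConfig, rng: np.random.Generator) -> ChainGeometry:
    """Fold-collapsed double strand: side-to-side crystals (no stagger),
    antiparallel fold topology, tapering only at the free ends.

    The kink end is at the top of the strand (largest z); the free,
    tapered extremities are at the bottom.  In the crystal ordering strand
    2 is the reversed continuation of strand 1 (fold topology).
    """
    if config.chain_type is not ChainType.DOUBLE_FOLDED:
        raise ValueError("config.chain_type must be 'double_folded'")
    n1, n2 = config.strand_counts
    lateral = config.reference_diameter * (1.0 + config.gap_g)
    for attempt in range(_MAX_RETRIES):
        sub = rng if attempt == 0 else np.random.default_rng(rng.integers(2**31))
        s1 = _build_strand(config, n1, sub, taper_ends="start")
        s2 = _build_strand(config, n2, sub, taper_ends="start")
        lat = lateral
        for lat_try in range(4):
            for c in s2:
                c.strand = 1
                c.center = np.array([lat, 0.0, c.center[2]])
            ordered = s1 + s2[::-1]  # strand 2 continues from the kink downward
            chain = ChainGeometry(crystals=ordered, chain_axis=np.array([0.0, 0.0, 1.0]),
                                  chain_type=ChainType.DOUBLE_FOLDED, config=config)
            gap = chain.min_surface_separation()
            if gap >= -1e-9:
                return chain
            lat += -gap + 0.1
        continue
    raise GeometryError("could not generate a non-overlapping fold-collapsed chain")


def build_ring(
    n: int,
    diameter: float,
    gap_g: float,
    rng: np.random.Generator | None = None,
    randomize_plane: bool = False,
) -> ChainGeometry:
    """Ring of ``n`` identical spheres, adjacent centers separated by the
    chord ``diameter * (1 + gap_g)``; the ring lies in the xy-plane unless
    ``randomize_plane`` is set."""
    if n < 3:
        raise ValueError("ring needs at least 3 crystals")
    chord = diameter * (1.0 + gap_g)
    R = chord / (2.0 * math.sin(math.pi / n))
    psi = 2.0 * math.pi * np.arange(n) / n
    crystals = []
    for k in range(n):
        center = np.array([R * math.cos(psi[k]), R * math.sin(psi[k]), 0.0])
        crystals.append(
            Crystal(center=center, shape=sphere(diameter),
                    rotation=np.eye(3), cubic_rotation=np.eye(3))
        )
    cfg = ChainConfig(chain_type=ChainType.RING, n_crystals=n,
                      mean_size=diameter, gap_g=gap_g, size_cv=0.0,
                      tapering=0.0, misorientation_deg=0.0, axis_ratio_sigma=0.0)
    chain = ChainGeometry(crystals=crystals, chain_axis=np.array([0.0, 0.0, 1.0]),
                          chain_type=ChainType.RING, config=cfg)
    if randomize_plane:
        if rng is None:
            raise ValueError("randomize_plane requires an rng")
        chain = randomize_orientation(chain, rng)
    return chain


def build_chain(config: ChainConfig, rng: np.random.Generator | None = None) -> ChainGeometry:
    """Dispatch on ``config.chain_type``; creates the rng from
    ``config.seed`` when none is passed (deterministic geometries)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.chain_type is ChainType.SINGLE:
        return build_single_stranded(config, rng)
    if config.chain_type is ChainType.DOUBLE_NATIVE:
        return build_double_stranded_native(config, rng)
    if config.chain_type is ChainType.DOUBLE_FOLDED:
        return build_fold_collapsed(config, rng)
    n = config.n_crystals if isinstance(config.n_crystals, int) else sum(config.n_crystals)
    return build_ring(n, config.mean_size, config.gap_g)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Arvo's method via quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def orient_axis(chain: ChainGeometry, direction, rng: np.random.Generator) -> ChainGeometry:
    """Rigidly rotate the chain so its axis maps onto ``direction`` with a
    random roll angle about it."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    roll = rng.uniform(0.0, 2.0 * math.pi)
    rotm = _axis_align_rotation(d, roll) @ _axis_align_rotation(chain.chain_axis, 0.0).T
    return _rotate_chain(chain, rotm)


def randomize_orientation(chain: ChainGeometry, rng: np.random.Generator) -> ChainGeometry:
    """Rigidly rotate the whole chain by a uniformly random rotation about
    its centroid.  Returns a new ChainGeometry."""
    rotm = _random_rotation(rng)
    return _rotate_chain(chain, rotm)


def _rotate_chain(chain: ChainGeometry, rotm: np.ndarray) -> ChainGeometry:
    centers = chain.centers()
    centroid = centers.mean(axis=0)
    new = []
    for c in chain.crystals:
        new.append(
            Crystal(
                center=rotm @ (c.center - centroid) + centroid,
                shape=c.shape,
                rotation=rotm @ c.rotation,
                cubic_rotation=rotm @ c.cubic_rotation,
                strand=c.strand,
            )
        )
    return ChainGeometry(
        crystals=new,
        chain_axis=rotm @ chain.chain_axis,
        chain_type=chain.chain_type,
        config=chain.config,
    )


# ---------------------------------------------------------------------------
# CSV round-trip (one row per crystal)


def _quat_from_matrix(R: np.ndarray) -> np.ndarray:
    t = np.trace(R)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2
        return np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                         (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    i = int(np.argmax(np.diag(R)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = math.sqrt(max(R[i, i] - R[j, j] - R[k, k] + 1.0, 0.0)) * 2
    q = np.empty(4)
    q[0] = (R[k, j] - R[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (R[j, i] + R[i, j]) / s
    q[1 + k] = (R[k, i] + R[i, k]) / s
    return q


def _matrix_from_quat(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def chain_to_frame(chain: ChainGeometry):
    """Serialize a chain to a pandas DataFrame (one row per crystal)."""
    import pandas as pd

    rows = []
    for idx, c in enumerate(chain.crystals):
        q = _quat_from_matrix(c.rotation)
        qc = _quat_from_matrix(c.cubic_rotation)
        row = {
            "index": idx,
            "strand": c.strand,
            "x_nm": c.center[0], "y_nm": c.center[1], "z_nm": c.center[2],
            "kind": c.shape.kind.value,
            "qw": q[0], "qx": q[1], "qy": q[2], "qz": q[3],
            "cqw": qc[0], "cqx": qc[1], "cqy": qc[2], "cqz": qc[3],
        }
        if c.shape.kind is ShapeKind.ELLIPSOID:
            row.update(sa=c.shape.semi_axes[0], sb=c.shape.semi_axes[1],
                       sc=c.shape.semi_axes[2], length=np.nan, diameter=np.nan,
                       chamfer=np.nan, ellipticity=np.nan)
        else:
            row.update(sa=np.nan, sb=np.nan, sc=np.nan, length=c.shape.length,
                       diameter=c.shape.diameter, chamfer=c.shape.chamfer_fraction,
                       ellipticity=c.shape.ellipticity)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["chain_type"] = chain.chain_type.value
    return frame


def chain_from_frame(frame) -> ChainGeometry:
    crystals = []
    for _, row in frame.iterrows():
        if row["kind"] == ShapeKind.ELLIPSOID.value:
            shape = ellipsoid(row["sa"], row["sb"], row["sc"])
        else:
            shape = chamfered_cylinder(row["length"], row["diameter"],
                                       row["chamfer"], row["ellipticity"])
        crystals.append(
            Crystal(
                center=np.array([row["x_nm"], row["y_nm"], row["z_nm"]]),
                shape=shape,
                rotation=_matrix_from_quat(np.array([row["qw"], row["qx"], row["qy"], row["qz"]])),
                cubic_rotation=_matrix_from_quat(np.array([row["cqw"], row["cqx"], row["cqy"], row["cqz"]])),
                strand=int(row["strand"]),
            )
        )
    ctype = ChainType(frame.attrs.get("chain_type", "single"))
    return ChainGeometry(crystals=crystals, chain_axis=np.array([0.0, 0.0, 1.0]),
                         chain_type=ctype)
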