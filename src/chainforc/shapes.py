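"""Magnetosome crystal shapes.

Two idealized shapes cover the crystal morphologies handled by the package:

* near-isometric triaxial ellipsoids for equant (cuboctahedral) magnetosomes;
* chamfered cylinders with a slightly elliptical cross-section for prismatic
  magnetosomes, where the chamfer imitates the faceted crystal ends.

The chamfer is implemented as a conical-frustum cut: over the outer fraction
``chamfer_fraction`` of the half-length the cross-section scale decreases
linearly from 1 to ``1 - chamfer_fraction``.  This gives the closed-form
volume ``pi*a*b*L * (1 - 2 c^2 + 2/3 c^3)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class ShapeKind(str, Enum):
    ELLIPSOID = "ellipsoid"
    CHAMFERED_CYLINDER = "chamfered_cylinder"


@dataclass(frozen=True)
class MagnetosomeShape:
    """Geometric description of a single crystal.

    For ``ELLIPSOID`` the three semi-axes (nm) are given by ``semi_axes``.
    For ``CHAMFERED_CYLINDER`` the cylinder has total ``length`` (nm) along
    its symmetry axis, cross-section semi-axes ``diameter/2 * (ellipticity,
    1/ellipticity)`` and a chamfer cut described above.
    """

    kind: ShapeKind
    semi_axes: tuple[float, float, float] | None = None
    length: float | None = None
    diameter: float | None = None
    ellipticity: float = 1.0
    chamfer_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind is ShapeKind.ELLIPSOID:
            if self.semi_axes is None or any(a <= 0 for a in self.semi_axes):
                raise ValueError("ellipsoid requires three positive semi-axes")
        else:
            if self.length is None or self.diameter is None:
                raise ValueError("cylinder requires length and diameter")
            if self.length <= 0 or self.diameter <= 0:
                raise ValueError("cylinder dimensions must be positive")
            if not (0.0 <= self.chamfer_fraction < 0.5):
                raise ValueError("chamfer_fraction must be in [0, 0.5)")
            if self.ellipticity <= 0:
                raise ValueError("ellipticity must be positive")

    @property
    def volume(self) -> float:
        """Volume in nm^3 (closed form)."""
        if self.kind is ShapeKind.ELLIPSOID:
            a, b, c = self.semi_axes
            return 4.0 / 3.0 * math.pi * a * b * c
        a = 0.5 * self.diameter * self.ellipticity
        b = 0.5 * self.diameter / self.ellipticity
        c = self.chamfer_fraction
        return math.pi * a * b * self.length * (1.0 - 2.0 * c * c + 2.0 / 3.0 * c**3)

    @property
    def max_extent(self) -> float:
        """Diameter of the circumscribing sphere (nm), used for overlap tests."""
        if self.kind is ShapeKind.ELLIPSOID:
            return 2.0 * max(self.semi_axes)
        a = 0.5 * self.diameter * max(self.ellipticity, 1.0 / self.ellipticity)
        return 2.0 * math.hypot(0.5 * self.length, a)

    @property
    def axial_extent(self) -> float:
        """Extent along the crystal symmetry axis (nm)."""
        if self.kind is ShapeKind.ELLIPSOID:
            return 2.0 * self.semi_axes[2]
        return self.length

    @property
    def equivalent_diameter(self) -> float:
        """Diameter of the equal-volume sphere (nm)."""
        return (6.0 * self.volume / math.pi) ** (1.0 / 3.0)


def sphere(diameter: float) -> MagnetosomeShape:
    r = 0.5 * diameter
    return MagnetosomeShape(kind=ShapeKind.ELLIPSOID, semi_axes=(r, r, r))


def ellipsoid(a: float, b: float, c: float) -> MagnetosomeShape:
    """Triaxial ellipsoid with semi-axes (a, b, c) in nm; c is the chain axis."""
    return MagnetosomeShape(kind=ShapeKind.ELLIPSOID, semi_axes=(a, b, c))


def chamfered_cylinder(
    length: float,
    diameter: float,
    chamfer_fraction: float = 0.0,
    ellipticity: float = 1.0,
) -> MagnetosomeShape:
    return MagnetosomeShape(
        kind=ShapeKind.CHAMFERED_CYLINDER,
        length=length,
        diameter=diameter,
        chamfer_fraction=chamfer_fraction,
        ellipticity=ellipticity,
    )
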