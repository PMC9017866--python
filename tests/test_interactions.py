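"""Magnetostatic interaction tensors: dipole limit and quadrature."""
import math

import numpy as np
import pytest

from chainforc.constants import KB, MS_MAGNETITE, MU0, T_ROOM
from chainforc.interactions import (NM, dipole_tensor, interaction_tensor,
                                    interaction_tensor_quadrature)
from chainforc.shapes import chamfered_cylinder, sphere
from chainforc.chains import Crystal

MS = MS_MAGNETITE
EYE = np.eye(3)


def _sphere_crystal(center, d=50.0):
    return Crystal(center=np.asarray(center, float), shape=sphere(d),
                   rotation=np.eye(3), cubic_rotation=np.eye(3))


def test_two_sphere_axial_pair_energy_closed_form():
    """Two 50-nm spheres 55 nm apart, both moments axial: the interaction
    energy is -2 mu0 m^2/(4 pi r^3), about -293 kT at room temperature."""
    m = MS * math.pi * (50e-9) ** 3 / 6
    F = dipole_tensor([0, 0, 0], [0, 0, 55.0], m, m)
    e_axial = np.array([0, 0, 1.0]) @ F @ np.array([0, 0, 1.0])
    expected = -2 * MU0 * m * m / (4 * math.pi * (55e-9) ** 3)
    assert e_axial == pytest.approx(expected, rel=1e-12)
    assert e_axial / (KB * T_ROOM) == pytest.approx(-293.3, abs=0.3)


@pytest.mark.parametrize("sep", [55.0, 100.0, 500.0])
def test_sphere_quadrature_matches_point_dipole(sep):
    """Uniformly magnetized spheres interact exactly as point dipoles; the
    surface-charge quadrature must agree to 1e-4 relative."""
    m = MS * math.pi * (50e-9) ** 3 / 6
    sh = sphere(50.0)
    Fq = interaction_tensor_quadrature(sh, EYE, np.zeros(3), sh, EYE,
                                       np.array([0, 0, sep]), MS, level=4)
    Fd = dipole_tensor(np.zeros(3), np.array([0, 0, sep]), m, m)
    assert np.max(np.abs(Fq - Fd)) <= 1e-4 * np.max(np.abs(Fd))


def test_cylinder_pair_far_field_approaches_dipole():
    """The faceted-crystal tensor converges to the point-dipole form with
    the expected multipole decay: below 1 percent at 10 crystal sizes and
    shrinking at least quadratically with separation."""
    sh = chamfered_cylinder(60, 40, 0.2)
    m = MS * sh.volume * NM**3

    def relerr(sep):
        Fq = interaction_tensor_quadrature(sh, EYE, np.zeros(3), sh, EYE,
                                           np.array([0, 0, sep]), MS, level=3)
        Fd = dipole_tensor(np.zeros(3), np.array([0, 0, sep]), m, m)
        return np.max(np.abs(Fq - Fd)) / np.max(np.abs(Fd))

    e10 = relerr(600.0)
    e20 = relerr(1200.0)
    assert e10 < 1e-2
    assert e20 < 0.5 * e10


def test_interaction_reciprocity():
    """F_ij(u1, u2) = F_ji(u2, u1): the tensor of the swapped pair is the
    transpose."""
    sh = chamfered_cylinder(60, 40, 0.2)
    r1 = np.zeros(3)
    r2 = np.array([10.0, 20.0, 60.0])
    F12 = interaction_tensor_quadrature(sh, EYE, r1, sh, EYE, r2, MS, level=2)
    F21 = interaction_tensor_quadrature(sh, EYE, r2, sh, EYE, r1, MS, level=2)
    assert np.allclose(F12, F21.T, rtol=1e-10, atol=1e-30)


def test_interaction_tensor_rejects_overlap():
    c1 = _sphere_crystal([0, 0, 0])
    c2 = _sphere_crystal([0, 0, 20.0])
    with pytest.raises(ValueError):
        interaction_tensor(c1, c2, MS)


def test_interaction_tensor_dispatches_to_dipole_for_spheres():
    c1 = _sphere_crystal([0, 0, 0])
    c2 = _sphere_crystal([0, 0, 55.0])
    m = MS * c1.shape.volume * NM**3
    F = interaction_tensor(c1, c2, MS)
    Fd = dipole_tensor(c1.center, c2.center, m, m)
    assert np.allclose(F, Fd)
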