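"""Energy model invariants."""
import math

import numpy as np
import pytest

from chainforc.chains import (ChainConfig, ChainType, MagnetosomeType,
                              build_chain, randomize_orientation)
from chainforc.constants import (KB, MAGNETITE, MAGNETITE_ISOTROPIC,
                                 MaterialParams, MU0, T_ROOM)
from chainforc.energy import build_energy_model, energy_terms, total_energy


def _ideal_chain(n=4):
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=n, size_cv=0.0,
                      tapering=0.0, misorientation_deg=0.0, axis_ratio_sigma=0.0)
    return build_chain(cfg)


def _random_state(n, rng):
    u = rng.standard_normal((n, 3))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def test_time_reversal_symmetry_in_zero_field():
    """Flipping every moment leaves the zero-field energy unchanged."""
    chain = _ideal_chain(6)
    model = build_energy_model(chain, MAGNETITE)
    rng = np.random.default_rng(0)
    u = _random_state(6, rng)
    e1 = total_energy(model, u)
    e2 = total_energy(model, -u)
    assert e2 == pytest.approx(e1, rel=1e-12)


def test_isolated_isotropic_sphere_energy_is_directionless():
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=2, gap_g=100.0,
                      size_cv=0.0, tapering=0.0, misorientation_deg=0.0,
                      axis_ratio_sigma=0.0)
    chain = build_chain(cfg)
    model = build_energy_model(chain, MAGNETITE_ISOTROPIC, isotropic_shapes=True)
    rng = np.random.default_rng(1)
    energies = [total_energy(model, _random_state(2, rng)) for _ in range(16)]
    scale = MU0 * MAGNETITE.Ms**2 * model.mV[0] / MAGNETITE.Ms
    assert np.ptp(energies) < 1e-6 * scale


def test_energy_invariant_under_rigid_rotation_of_everything():
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=5,
                      magnetosome_type=MagnetosomeType.EQUANT, seed=2)
    chain = build_chain(cfg)
    rng = np.random.default_rng(3)
    rotated = randomize_orientation(chain, rng)
    rotm = rotated.crystals[0].rotation @ chain.crystals[0].rotation.T
    m1 = build_energy_model(chain, MAGNETITE)
    m2 = build_energy_model(rotated, MAGNETITE)
    u = _random_state(5, rng)
    B = np.array([0.01, -0.02, 0.05])
    e1 = total_energy(m1, u, B)
    e2 = total_energy(m2, u @ rotm.T, rotm @ B)
    assert e2 == pytest.approx(e1, rel=1e-9)


def test_cubic_term_with_negative_k1_prefers_111():
    """For K1 < 0 the magnetocrystalline energy is minimized along <111>."""
    chain = _ideal_chain(2)
    for c in chain.crystals:
        c.cubic_rotation = np.eye(3)
    model = build_energy_model(chain, MaterialParams(K1=-1.1e4))
    rng = np.random.default_rng(4)
    u111 = np.tile(np.array([1.0, 1, 1]) / math.sqrt(3), (2, 1))
    e111 = energy_terms(model, u111, np.zeros(3))["magnetocrystalline"]
    for _ in range(1000):
        u = _random_state(2, rng)
        e = energy_terms(model, u, np.zeros(3))["magnetocrystalline"]
        assert e >= e111 - 1e-30


def test_shape_term_prefers_long_axis():
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=2,
                      magnetosome_type=MagnetosomeType.PRISMATIC, size_cv=0.0,
                      tapering=0.0, misorientation_deg=0.0, axis_ratio_sigma=0.0)
    chain = build_chain(cfg)
    model = build_energy_model(chain, MAGNETITE)
    axis = chain.crystals[0].rotation[:, 2]
    perp = chain.crystals[0].rotation[:, 0]
    u_long = np.tile(axis, (2, 1))
    u_perp = np.tile(perp, (2, 1))
    e_long = energy_terms(model, u_long, np.zeros(3))["shape"]
    e_perp = energy_terms(model, u_perp, np.zeros(3))["shape"]
    assert e_long < e_perp


def test_two_sphere_pair_states_closed_form():
    """Aligned axial pair vs coherently perpendicular pair differ by
    3 mu0 m^2/(4 pi r^3)."""
    chain = _ideal_chain(2)
    model = build_energy_model(chain, MAGNETITE_ISOTROPIC, isotropic_shapes=True)
    u_axial = np.array([[0, 0, 1.0], [0, 0, 1.0]])
    u_perp = np.array([[1.0, 0, 0], [1.0, 0, 0]])
    m = model.mV[0]
    expected = 3 * MU0 * m * m / (4 * math.pi * (55e-9) ** 3)
    diff = total_energy(model, u_perp) - total_energy(model, u_axial)
    assert diff == pytest.approx(expected, rel=1e-9)
    assert diff / (KB * T_ROOM) == pytest.approx(439.93, abs=0.05)


def test_total_energy_validates_input():
    chain = _ideal_chain(3)
    model = build_energy_model(chain, MAGNETITE)
    with pytest.raises(ValueError):
        total_energy(model, np.zeros((2, 3)))
    with pytest.raises(ValueError):
        total_energy(model, np.full((3, 3), 2.0))
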