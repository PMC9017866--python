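"""LEM tracking: relaxation, sweeps and FORC grids."""
import math

import numpy as np
import pytest

from chainforc.chains import ChainConfig, ChainType, MagnetosomeType, build_chain
from chainforc.constants import MAGNETITE, MAGNETITE_ISOTROPIC, MU0
from chainforc.demag import demag_tensor_ellipsoid
from chainforc.energy import build_energy_model, total_energy
from chainforc.simulate import (FieldProtocol, relax_state, simulate_forc,
                                sweep, write_forc_text, read_forc_text)
from chainforc.sw import anisotropy_field, switching_field_astroid


def _sw_particle(aspect=1.5, direction=(0, 0, 1.0)):
    """Single prolate crystal: the generic machinery's Stoner-Wohlfarth
    limit (shape anisotropy only)."""
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=2, gap_g=1000.0,
                      size_cv=0.0, tapering=0.0, misorientation_deg=0.0,
                      axis_ratio_sigma=0.0)
    chain = build_chain(cfg)
    # stretch both far-separated crystals into prolate spheroids with the
    # long (easy) axis along z
    from chainforc.shapes import ellipsoid

    for c in chain.crystals:
        c.shape = ellipsoid(25.0, 25.0, 25.0 * aspect)
        c.rotation = np.eye(3)
        c.cubic_rotation = np.eye(3)
    from chainforc.constants import MaterialParams

    return build_energy_model(chain, MaterialParams(K1=0.0))


def test_relax_is_idempotent_at_a_minimum():
    chain = build_chain(ChainConfig(chain_type=ChainType.SINGLE, n_crystals=5,
                                    size_cv=0.0, tapering=0.0,
                                    misorientation_deg=0.0, axis_ratio_sigma=0.0))
    model = build_energy_model(chain, MAGNETITE)
    u0 = np.tile([0.0, 0.0, 1.0], (5, 1))
    u1, e1 = relax_state(model, u0)
    u2, e2 = relax_state(model, u1)
    assert e2 <= e1 + 1e-30
    assert abs(e2 - e1) < 1e-12 * abs(e1)


def test_relax_never_increases_energy():
    chain = build_chain(ChainConfig(chain_type=ChainType.SINGLE, n_crystals=6, seed=8))
    model = build_energy_model(chain, MAGNETITE)
    rng = np.random.default_rng(5)
    for _ in range(5):
        u0 = rng.standard_normal((6, 3))
        u0 /= np.linalg.norm(u0, axis=1, keepdims=True)
        e0 = total_energy(model, u0)
        _, e1 = relax_state(model, u0)
        assert e1 <= e0 + 1e-25


def test_single_particle_switching_on_easy_axis():
    """Field antiparallel to the easy axis: switching at the full
    anisotropy field."""
    model = _sw_particle()
    bk = anisotropy_field(1.5)
    b, md, ma = sweep(model, protocol=FieldProtocol(b_sat=0.2, b_step=1e-3))
    ms = model.saturation_moment()
    drop = np.where(np.diff(md) < -ms)[0]
    assert len(drop) == 1
    b_sw = -b[drop[0] + 1]
    assert b_sw == pytest.approx(bk, abs=2e-3)


def test_single_particle_switching_at_45_degrees():
    """Stoner-Wohlfarth astroid: at 45 degrees the switching field is half
    the anisotropy field."""
    direction = np.array([1.0, 0, 1.0]) / math.sqrt(2)
    model = _sw_particle()
    bk = anisotropy_field(1.5)
    proto = FieldProtocol(b_sat=0.2, b_step=1e-3, direction=tuple(direction))
    b, md, ma = sweep(model, protocol=proto)
    ms_proj = model.saturation_moment()
    jumps = np.where(np.diff(md) < -0.2 * ms_proj)[0]
    assert len(jumps) >= 1
    b_sw = -b[jumps[0] + 1]
    assert b_sw == pytest.approx(0.5 * bk, abs=2.5e-3)
    assert switching_field_astroid(math.pi / 4, bk) == pytest.approx(0.5 * bk, rel=1e-9)


def test_major_loop_branch_symmetry():
    """For a symmetric system the ascending branch is the point reflection
    of the descending branch."""
    chain = build_chain(ChainConfig(chain_type=ChainType.SINGLE, n_crystals=8,
                                    size_cv=0.0, tapering=0.0,
                                    misorientation_deg=0.0, axis_ratio_sigma=0.0))
    model = build_energy_model(chain, MAGNETITE,
                               isotropic_shapes=True)
    proto = FieldProtocol(b_sat=0.3, b_step=3e-3,
                          direction=(0.3, 0.1, 0.95))
    b, md, ma = sweep(model, protocol=proto)
    ms = model.saturation_moment()
    assert np.max(np.abs(md - (-ma[::-1]))) < 1e-3 * ms


def test_reversible_system_has_zero_forc_function():
    """A uniaxial particle with the field perpendicular to its easy axis
    rotates reversibly: every reversal curve coincides with the major
    branch, no jumps are logged, and the FORC function vanishes."""
    model = _sw_particle()
    # threshold above the steep reversible step size so only genuine
    # Barkhausen jumps would be logged
    grid = simulate_forc(model, protocol=FieldProtocol(
        b_sat=0.05, b_step=2e-3, direction=(1.0, 0.0, 0.0)),
        jump_threshold_frac=0.1)
    from chainforc.variforc import compute_forc_distribution

    dist = compute_forc_distribution(grid)
    ms = model.saturation_moment()
    assert len(grid.jumps) == 0
    assert abs(dist.integral()) < 1e-3 * ms
    # all curves coincide with the descending branch
    m = len(grid.bfields)
    for ir in range(m):
        assert np.allclose(grid.Mgrid[ir, : ir + 1],
                           np.diagonal(grid.Mgrid)[: ir + 1], atol=1e-4 * ms)


def test_forc_saturation_closure_and_continuity():
    chain = build_chain(ChainConfig(chain_type=ChainType.SINGLE, n_crystals=6, seed=3))
    model = build_energy_model(chain, MAGNETITE)
    grid = simulate_forc(model, protocol=FieldProtocol(b_sat=0.3, b_step=3e-3))
    ms = model.saturation_moment()
    bdir_proj = grid.Mgrid[0, 0]
    # every curve rejoins the saturation state at +Bsat
    ends = grid.Mgrid[:, 0]
    assert np.nanmax(np.abs(ends - bdir_proj)) < 0.01 * ms


def test_forc_text_round_trip(tmp_path):
    chain = build_chain(ChainConfig(chain_type=ChainType.SINGLE, n_crystals=4, seed=1))
    model = build_energy_model(chain, MAGNETITE)
    grid = simulate_forc(model, protocol=FieldProtocol(b_sat=0.03, b_step=3e-3))
    path = tmp_path / "grid.txt"
    write_forc_text(grid, path)
    back = read_forc_text(path)
    assert np.allclose(back.bfields, grid.bfields, atol=1e-9)
    valid = np.isfinite(grid.Mgrid)
    assert np.allclose(back.Mgrid[valid], grid.Mgrid[valid], rtol=1e-6)
    assert back.Ms == pytest.approx(grid.Ms, rel=1e-6)
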