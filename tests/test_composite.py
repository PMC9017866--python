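"""Composite mixing and RPI proxy formulas."""
import math

import numpy as np
import pytest

from chainforc.composite import (CompositeSpec, RpiConfiguration, RpiParams,
                                 mix_composite, rpi_parameters)
from chainforc.chains import ChainConfig
from chainforc.fixtures import synthetic_forc_grid
from chainforc.variforc import compute_forc_distribution, extract_central_ridge


def test_single_component_mixing_is_identity():
    g = synthetic_forc_grid(ridge_mass=0.5)
    mixed = mix_composite([g], [1.0])
    valid = np.isfinite(g.Mgrid)
    assert np.allclose(mixed.Mgrid[valid], g.Mgrid[valid] / g.Ms)
    assert mixed.Ms == 1.0


def test_mixing_is_linear_in_saturation_fractions():
    g1 = synthetic_forc_grid(ridge_mass=0.5, mean_switching=30e-3)
    g2 = synthetic_forc_grid(ridge_mass=0.5, mean_switching=60e-3)
    mixed = mix_composite([g1, g2], [0.25, 0.75])
    valid = np.isfinite(g1.Mgrid)
    expected = 0.25 * g1.Mgrid[valid] / g1.Ms + 0.75 * g2.Mgrid[valid] / g2.Ms
    assert np.allclose(mixed.Mgrid[valid], expected)
    # linear statistics mix linearly
    def mcr(grid):
        dist = compute_forc_distribution(grid)
        extract_central_ridge(dist)
        return dist.integral(dist.rho_cr) / grid.Ms

    assert mcr(mixed) == pytest.approx(0.25 * mcr(g1) + 0.75 * mcr(g2), rel=0.02)


def test_mixing_validation():
    g1 = synthetic_forc_grid()
    g2 = synthetic_forc_grid(protocol=None)
    with pytest.raises(ValueError):
        mix_composite([g1, g2], [0.5])
    with pytest.raises(ValueError):
        mix_composite([g1, g2], [0.7, 0.7])
    from chainforc.simulate import FieldProtocol

    g3 = synthetic_forc_grid(protocol=FieldProtocol(b_sat=0.1, b_step=2e-3))
    with pytest.raises(ValueError):
        mix_composite([g1, g3], [0.5, 0.5])


def test_composite_spec_weight_validation():
    cfg = ChainConfig()
    with pytest.raises(ValueError):
        CompositeSpec(components=((cfg, 0.6), (cfg, 0.6)))
    spec = CompositeSpec(components=((cfg, 0.5), (cfg, 0.5)))
    assert spec.weights.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("cfg,n,dn,expect", [
    (RpiConfiguration.SINGLE_STRANDED, 10, 0, dict(m0=10, m_irm=5, m_arm=10,
                                                   r_irm=20, r_arm=10)),
    (RpiConfiguration.DOUBLE_STRANDED, 10, 2, dict(m0=10, m_irm=5, m_arm=2,
                                                   r_irm=20, r_arm=50)),
    (RpiConfiguration.FOLD_COLLAPSED, 10, 2, dict(m0=2, m_irm=5, m_arm=2,
                                                  r_irm=0.8, r_arm=2)),
])
def test_rpi_table_formulas(cfg, n, dn, expect):
    out = rpi_parameters(RpiParams(configuration=cfg, n=n, delta_n=dn))
    for key, val in expect.items():
        assert out[key] == pytest.approx(val, rel=1e-12), key


def test_rpi_silicate_inclusions_random_sum():
    out = rpi_parameters(RpiParams(configuration=RpiConfiguration.SILICATE_INCLUSIONS,
                                   n=25))
    assert out["m0"] == pytest.approx(math.sqrt(200 / (3 * math.pi)), rel=1e-12)
    assert out["r_irm"] == pytest.approx(16 / (3 * math.pi), rel=1e-12)


def test_rpi_degenerate_fold_at_the_middle():
    """A chain folded exactly in the middle carries no native moment."""
    out = rpi_parameters(RpiParams(configuration=RpiConfiguration.FOLD_COLLAPSED,
                                   n=10, delta_n=0))
    assert out["m0"] == 0.0
    assert out["r_irm"] == 0.0
    out2 = rpi_parameters(RpiParams(configuration=RpiConfiguration.DOUBLE_STRANDED,
                                    n=10, delta_n=0))
    assert out2["r_arm"] == math.inf


def test_rpi_validation():
    with pytest.raises(ValueError):
        RpiParams(configuration=RpiConfiguration.SINGLE_STRANDED, n=0)
    with pytest.raises(ValueError):
        RpiParams(configuration=RpiConfiguration.SINGLE_STRANDED, n=5, delta_n=9)
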