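"""Chain geometry construction contracts."""
import math

import numpy as np
import pytest
from scipy import stats

from chainforc.chains import (ChainConfig, ChainType, MagnetosomeType,
                              build_chain, build_double_stranded_native,
                              build_fold_collapsed, build_ring,
                              build_single_stranded, chain_from_frame,
                              chain_to_frame, randomize_orientation,
                              sample_magnetosome)


def _ideal_single(n=15, d=50.0, g=0.1, **kw):
    return ChainConfig(chain_type=ChainType.SINGLE, n_crystals=n, mean_size=d,
                       gap_g=g, size_cv=0.0, tapering=0.0, misorientation_deg=0.0,
                       axis_ratio_sigma=0.0, bend_curvature_max=0.0, **kw)


def test_single_strand_uniform_spacing():
    """Identical spheres with g = 0.1: consecutive centers 55 nm apart."""
    chain = build_chain(_ideal_single())
    z = np.sort(chain.centers()[:, 2])
    assert np.allclose(np.diff(z), 55.0, atol=1e-9)
    assert np.allclose(chain.centers()[:, :2], 0.0, atol=1e-9)


def test_seed_determinism_bit_for_bit():
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=9, seed=42)
    c1 = build_chain(cfg)
    c2 = build_chain(cfg)
    assert np.array_equal(c1.centers(), c2.centers())
    assert np.array_equal(c1.rotations(), c2.rotations())


def test_tapering_profile_monotone_to_the_middle():
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=9, tapering=0.3,
                      taper_span=3, size_cv=0.0, misorientation_deg=0.0,
                      axis_ratio_sigma=0.0)
    chain = build_chain(cfg)
    d = np.array([c.shape.equivalent_diameter for c in chain.crystals])
    mid = d[4]
    assert d[0] / mid == pytest.approx(0.7, rel=1e-9)
    assert d[-1] / mid == pytest.approx(0.7, rel=1e-9)
    assert np.all(np.diff(d[:5]) >= -1e-12)   # rising toward the middle
    assert np.all(np.diff(d[4:]) <= 1e-12)


def test_double_native_staggering_midpoint_property():
    """With lag 0.5 every strand-2 crystal is axially equidistant from its
    two nearest strand-1 neighbours."""
    cfg = ChainConfig(chain_type=ChainType.DOUBLE_NATIVE, n_crystals=(11, 10),
                      strand_lag=0.5, twist_deg_per_crystal=0.0, size_cv=0.0,
                      tapering=0.0, misorientation_deg=0.0, axis_ratio_sigma=0.0)
    chain = build_chain(cfg)
    z1 = np.sort([c.center[2] for c in chain.crystals if c.strand == 0])
    z2 = np.sort([c.center[2] for c in chain.crystals if c.strand == 1])
    for z in z2:
        below = z1[z1 < z]
        above = z1[z1 > z]
        if len(below) and len(above):
            assert (z - below.max()) == pytest.approx(above.min() - z, abs=1e-6)


def test_double_native_twist_keeps_cylindrical_radius():
    cfg = ChainConfig(chain_type=ChainType.DOUBLE_NATIVE, n_crystals=(8, 8),
                      twist_deg_per_crystal=10.0, size_cv=0.0, tapering=0.0,
                      misorientation_deg=0.0, axis_ratio_sigma=0.0)
    chain = build_chain(cfg)
    s2 = np.array([c.center for c in chain.crystals if c.strand == 1])
    radii = np.hypot(s2[:, 0], s2[:, 1])
    assert np.allclose(radii, radii[0], atol=1e-6)


def test_fold_collapsed_side_by_side_and_one_sided_taper():
    cfg = ChainConfig(chain_type=ChainType.DOUBLE_FOLDED, n_crystals=(11, 10),
                      strand_lag=0.0, tapering=0.3, taper_span=3, size_cv=0.0,
                      misorientation_deg=0.0, axis_ratio_sigma=0.0)
    chain = build_chain(cfg)
    s1 = [c for c in chain.crystals if c.strand == 0]
    s2 = [c for c in chain.crystals if c.strand == 1]
    z1 = np.array([c.center[2] for c in s1])
    z2 = np.array([c.center[2] for c in s2])
    # side-by-side: shared axial coordinates
    for z in z2:
        assert np.min(np.abs(z1 - z)) < 1e-6
    # tapering only at the free (low-z) ends: the kink-end crystals keep
    # full size, the free-end crystals are reduced
    d1 = np.array([c.shape.equivalent_diameter for c in s1])
    order = np.argsort(z1)
    assert d1[order][-1] == pytest.approx(50.0, rel=1e-9)
    assert d1[order][0] == pytest.approx(35.0, rel=1e-9)


def test_ring_chord_geometry():
    chain = build_ring(20, 50.0, 0.1)
    c = chain.centers()
    r = np.linalg.norm(c[:, :2], axis=1)
    assert np.allclose(r, 55.0 / (2 * math.sin(math.pi / 20)), rtol=1e-9)
    d = np.linalg.norm(np.roll(c, -1, axis=0) - c, axis=1)
    assert np.allclose(d, 55.0, rtol=1e-9)
    # n = 4 degenerates to a square of side d(1+g)
    sq = build_ring(4, 50.0, 0.1).centers()
    side = np.linalg.norm(np.roll(sq, -1, axis=0) - sq, axis=1)
    assert np.allclose(side, 55.0, rtol=1e-9)


def test_no_overlaps_across_randomized_chains():
    for ctype in ChainType:
        for seed in range(5):
            cfg = ChainConfig(chain_type=ctype, n_crystals=10, seed=seed)
            chain = build_chain(cfg)
            assert chain.min_surface_separation() >= -1e-9


def test_rigid_rotation_preserves_distances():
    rng = np.random.default_rng(0)
    chain = build_chain(_ideal_single(8))
    rotated = randomize_orientation(chain, rng)
    d0 = np.linalg.norm(chain.centers()[1:] - chain.centers()[:-1], axis=1)
    d1 = np.linalg.norm(rotated.centers()[1:] - rotated.centers()[:-1], axis=1)
    assert np.allclose(d0, d1, rtol=1e-9)
    for c in rotated.crystals:
        R = c.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


def test_orientation_distribution_is_uniform():
    """Rayleigh-type test: the mean of 10^4 random chain-axis images must
    be compatible with a uniform orientation distribution."""
    rng = np.random.default_rng(1)
    chain = build_chain(_ideal_single(3))
    axes = np.array([randomize_orientation(chain, rng).chain_axis
                     for _ in range(10_000)])
    mean_norm = np.linalg.norm(axes.mean(axis=0))
    # CLT: 3 sigma ~ 3/sqrt(3 n)
    assert mean_norm < 3.0 / math.sqrt(3 * len(axes))


def test_magnetosome_size_distribution_moments():
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=5, size_cv=0.1)
    rng = np.random.default_rng(3)
    diam = np.array([
        sample_magnetosome(cfg, 0.5, rng).shape.equivalent_diameter
        for _ in range(10_000)
    ])
    assert diam.mean() == pytest.approx(50.0, rel=0.01)
    assert diam.std() / diam.mean() == pytest.approx(0.1, abs=0.01)


def test_misorientation_zero_aligns_easy_axis_exactly():
    cfg = ChainConfig(chain_type=ChainType.SINGLE, n_crystals=5,
                      misorientation_deg=0.0, size_cv=0.0, axis_ratio_sigma=0.0)
    rng = np.random.default_rng(0)
    crystal = sample_magnetosome(cfg, 0.5, rng, local_axis=np.array([0, 0, 1.0]))
    angles = np.arccos(np.clip(np.abs(crystal.easy_axis_set @ [0, 0, 1.0]), 0, 1))
    assert angles.min() < 1e-9


def test_chain_csv_round_trip():
    cfg = ChainConfig(chain_type=ChainType.DOUBLE_NATIVE, n_crystals=(3, 3),
                      magnetosome_type=MagnetosomeType.PRISMATIC, seed=5)
    chain = build_chain(cfg)
    frame = chain_to_frame(chain)
    back = chain_from_frame(frame)
    assert np.allclose(back.centers(), chain.centers(), atol=1e-12)
    assert np.allclose(back.rotations(), chain.rotations(), atol=1e-9)
    assert back.strands().tolist() == chain.strands().tolist()


def test_config_validation():
    with pytest.raises(ValueError):
        ChainConfig(n_crystals=1)
    with pytest.raises(ValueError):
        ChainConfig(gap_g=-0.1)
    with pytest.raises(ValueError):
        ChainConfig(tapering=1.0)
    with pytest.raises(ValueError):
        build_single_stranded(ChainConfig(chain_type=ChainType.RING),
                              np.random.default_rng(0))
    with pytest.raises(ValueError):
        build_ring(2, 50.0, 0.1)
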