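"""Geometry and conductivity-map construction."""

import numpy as np
import pytest

from anisoblock.geometry import (
    REGION_ISOTROPIC,
    REGION_LONGITUDINAL,
    REGION_TRANSVERSE,
    TissueGeometry,
    build_conductivity,
    two_region_cable,
    two_region_sheet,
)


def test_isotropic_limit_gives_uniform_map():
    geom = two_region_cable(length_mm=8.0)
    cmap = build_conductivity(geom, ar=1.0, sigma_par=0.154)
    assert np.allclose(cmap.sigx, 0.154)


def test_perpendicular_coupling_follows_inverse_square_rule():
    geom = two_region_cable(length_mm=8.0)
    cmap = build_conductivity(geom, ar=2.0, sigma_par=0.154)
    assert cmap.sigma_perp == pytest.approx(0.0385)


def test_cable_has_exactly_one_conductivity_jump():
    geom = two_region_cable()          # 512 nodes, border at midpoint
    assert geom.nx == 512
    cmap = build_conductivity(geom, ar=4.0)
    row = cmap.sigx[0]
    jumps = np.nonzero(np.diff(row) != 0)[0]
    assert jumps.size == 1
    k = jumps[0]
    assert row[k] == pytest.approx(0.154 / 16)
    assert row[k + 1] == pytest.approx(0.154)


def test_sub_unity_ar_rejected():
    geom = two_region_cable(length_mm=8.0)
    with pytest.raises(ValueError, match="AR"):
        build_conductivity(geom, ar=0.5)


def test_anisotropic_regions_preserve_conductivity_product():
    geom = two_region_sheet(width_cm=0.8, height_cm=0.4, h_um=250.0)
    ar, sp = 3.0, 0.154
    cmap = build_conductivity(geom, ar, sp)
    prod = sp * sp / ar ** 2
    # x-links away from the border: sigx * sigy(label at same x) == par*perp
    region = geom.region_map()[0]
    for ix in (2, geom.nx - 3):
        assert cmap.sigx[0, ix] * cmap.sigy[0, ix] == pytest.approx(prod)
    # orientation: left region slow in x, right region fast in x
    assert cmap.sigx[0, 2] == pytest.approx(sp / ar ** 2)
    assert cmap.sigx[0, geom.nx - 3] == pytest.approx(sp)
    assert region[0] == REGION_TRANSVERSE and region[-1] == REGION_LONGITUDINAL


def test_isotropic_strip_coupling_modes():
    geom = two_region_sheet(width_cm=0.8, height_cm=0.4, h_um=250.0,
                            strip_halfwidth_mm=1.0)
    mid = geom.node_at_x(geom.border_x_mm)
    expect = {"par": 0.154, "perp": 0.154 / 4, "geometric": 0.154 / 2}
    for mode, sigma in expect.items():
        cmap = build_conductivity(geom, ar=2.0, strip_sigma=mode)
        assert np.all(cmap.sigy[:, mid] == pytest.approx(sigma))
        assert cmap.sigx[0, mid - 1] == pytest.approx(sigma)
    with pytest.raises(ValueError, match="strip_sigma"):
        build_conductivity(geom, ar=2.0, strip_sigma="odd")
    assert REGION_ISOTROPIC in geom.region_map()


def test_node_count_matches_grid():
    geom = two_region_sheet(width_cm=1.0, height_cm=0.5, h_um=250.0)
    assert geom.shape == (20, 40)
    assert geom.region_map().shape == (20, 40)


def test_border_must_be_inside_domain():
    with pytest.raises(ValueError):
        TissueGeometry(width_mm=10.0, height_mm=1.0, h_um=125.0, border_x_mm=10.0)


def test_geometry_dict_roundtrip_and_region_export(tmp_path):
    geom = two_region_sheet(width_cm=0.4, height_cm=0.2, h_um=250.0)
    again = TissueGeometry.from_dict(geom.as_dict())
    assert again == geom
    path = tmp_path / "regions.csv"
    geom.export_region_csv(path)
    grid = np.loadtxt(path, delimiter=",")
    assert grid.shape == geom.shape
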