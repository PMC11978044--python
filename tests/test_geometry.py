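import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoflow.geometry import (LumenGeometry, StenosisSpec, contains,
                                ellipse_section, lumen_volume, radius_profile)
from stenoflow.grid import build_grid


def make_geom(degree=0.4, kappa=1.0, R0=1.0, L=10.0):
    sten = StenosisSpec(degree=degree, length=2.0, center=5.0) \
        if degree > 0 else None
    return LumenGeometry(R0, L, ellipse_ratio=kappa, stenosis=sten)


class TestRadiusProfile:
    @pytest.mark.parametrize("z,degree,expected", [
        (1.0, 0.4, 1.0),    # far from the throat the vessel is unnarrowed
        (5.0, 0.4, 0.6),    # 40% diameter reduction at the throat
        (5.5, 0.8, 0.6),    # cosine bump at a quarter-length offset
        (9.0, 0.4, 1.0),
    ])
    def test_cosine_bump_values(self, z, degree, expected):
        assert radius_profile(z, make_geom(degree)) == pytest.approx(expected)

    def test_symmetric_about_throat(self):
        g = make_geom(0.6)
        d = np.linspace(0, 1.0, 11)
        np.testing.assert_allclose(radius_profile(5.0 - d, g),
                                   radius_profile(5.0 + d, g), rtol=1e-12)

    def test_smooth_at_window_edges(self):
        g = make_geom(0.6)
        eps = 1e-9
        assert radius_profile(4.0 - eps, g) == pytest.approx(
            radius_profile(4.0 + eps, g), abs=1e-6)

    def test_outside_segment_raises(self):
        with pytest.raises(ValueError):
            radius_profile(-0.5, make_geom())
        with pytest.raises(ValueError):
            radius_profile(10.5, make_geom())

    def test_throat_radius_positive(self):
        g = make_geom(0.8)
        z = np.linspace(0, 10, 401)
        assert np.all(radius_profile(z, g) >= 0.2 - 1e-12)


class TestEllipseSection:
    def test_circle_when_kappa_one(self):
        a, b = ellipse_section(3.0, make_geom(0.0, kappa=1.0))
        assert a == pytest.approx(1.0) and b == pytest.approx(1.0)

    def test_half_aspect(self):
        a, b = ellipse_section(3.0, make_geom(0.0, kappa=0.5))
        assert a == pytest.approx(np.sqrt(2.0))
        assert b == pytest.approx(1.0 / np.sqrt(2.0))
        assert a * b == pytest.approx(1.0)

    def test_boundary_point_containment(self):
        a, b = ellipse_section(3.0, make_geom(0.0, kappa=0.5))
        assert contains(a, 0.0, a, b)
        assert not contains(a * (1 + 1e-6), 0.0, a, b)

    @settings(deadline=None, max_examples=40)
    @given(kappa=st.floats(0.05, 1.0), z=st.floats(0.0, 10.0),
           degree=st.sampled_from([0.0, 0.4, 0.6, 0.8]))
    def test_area_preserved_for_every_kappa_and_z(self, kappa, z, degree):
        g = make_geom(degree, kappa=kappa)
        a, b = ellipse_section(z, g)
        r = radius_profile(z, g)
        assert a * b == pytest.approx(r * r, rel=1e-12)


class TestInvariants:
    def test_degree_range_enforced(self):
        with pytest.raises(ValueError):
            StenosisSpec(degree=1.0, length=1.0, center=5.0)
        with pytest.raises(ValueError):
            StenosisSpec(degree=-0.1, length=1.0, center=5.0)

    def test_window_must_fit_segment(self):
        with pytest.raises(ValueError):
            LumenGeometry(1.0, 10.0,
                          stenosis=StenosisSpec(0.4, 4.0, center=1.0))

    def test_kappa_range(self):
        with pytest.raises(ValueError):
            LumenGeometry(1.0, 10.0, ellipse_ratio=0.0)
        with pytest.raises(ValueError):
            LumenGeometry(1.0, 10.0, ellipse_ratio=1.2)


class TestMaskGeometryConsistency:
    def test_circular_mask_fraction_approaches_pi_over_4(self):
        # cell-center containment on an n x n box bounding the diameter
        n = 128
        x = (np.arange(n) + 0.5) / n * 2.0 - 1.0
        inside = (x[:, None] ** 2 + x[None, :] ** 2) < 1.0
        assert inside.mean() == pytest.approx(np.pi / 4.0, rel=0.02)

    def test_mask_volume_matches_quadrature(self):
        g = LumenGeometry(2e-3, 20e-3, ellipse_ratio=0.7,
                          stenosis=StenosisSpec(0.6, 4e-3, 10e-3))
        grid = build_grid(g, (96, 96, 64), mode="cart3d")
        assert grid.open_volume() == pytest.approx(lumen_volume(g), rel=0.02)

    def test_axisym_mask_volume_matches_quadrature(self):
        g = LumenGeometry(2e-3, 20e-3,
                          stenosis=StenosisSpec(0.6, 4e-3, 10e-3))
        grid = build_grid(g, (128, 256))
        assert grid.open_volume() == pytest.approx(lumen_volume(g), rel=0.02)
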