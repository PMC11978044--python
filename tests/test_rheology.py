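import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoflow.rheology import (FluidProperties, extra_stress_tensor,
                                shear_rate_magnitude, williamson_viscosity)


def simple_shear(kappa):
    g = np.zeros((3, 3))
    g[0, 1] = kappa
    return g


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return q


class TestShearRate:
    def test_simple_shear_recovers_rate(self):
        assert shear_rate_magnitude(simple_shear(3.7)) == pytest.approx(3.7)

    def test_rigid_rotation_is_zero(self):
        g = np.array([[0, 1, 0], [-1, 0, 0], [0, 0, 0.0]])
        assert shear_rate_magnitude(g) == pytest.approx(0.0, abs=1e-14)

    def test_uniaxial_extension(self):
        e = 0.9
        g = np.diag([e, -e / 2, -e / 2])
        assert shear_rate_magnitude(g) == pytest.approx(np.sqrt(3) * e)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=(3, 3))
        R = random_rotation(seed + 1)
        gr = R @ g @ R.T
        assert shear_rate_magnitude(gr) == pytest.approx(
            shear_rate_magnitude(g), rel=1e-10)

    def test_nonfinite_rejected(self):
        g = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            shear_rate_magnitude(g)


class TestWilliamsonViscosity:
    def setup_method(self):
        self.p = FluidProperties()

    def test_zero_shear_limit(self):
        assert williamson_viscosity(0.0, self.p) == self.p.mu0

    def test_infinite_shear_limit(self):
        assert williamson_viscosity(1e12, self.p) == pytest.approx(
            self.p.mu_inf, rel=1e-6)

    def test_halfway_at_unit_weissenberg(self):
        gd = 1.0 / self.p.lam
        expected = self.p.mu_inf + (self.p.mu0 - self.p.mu_inf) / 2.0
        assert williamson_viscosity(gd, self.p) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(g1=st.floats(0, 1e4), g2=st.floats(0, 1e4))
    def test_monotone_shear_thinning(self, g1, g2):
        lo, hi = sorted([g1, g2])
        assert williamson_viscosity(lo, self.p) >= williamson_viscosity(
            hi, self.p)
        assert self.p.mu_inf < williamson_viscosity(hi, self.p) <= self.p.mu0

    def test_newtonian_when_lam_zero(self):
        p = FluidProperties.newtonian(0.004)
        gd = np.linspace(0, 1e3, 7)
        np.testing.assert_allclose(williamson_viscosity(gd, p), 0.004)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            williamson_viscosity(-1.0, self.p)

    def test_property_validation(self):
        with pytest.raises(ValueError):
            FluidProperties(mu0=0.001, mu_inf=0.01)
        with pytest.raises(ValueError):
            FluidProperties(lam=-1.0)


class TestExtraStress:
    def test_zero_gradient_zero_stress(self):
        assert np.allclose(extra_stress_tensor(np.zeros((3, 3)), 0.05, 0.1),
                           0.0)

    def test_newtonian_limit_gamma_zero(self):
        k = 2.5
        s = extra_stress_tensor(simple_shear(k), eta0=0.05, Gamma=0.0)
        assert s[0, 1] == pytest.approx(0.05 * k)
        assert s[0, 1] == s[1, 0]

    def test_linear_williamson_shear(self):
        k, eta0, G = 2.0, 0.05, 0.1
        s = extra_stress_tensor(simple_shear(k), eta0, G)
        assert s[0, 1] == pytest.approx(eta0 * (1 + G * k) * k)

    def test_symmetric_and_traceless_incompressible(self):
        rng = np.random.default_rng(7)
        g = rng.normal(size=(3, 3))
        g -= np.eye(3) * np.trace(g) / 3.0  # incompressible gradient
        s = extra_stress_tensor(g, 0.05, 0.01)
        np.testing.assert_allclose(s, s.T)
        assert abs(np.trace(s)) < 1e-12

    def test_validity_warning(self):
        with pytest.warns(RuntimeWarning):
            extra_stress_tensor(simple_shear(100.0), 0.05, 1.0)
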