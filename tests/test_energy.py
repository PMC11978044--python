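import copy

import numpy as np
import pytest

from stenoflow import (DimensionlessGroups, FluidProperties, make_case,
                       solve_energy, solve_steady)
from stenoflow.energy import (default_thermal_bc, dissipation_source,
                              wall_heat_balance)
from stenoflow.verification import couette_energy_error


@pytest.fixture(scope="module")
def heated_tube():
    cfg = make_case("healthy", resolution=(24, 96))
    flow, hist = solve_steady(cfg)
    assert hist.converged
    return cfg, flow


def groups_for(cfg, Pr=2.0, Br=0.0):
    g = cfg.resolved_groups()
    return DimensionlessGroups(Re=g.Re, Pr=Pr, Br=Br, beta=g.u0 * g.L
                               / (g.Re * Pr), u0=g.u0, L=g.L,
                               Ti=g.Ti, Tb=g.Tb)


class TestHomogeneousAndBounds:
    def test_no_dissipation_no_heating_gives_zero_field(self, heated_tube):
        cfg, flow = heated_tube
        g = groups_for(cfg, Br=0.0)
        bc = {"inlet": ("dirichlet", 0.0), "outlet": ("neumann", 0.0),
              "wall": ("dirichlet", 0.0)}
        temp = solve_energy(flow, cfg.grid, cfg.fluid, g, bc=bc)
        assert np.abs(temp.theta).max() < 1e-12

    def test_maximum_principle_hot_wall(self, heated_tube):
        cfg, flow = heated_tube
        g = groups_for(cfg, Br=0.0)
        temp = solve_energy(flow, cfg.grid, cfg.fluid, g,
                            bc=default_thermal_bc(1.0))
        th = temp.theta[cfg.grid.open_]
        assert th.min() >= -1e-12
        assert th.max() <= 1.0 + 1e-12

    def test_dissipation_source_nonnegative(self, heated_tube):
        cfg, flow = heated_tube
        g = groups_for(cfg, Br=1.0)
        src = dissipation_source(flow, cfg.grid, g, cfg.fluid)
        assert src.min() >= 0.0

    def test_alpha_switch_disables_dissipation(self, heated_tube):
        cfg, flow = heated_tube
        g = groups_for(cfg, Br=1.0)
        props_off = FluidProperties(alpha=0.0)
        bc = {"inlet": ("dirichlet", 0.0), "outlet": ("neumann", 0.0),
              "wall": ("dirichlet", 0.0)}
        temp = solve_energy(flow, cfg.grid, props_off, g, bc=bc)
        assert np.abs(temp.theta).max() < 1e-12


class TestCouetteDissipation:
    def test_matches_closed_form_within_one_percent(self):
        err, theta, ref = couette_energy_error(n=(4, 32, 4), Br=1.0)
        assert err < 0.01

    def test_scales_linearly_with_brinkman_group(self):
        _, th1, _ = couette_energy_error(n=(4, 24, 4), Br=0.5)
        _, th2, _ = couette_energy_error(n=(4, 24, 4), Br=1.0)
        np.testing.assert_allclose(2.0 * th1, th2, rtol=1e-10)


class TestEnergyBalance:
    def test_wall_heat_matches_advected_enthalpy(self, heated_tube):
        cfg, flow = heated_tube
        g = groups_for(cfg, Pr=2.0, Br=0.0)
        temp = solve_energy(flow, cfg.grid, cfg.fluid, g,
                            bc=default_thermal_bc(1.0))
        bal = wall_heat_balance(flow, cfg.grid, temp)
        assert bal["advected_net"] == pytest.approx(bal["wall_in"], rel=0.01)


class TestPrandtlResponse:
    def test_wall_gradient_steepens_with_prandtl(self, heated_tube):
        # thermal boundary layer thins as Pr grows at fixed Re
        cfg, flow = heated_tube
        grid = cfg.grid
        grads = []
        for Pr in (0.7, 2.0, 5.0):
            g = groups_for(cfg, Pr=Pr, Br=0.0)
            temp = solve_energy(flow, grid, cfg.fluid, g,
                                bc=default_thermal_bc(1.0))
            i = int(0.5 * grid.shape[1])
            mi = int(grid.open_[:, i].sum())
            d = grid.geom.base_radius - grid.r_c[mi - 1]
            grads.append((1.0 - temp.theta[mi - 1, i]) / d)
        assert grads[0] < grads[1] < grads[2]

    def test_dissipation_heats_interior_with_br(self, heated_tube):
        cfg, flow = heated_tube
        grid = cfg.grid
        bc = {"inlet": ("dirichlet", 0.0), "outlet": ("neumann", 0.0),
              "wall": ("dirichlet", 0.0)}
        peaks = []
        for Br in (0.1, 0.5, 1.0, 2.0):
            g = groups_for(cfg, Pr=2.0, Br=Br)
            temp = solve_energy(flow, grid, cfg.fluid, g, bc=bc)
            peaks.append(float(temp.theta.max()))
        assert np.all(np.diff(peaks) > 0)
        assert peaks[0] > 0
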