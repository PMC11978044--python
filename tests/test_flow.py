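import copy

import numpy as np
import pytest

from stenoflow import (FluidProperties, SolverSettings,
                       apply_boundary_conditions, make_case, simple_iterate,
                       solve_steady)
from stenoflow.flow import make_field
from stenoflow.oracles import poiseuille_pressure_drop
from stenoflow.postprocess import extract_line, pressure_drop
from stenoflow import _axisym as ax


class TestBoundaryConditions:
    def test_wall_and_solid_faces_zero(self, stenosed_s60):
        cfg, flow, _ = stenosed_s60
        grid = cfg.grid
        apply_boundary_conditions(flow, grid)
        w = ax._work(grid)
        assert np.all(flow.u[:, 1:-1][~w.act_u[:, 1:-1]] == 0.0)
        assert np.all(flow.v[~w.act_v] == 0.0)

    def test_inlet_discrete_mean_equals_U(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        grid = cfg.grid
        A = grid.axial_face_area()
        mean = (flow.u[:, 0] * A).sum() / A.sum()
        assert mean == pytest.approx(cfg.inlet_speed, rel=1e-12)

    def test_shape_mismatch_rejected(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        other = make_case("healthy", resolution=(8, 32)).build_grid()
        with pytest.raises(ValueError):
            apply_boundary_conditions(flow, other)

    def test_axis_symmetry_zero_radial_velocity(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        assert np.all(flow.v[0, :] == 0.0)


class TestSimpleIterate:
    def test_residual_below_tolerance_from_converged_state(
            self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        fld = copy.deepcopy(flow)
        _, res = simple_iterate(fld, cfg.grid, cfg.fluid, cfg.solver)
        assert res["momentum"] <= cfg.solver.tol_momentum
        assert res["continuity"] <= cfg.solver.tol_continuity

    def test_zero_relaxation_limit_leaves_velocity_unchanged(self):
        # the momentum update must vanish with the under-relaxation factor,
        # even far from convergence
        cfg = make_case("s40", resolution=(16, 48))
        grid = cfg.build_grid()
        st = copy.deepcopy(cfg.solver)
        st.relax_u = 1e-12
        fld = make_field(grid, cfg.fluid, cfg.inlet_speed, st)
        w = ax._work(grid)
        mu_x = ax.corner_mu(fld.mu, w.open, cfg.fluid.mu0)
        u0, v0 = fld.u.copy(), fld.v.copy()
        ax.solve_u_momentum(fld, grid, cfg.fluid, st, mu_x)
        ax.solve_v_momentum(fld, grid, cfg.fluid, st, mu_x)
        np.testing.assert_allclose(fld.u, u0, atol=1e-9 * abs(u0).max())
        np.testing.assert_allclose(fld.v, v0, atol=1e-9 * abs(u0).max())

    def test_pressure_correction_annihilates_divergence(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        grid = cfg.grid
        fld = copy.deepcopy(flow)
        rng = np.random.default_rng(42)
        w = ax._work(grid)
        fld.u[w.act_u] += 0.1 * cfg.inlet_speed * rng.normal(
            size=int(w.act_u.sum()))
        fld.v[w.act_v] += 0.1 * cfg.inlet_speed * rng.normal(
            size=int(w.act_v.sum()))
        ax.apply_bcs(fld, grid, fld.inlet_speed)
        pre = np.abs(ax.divergence(fld, grid)).max()
        assert pre > 0
        _, res = simple_iterate(fld, grid, cfg.fluid, cfg.solver)
        post = np.abs(ax.divergence(fld, grid)).max()
        assert post <= pre
        assert post < 1e-12 * fld.flow_rate(0)


class TestSolveSteady:
    def test_poiseuille_centerline_and_pressure_drop(self, newtonian_tube):
        cfg, flow, hist = newtonian_tube
        assert hist.converged
        U = cfg.inlet_speed
        prof = extract_line(flow.axial_velocity(), cfg.grid, "centerline")
        assert prof.values[len(prof.values) // 2] == pytest.approx(
            2 * U, rel=0.01)
        dp_ref = poiseuille_pressure_drop(
            cfg.fluid.mu0, cfg.geometry.segment_length, U,
            cfg.geometry.base_radius)
        assert pressure_drop(flow, cfg.grid)["dp"] == pytest.approx(
            dp_ref, rel=0.01)

    def test_flow_rate_identical_through_every_section(self, stenosed_s60):
        cfg, flow, _ = stenosed_s60
        Q0 = flow.flow_rate(0)
        for i in range(cfg.grid.shape[1] + 1):
            assert flow.flow_rate(i) == pytest.approx(Q0, rel=1e-6)

    def test_throat_speedup_follows_area_ratio(self, stenosed_s60):
        cfg, flow, _ = stenosed_s60
        grid = cfg.grid
        i_th = int(np.argmin(grid.local_radius(grid.z_c)))
        A_in = grid.open_section_area(0)
        A_th = grid.open_section_area(i_th)
        uc = flow.u[:, i_th]  # face just left of throat center; use section
        Q = flow.flow_rate(i_th)
        mean_throat = Q / (2 * np.pi * A_th)
        mean_in = flow.flow_rate(0) / (2 * np.pi * A_in)
        assert mean_throat == pytest.approx(mean_in * A_in / A_th, rel=1e-9)

    def test_williamson_profile_flatter_than_parabola(self, stenosed_s60):
        cfg, _, _ = stenosed_s60
        healthy = make_case("healthy", resolution=(24, 96))
        flow, hist = solve_steady(healthy)
        assert hist.converged
        prof = extract_line(flow.axial_velocity(), healthy.grid,
                            "radial-at-z", z=0.8 * 20e-3)
        mean = healthy.inlet_speed
        assert prof.values.max() / mean < 2.0

    def test_nonconvergence_is_flagged_not_raised(self):
        cfg = make_case("s80", resolution=(16, 48))
        cfg.solver = SolverSettings(max_outer=2)
        flow, hist = solve_steady(cfg)
        assert hist.converged is False
        assert hist.iterations == 2

    def test_deterministic_rerun_bitwise(self):
        cfg1 = make_case("healthy", resolution=(12, 48))
        f1, h1 = solve_steady(cfg1)
        cfg2 = make_case("healthy", resolution=(12, 48))
        f2, h2 = solve_steady(cfg2)
        assert np.array_equal(f1.u, f2.u)
        assert np.array_equal(f1.p, f2.p)
        assert h1.iterations == h2.iterations

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SolverSettings(relax_u=0.0)
        with pytest.raises(ValueError):
            SolverSettings(advection="quick")
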