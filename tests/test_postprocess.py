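import numpy as np
import pytest

from stenoflow import FluidProperties, make_case
from stenoflow.flow import FlowField
from stenoflow.postprocess import (LineProfile, derived_fields, extract_line,
                                   pathlines, pressure_drop, stream_function,
                                   write_profile_csv)


def uniform_flow_field(cfg, speed_xy=(3.0, 4.0)):
    """A hand-built axisym field with |u| = 5 everywhere (u=3 axial... we use
    axial=3, radial=4 on interior faces to make the cell speed 5)."""
    grid = cfg.build_grid()
    nr, nz = grid.shape
    u = np.full((nr, nz + 1), speed_xy[0])
    v = np.full((nr + 1, nz), speed_xy[1])
    p = np.zeros((nr, nz))
    mu = np.full((nr, nz), cfg.fluid.mu0)
    return FlowField(grid=grid, inlet_speed=1.0, u=u, v=v, p=p, mu=mu)


class TestDerivedFields:
    def test_dynamic_pressure_arithmetic(self):
        cfg = make_case("healthy", resolution=(8, 32),
                        fluid=FluidProperties(density=2.0))
        flow = uniform_flow_field(cfg)
        der = derived_fields(flow, cfg.fluid, U_ref=1.0, p_ref=0.0)
        # |u| = 5, rho = 2 -> p_dyn = 25
        assert der["dynamic_pressure"][2, 5] == pytest.approx(25.0)

    def test_cp_zero_when_pressure_equals_reference(self):
        cfg = make_case("healthy", resolution=(8, 32))
        flow = uniform_flow_field(cfg)
        flow.p[:] = 7.5
        der = derived_fields(flow, cfg.fluid, U_ref=1.0, p_ref=7.5)
        assert np.allclose(der["pressure_coefficient"], 0.0)

    def test_cp_vanishes_at_outlet_reference_by_default(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        der = derived_fields(flow, cfg.fluid)
        cp_out = der["pressure_coefficient"][:, -1]
        assert abs(cp_out.mean()) < 0.05 * np.abs(
            der["pressure_coefficient"]).max()

    def test_cp_linear_along_centerline_for_poiseuille(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        der = derived_fields(flow, cfg.fluid)
        prof = extract_line(der["pressure_coefficient"], cfg.grid,
                            "centerline")
        z, cp = prof.coords, prof.values
        coeffs = np.polyfit(z, cp, 1)
        resid = cp - np.polyval(coeffs, z)
        assert np.abs(resid).max() < 0.02 * (cp.max() - cp.min())

    def test_positivity_invariants(self, stenosed_s60):
        cfg, flow, _ = stenosed_s60
        der = derived_fields(flow, cfg.fluid)
        assert der["dynamic_pressure"].min() >= 0.0
        assert der["cell_reynolds"].min() >= 0.0

    def test_bad_reference_speed_rejected(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        with pytest.raises(ValueError):
            derived_fields(flow, cfg.fluid, U_ref=0.0)


class TestStreamFunction:
    def test_axis_value_zero_and_wall_value_flux(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        psi = stream_function(flow, cfg.grid)
        assert np.allclose(psi[0, :], 0.0)
        Q = flow.flow_rate(0)
        np.testing.assert_allclose(psi[-1, :], Q / (2 * np.pi), rtol=1e-9)

    def test_poiseuille_contours_parallel_to_wall(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        psi = stream_function(flow, cfg.grid)
        # fully developed: psi rows constant along z away from boundaries
        interior = psi[1:-1, 2:-2]
        var = np.ptp(interior, axis=1) / psi[-1, 0]
        assert var.max() < 5e-3

    def test_analytic_shape(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        grid = cfg.grid
        psi = stream_function(flow, grid)
        R, U = cfg.geometry.base_radius, cfg.inlet_speed
        r = grid.r_f
        ref = U * (r**2 - r**4 / (2 * R**2))  # analytic Stokes psi
        np.testing.assert_allclose(psi[:, grid.shape[1] // 2], ref,
                                   atol=0.01 * ref.max())

    def test_3d_mode_rejected_with_pathline_companion(self):
        cfg = make_case("healthy", mode="cart3d", resolution=(8, 8, 16))
        flow = FlowField(grid=cfg.build_grid(), inlet_speed=1.0,
                        u=np.zeros((9, 8, 16)), v=np.zeros((8, 9, 16)),
                        w=np.ones((8, 8, 17)), p=np.zeros((8, 8, 16)),
                        mu=np.ones((8, 8, 16)))
        with pytest.raises(ValueError):
            stream_function(flow, cfg.grid)
        lines = pathlines(flow, [(0.0, 0.0, 1e-3)], n_steps=20)
        assert len(lines) == 1 and len(lines[0]) > 1
        assert np.all(np.diff(lines[0][:, 2]) > 0)  # advected downstream


class TestExtractLine:
    def test_centerline_constant_2U(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        prof = extract_line(flow.axial_velocity(), cfg.grid, "centerline")
        mid = prof.values[len(prof.values) // 3:]
        assert np.allclose(mid, 2 * cfg.inlet_speed, rtol=0.01)

    def test_radial_profile_vanishes_at_wall(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        prof = extract_line(flow.axial_velocity(), cfg.grid, "radial-at-z",
                            z=0.5 * cfg.geometry.segment_length)
        assert prof.values[-1] < 0.2 * prof.values[0]

    def test_repeat_extraction_bitwise_identical(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        p1 = extract_line(flow.speed(), cfg.grid, "centerline")
        p2 = extract_line(flow.speed(), cfg.grid, "centerline")
        assert np.array_equal(p1.values, p2.values)
        assert np.array_equal(p1.coords, p2.coords)

    def test_line_outside_domain_rejected(self, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        with pytest.raises(ValueError):
            extract_line(flow.speed(), cfg.grid, "radial-at-z", z=1.0)
        with pytest.raises(ValueError):
            extract_line(flow.speed(), cfg.grid, "axial-at-r", r=1.0)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            LineProfile(np.array([0.0, 1.0]), np.array([1.0]), "q", "-", "c")
        with pytest.raises(ValueError):
            LineProfile(np.array([1.0, 0.0]), np.array([1.0, 2.0]),
                        "q", "-", "c")

    def test_csv_roundtrip(self, tmp_path, newtonian_tube):
        cfg, flow, _ = newtonian_tube
        prof = extract_line(flow.speed(), cfg.grid, "centerline",
                            quantity="velocity_magnitude", units="m/s")
        path = tmp_path / "prof.csv"
        write_profile_csv(prof, path)
        data = np.genfromtxt(path, delimiter=",", skip_header=1,
                             usecols=(0, 1))
        np.testing.assert_allclose(data[:, 0], prof.coords)
        np.testing.assert_allclose(data[:, 1], prof.values)


class TestPressureDrop:
    def test_zero_velocity_zero_drop(self):
        cfg = make_case("healthy", resolution=(8, 32))
        flow = uniform_flow_field(cfg, (0.0, 0.0))
        assert pressure_drop(flow, cfg.grid)["dp"] == 0.0

    def test_post_minus_pre_sections_reported(self, stenosed_s60):
        cfg, flow, _ = stenosed_s60
        pd = pressure_drop(flow, cfg.grid)
        assert pd["pre_stenotic_mean"] > pd["post_stenotic_mean"]
        assert pd["dp"] > 0


class TestPanelPlot:
    def test_writes_figure_for_axisym_case(self, tmp_path, stenosed_s60):
        from stenoflow.postprocess import plot_case_panels
        cfg, flow, _ = stenosed_s60
        out = tmp_path / "panels.png"
        fig = plot_case_panels(flow, cfg.grid, cfg.fluid, path=out)
        assert out.exists() and out.stat().st_size > 0
        import matplotlib.pyplot as plt
        plt.close(fig)

    def test_rejects_cart3d(self):
        from stenoflow import make_case
        from stenoflow.flow import make_field
        from stenoflow.postprocess import plot_case_panels
        import pytest
        cfg = make_case("healthy", mode="cart3d", resolution=(8, 8, 16))
        grid = cfg.build_grid()
        fld = make_field(grid, cfg.fluid, cfg.inlet_speed, cfg.solver)
        with pytest.raises(ValueError):
            plot_case_panels(fld, grid, cfg.fluid)
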