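import copy
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoflow import (FluidProperties, dimensionless_groups, load_config,
                       make_case, run_case, run_sweep, save_config)
from stenoflow.cases import CANONICAL_DEGREES, PROFILE_QUANTITIES, _set_path
from stenoflow.groups import DimensionlessGroups


class TestDimensionlessGroups:
    def test_reynolds_arithmetic(self):
        p = FluidProperties(density=1000.0, mu0=0.001, mu_inf=0.001, lam=0.0)
        g = dimensionless_groups(p, u0=0.01, L=0.01, Ti=300.0, Tb=310.0)
        assert g.Re == pytest.approx(100.0)

    def test_prandtl_arithmetic(self):
        p = FluidProperties(conductivity=0.52, specific_heat=3617.0,
                            mu0=0.00345, mu_inf=0.00345, lam=0.0)
        g = dimensionless_groups(p, 0.01, 0.01, 300.0, 310.0)
        assert g.Pr == pytest.approx(24.0, abs=0.05)

    def test_brinkman_group_quadratic_in_u0(self):
        p = FluidProperties()
        g1 = dimensionless_groups(p, 0.01, 0.01, 300.0, 310.0)
        g2 = dimensionless_groups(p, 0.02, 0.01, 300.0, 310.0)
        assert g2.Br == pytest.approx(4.0 * g1.Br)
        g0 = dimensionless_groups(p, 1e-9, 0.01, 300.0, 310.0)
        assert g0.Br == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(u0=st.floats(1e-4, 1.0), L=st.floats(1e-4, 1.0))
    def test_re_pr_identity(self, u0, L):
        p = FluidProperties()
        g = dimensionless_groups(p, u0, L, 300.0, 310.0)
        assert g.Re * g.Pr == pytest.approx(u0 * L / g.beta, rel=1e-12)

    def test_degenerate_temperature_scale_rejected(self):
        with pytest.raises(ValueError):
            dimensionless_groups(FluidProperties(), 0.01, 0.01, 310.0, 310.0)


class TestMakeCase:
    @pytest.mark.parametrize("name,degree", sorted(CANONICAL_DEGREES.items()))
    def test_canonical_degrees(self, name, degree):
        cfg = make_case(name)
        got = cfg.geometry.stenosis.degree if cfg.geometry.stenosis else 0.0
        assert got == degree

    def test_unknown_case_lists_options(self):
        with pytest.raises(ValueError, match="healthy.*s40.*s60.*s80"):
            make_case("s90")

    def test_overrides(self):
        cfg = make_case("s40", ellipse_ratio=0.5, inlet_speed=0.05)
        assert cfg.geometry.ellipse_ratio == 0.5
        assert cfg.inlet_speed == 0.05


@pytest.fixture(scope="module")
def manifest(tmp_path_factory):
    cfg = make_case("healthy", resolution=(12, 48))
    cfg.outdir = str(tmp_path_factory.mktemp("run"))
    return cfg, run_case(cfg)


class TestRunCase:
    def test_manifest_file_inventory(self, manifest):
        cfg, man = manifest
        files = man["files"]
        assert sum(f.endswith(".vtk") for f in files) == 1
        assert sum(f.endswith(".csv") for f in files) == len(
            PROFILE_QUANTITIES) + 1  # 7 profiles + convergence log
        assert sum(f.endswith("_summary.json") for f in files) == 1
        assert sum(f.endswith(".yaml") for f in files) == 1

    def test_summary_contents(self, manifest):
        cfg, man = manifest
        s = man["summary"]
        assert s["converged"] is True
        assert s["dp_Pa"] > 0
        assert s["peak_velocity_m_per_s"] > cfg.inlet_speed

    def test_rerun_is_bitwise_identical(self, manifest, tmp_path):
        cfg, man = manifest
        cfg2 = copy.deepcopy(cfg)
        cfg2.grid = None
        cfg2.outdir = str(tmp_path)
        man2 = run_case(cfg2)
        assert np.array_equal(man["flow"].u, man2["flow"].u)
        assert np.array_equal(man["flow"].p, man2["flow"].p)
        a = json.dumps(man["summary"])
        b = json.dumps(man2["summary"])
        assert a == b

    def test_unconverged_case_flagged(self, tmp_path):
        cfg = make_case("s80", resolution=(16, 48))
        cfg.solver.max_outer = 1
        cfg.outdir = str(tmp_path)
        man = run_case(cfg)
        assert man["converged"] is False
        assert any(f.endswith(".vtk") for f in man["files"])


class TestConfigRoundTrip:
    def test_yaml_roundtrip_preserves_case(self, tmp_path):
        cfg = make_case("s60", ellipse_ratio=0.8, inlet_speed=0.03)
        path = tmp_path / "case.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert back.geometry.stenosis.degree == 0.6
        assert back.geometry.ellipse_ratio == 0.8
        assert back.inlet_speed == 0.03
        assert back.solver.relax_u == cfg.solver.relax_u

    def test_roundtrip_reruns_identically(self, tmp_path):
        cfg = make_case("healthy", resolution=(10, 40))
        path = tmp_path / "case.yaml"
        save_config(cfg, path)
        back = load_config(path)
        m1 = run_case(cfg, write_outputs=False)
        m2 = run_case(back, write_outputs=False)
        assert np.array_equal(m1["flow"].u, m2["flow"].u)


class TestSweeps:
    def test_parameter_path_resolution(self):
        cfg = make_case("healthy")
        _set_path(cfg, "groups.Pr", 5.0)
        assert cfg.groups.Pr == 5.0
        _set_path(cfg, "degree", 0.4)
        assert cfg.geometry.stenosis.degree == 0.4
        with pytest.raises(ValueError):
            _set_path(cfg, "no.such.path", 1)

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            run_sweep(make_case("healthy"), "groups.Pr", [])

    def test_pr_sweep_profiles_aligned(self):
        base = make_case("healthy", resolution=(12, 48))
        res = run_sweep(base, "groups.Pr", [0.7, 2.0])
        p0, p1 = res["profiles"]
        assert np.array_equal(p0.coords, p1.coords)

    def test_degree_sweep_monotone_pressure_drop(self):
        base = make_case("healthy", resolution=(16, 64))
        res = run_sweep(base, "degree", [0.0, 0.4, 0.6])
        dps = [s["dp_Pa"] for s in res["summaries"]]
        assert dps[0] < dps[1] < dps[2]
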