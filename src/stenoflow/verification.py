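"""Verification battery: oracle checks and the grid-independence procedure.

Every check compares the finite-volume solution against an independent
analytic or quadrature oracle from :mod:`stenoflow.oracles`:

* Hagen-Poiseuille centerline velocity and pressure drop (Newtonian pipe);
* fully developed Williamson pipe profile vs the 1D tau-gamma_dot
  root-finding + quadrature solution;
* elliptic-duct Poiseuille (3D masked-cell solver, Newtonian);
* plane Couette flow with viscous dissipation (energy solver);
* exact discrete mass conservation on a stenosed case;
* monotone error reduction under grid refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Union

import numpy as np

from . import oracles
from .cases import CaseConfig, make_case
from .energy import solve_energy
from .flow import SolverSettings, solve_steady
from .geometry import LumenGeometry
from .grid import Grid, build_grid
from .groups import DimensionlessGroups
from .postprocess import extract_line, pressure_drop
from .rheology import FluidProperties

__all__ = ["grid_independence", "validate_suite", "couette_energy_error",
           "elliptic_duct_error", "williamson_profile_error"]


# ------------------------------------------------------------------ #
# named quantities of interest

def qoi_peak_axial_velocity(flow, grid) -> float:
    prof = extract_line(flow.speed(), grid, "centerline")
    return float(prof.values.max())


def qoi_pressure_drop(flow, grid) -> float:
    return pressure_drop(flow, grid)["dp"]


_QOIS = {
    "peak_axial_velocity": qoi_peak_axial_velocity,
    "pressure_drop": qoi_pressure_drop,
}


def grid_independence(case: CaseConfig,
                      resolutions: Sequence,
                      qoi: Union[str, Callable] = "peak_axial_velocity",
                      threshold: float = 0.01) -> Dict:
    """Re-solve ``case`` on an increasing resolution ladder and report the
    quantity of interest with successive relative changes.

    Mirrors the study's mesh-independence procedure: the case counts as
    grid-independent at the first resolution whose relative change from the
    previous one falls below ``threshold`` (default 1%).  A non-convergent
    solve is recorded as a failed row, not raised.
    """
    if len(resolutions) < 3:
        raise ValueError("need at least 3 resolutions")
    fn = _QOIS[qoi] if isinstance(qoi, str) else qoi
    rows: List[Dict] = []
    prev = None
    converged_at = None
    import copy

    for res in resolutions:
        cfg = copy.deepcopy(case)
        cfg.resolution = tuple(res) if np.iterable(res) else res
        cfg.grid = None
        try:
            flow, hist = solve_steady(cfg)
            ok = hist.converged
            val = fn(flow, cfg.grid) if ok else None
        except Exception as exc:  # recorded, not raised
            ok, val = False, None
        row = {"resolution": res, "qoi": val, "solver_converged": ok,
               "rel_change": None}
        if ok and prev is not None:
            row["rel_change"] = abs(val - prev) / max(abs(prev), 1e-300)
            if converged_at is None and row["rel_change"] < threshold:
                converged_at = res
        if ok:
            prev = val
        rows.append(row)
    return {"rows": rows, "converged_at": converged_at,
            "threshold": threshold, "qoi": qoi if isinstance(qoi, str)
            else getattr(qoi, "__name__", "custom")}


# ------------------------------------------------------------------ #
# individual oracle errors

def poiseuille_errors(resolution=(32, 128), U=0.02, R0=2e-3, L=20e-3,
                      mu=0.00345, settings: SolverSettings = None):
    """(centerline error, pressure-drop error) vs Hagen-Poiseuille,
    as relative magnitudes."""
    props = FluidProperties.newtonian(mu)
    cfg = make_case("healthy", base_radius=R0, segment_length=L,
                    inlet_speed=U, fluid=props, resolution=resolution)
    if settings is not None:
        cfg.solver = settings
    flow, hist = solve_steady(cfg)
    grid = cfg.grid
    prof = extract_line(flow.axial_velocity(), grid, "centerline")
    mid = prof.values[len(prof.values) // 2]
    err_u = abs(mid - 2.0 * U) / (2.0 * U)
    dp = pressure_drop(flow, grid)["dp"]
    dp_ref = oracles.poiseuille_pressure_drop(mu, L, U, R0)
    err_dp = abs(dp - dp_ref) / dp_ref
    return err_u, err_dp, flow, hist


def williamson_profile_error(resolution=(48, 160), U=0.02, R0=2e-3,
                             L=None, props: FluidProperties = None,
                             station: float = 0.8):
    """Max relative deviation (scaled by 2U) of the computed fully developed
    Williamson profile from the 1D quadrature oracle, at z = station*L."""
    props = props or FluidProperties()
    L = L if L is not None else 10.0 * R0
    cfg = make_case("healthy", base_radius=R0, segment_length=L,
                    inlet_speed=U, fluid=props, resolution=resolution)
    flow, hist = solve_steady(cfg)
    grid = cfg.grid
    prof = extract_line(flow.axial_velocity(), grid, "radial-at-z",
                        z=station * L)
    sol = oracles.williamson_pipe_flow(U, R0, props)
    ref = np.interp(prof.coords, sol.r, sol.u)
    err = float(np.max(np.abs(prof.values - ref)) / (2.0 * U))
    return err, flow, hist, sol


def elliptic_duct_error(resolution=(32, 32, 64), U=0.02, R0=2e-3,
                        kappa=0.5, L=None, mu=0.00345,
                        settings: SolverSettings = None):
    """L_inf error (relative to the analytic peak) of the Newtonian
    masked-cell solution in a straight elliptic duct, measured over the
    developed half of the duct."""
    L = L if L is not None else 8.0 * R0
    props = FluidProperties.newtonian(mu)
    cfg = make_case("healthy", base_radius=R0, segment_length=L,
                    inlet_speed=U, fluid=props, ellipse_ratio=kappa,
                    mode="cart3d", resolution=resolution)
    # diffusion-dominated duct: stronger pressure relaxation converges fast
    cfg.solver = settings if settings is not None \
        else SolverSettings(relax_p=0.5)
    flow, hist = solve_steady(cfg)
    grid = cfg.grid
    a, b = grid.section_semi_axes(0.0)
    xc = grid.centers["x"][:, None, None]
    yc = grid.centers["y"][None, :, None]
    ref = oracles.elliptic_poiseuille_velocity(xc, yc, a, b, U)
    ref = np.broadcast_to(ref, grid.shape)
    wc = flow.axial_velocity()
    nz = grid.shape[2]
    sl = slice(nz // 2, nz - max(2, nz // 16))
    mask = grid.open_[:, :, sl]
    err = np.abs(wc[:, :, sl] - ref[:, :, sl])[mask].max() / (2.0 * U)
    return float(err), flow, hist


def couette_energy_error(n=(6, 48, 6), Br=1.0, Pr=2.0, Re=10.0):
    """Relative mid-gap error of the energy solver against the closed-form
    Couette-with-dissipation profile theta = Br*eta*(1-eta)/2.

    The linear-shear velocity field is imposed analytically on a plane
    channel (walls normal to y, both at theta = 0), so the check isolates
    the scalar transport + dissipation discretization.
    """
    from .flow import FlowField

    H = 1.0e-3          # gap [m]
    U0 = 0.01           # wall speed scale [m/s]
    nx, ny, nz = n
    Lx, Lz = H, H
    x_f = np.linspace(0.0, Lx, nx + 1)
    y_f = np.linspace(0.0, H, ny + 1)
    z_f = np.linspace(0.0, Lz, nz + 1)
    geom = LumenGeometry(base_radius=H, segment_length=Lz)
    grid = Grid(
        mode="cart3d", geom=geom,
        faces={"x": x_f, "y": y_f, "z": z_f},
        centers={"x": 0.5 * (x_f[:-1] + x_f[1:]),
                 "y": 0.5 * (y_f[:-1] + y_f[1:]),
                 "z": 0.5 * (z_f[:-1] + z_f[1:])},
        spacings={"x": float(np.diff(x_f)[0]), "y": float(np.diff(y_f)[0]),
                  "z": np.diff(z_f)},
        open_=np.ones((nx, ny, nz), bool),
    )
    y_c = grid.centers["y"]
    u = np.zeros((nx + 1, ny, nz))
    u[...] = (U0 * y_c / H)[None, :, None]
    v = np.zeros((nx, ny + 1, nz))
    w = np.zeros((nx, ny, nz + 1))
    p = np.zeros((nx, ny, nz))
    mu = np.ones((nx, ny, nz))
    flow = FlowField(grid=grid, inlet_speed=U0, u=u, v=v, w=w, p=p, mu=mu)
    groups = DimensionlessGroups(Re=Re, Pr=Pr, Br=Br, beta=U0 * H / (Re * Pr),
                                 u0=U0, L=H)
    props = FluidProperties()
    bc = {"inlet": ("neumann", 0.0), "outlet": ("neumann", 0.0),
          "wall_x": ("neumann", 0.0), "wall_y": ("dirichlet", 0.0),
          "wall_z": ("neumann", 0.0)}
    temp = solve_energy(flow, grid, props, groups, bc=bc)
    theta = temp.theta[nx // 2, :, nz // 2]
    ref = oracles.couette_dissipation_theta(y_c / H, Br)
    err = float(np.max(np.abs(theta - ref)) / (Br / 8.0))
    return err, theta, ref


def mass_conservation_errors(cfg: CaseConfig):
    """(max cross-section flow-rate error, global imbalance), relative."""
    flow, hist = solve_steady(cfg)
    grid = cfg.grid
    nfaces = grid.shape[-1] + 1
    Q0 = flow.flow_rate(0)
    errs = [abs(flow.flow_rate(i) - Q0) / abs(Q0) for i in range(nfaces)]
    global_err = abs(flow.flow_rate(nfaces - 1) - Q0) / abs(Q0)
    return max(errs), global_err, flow, hist


# ------------------------------------------------------------------ #

def validate_suite(tier: str = "quick",
                   tolerance_scale: float = 1.0) -> List[Dict]:
    """Run the oracle battery and report each error against its tolerance.

    tier "quick" uses coarse resolutions (~1 min total); "full" uses the
    verification resolutions of the study plan.  ``tolerance_scale``
    multiplies every tolerance (0 makes every finite-error check fail, a
    contract probe).  Failures are report entries, never exceptions.
    """
    if tier not in ("quick", "full"):
        raise ValueError("tier must be 'quick' or 'full'")
    full = tier == "full"
    report: List[Dict] = []

    def add(name, value, tol):
        tol = tol * tolerance_scale
        report.append({"check": name, "value": float(value),
                       "tolerance": float(tol),
                       "passed": bool(value <= tol)})

    try:
        err_u, err_dp, _, hist = poiseuille_errors(
            resolution=(64, 256) if full else (24, 96))
        add("poiseuille_centerline_rel_err", err_u, 0.01)
        add("poiseuille_pressure_drop_rel_err", err_dp, 0.01)
    except Exception as exc:
        report.append({"check": "poiseuille", "error": str(exc),
                       "passed": False})

    try:
        err_w, _, _, _ = williamson_profile_error(
            resolution=(64, 256) if full else (32, 96))
        add("williamson_profile_rel_err", err_w, 0.02)
    except Exception as exc:
        report.append({"check": "williamson", "error": str(exc),
                       "passed": False})

    try:
        err_e, _, _ = elliptic_duct_error(
            resolution=(48, 48, 96) if full else (20, 20, 40))
        add("elliptic_duct_linf_err", err_e, 0.05)
    except Exception as exc:
        report.append({"check": "elliptic_duct", "error": str(exc),
                       "passed": False})

    try:
        err_c, _, _ = couette_energy_error(n=(6, 64, 6) if full else (4, 32, 4))
        add("couette_dissipation_rel_err", err_c, 0.01)
    except Exception as exc:
        report.append({"check": "couette", "error": str(exc),
                       "passed": False})

    try:
        cfg = make_case("s60", resolution=(48, 192) if full else (24, 96))
        errq, errg, _, _ = mass_conservation_errors(cfg)
        add("cross_section_flow_rate_rel_err", errq, 1e-6)
        add("global_mass_imbalance_rel_err", errg, 1e-8)
    except Exception as exc:
        report.append({"check": "mass_conservation", "error": str(exc),
                       "passed": False})

    try:
        cfg = make_case("healthy", fluid=FluidProperties.newtonian(0.00345))
        ladder = [(8, 32), (16, 64), (32, 128), (64, 256)] if full else \
            [(8, 32), (16, 64), (32, 128)]
        rep = grid_independence(cfg, ladder, "peak_axial_velocity")
        changes = [r["rel_change"] for r in rep["rows"]
                   if r["rel_change"] is not None]
        add("grid_independence_final_change", changes[-1], 0.01)
    except Exception as exc:
        report.append({"check": "grid_independence", "error": str(exc),
                       "passed": False})

    return report
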