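"""Study orchestration: canonical cases, runs, sweeps.

The four canonical lumen configurations of the study are a healthy segment
and 40/60/80% diameter reductions of the center section.  The paper prints
no dimensional values for the vessel or the fluid, so the defaults below
are clearly-labeled fixtures: a small artery (R0 = 2 mm, L = 20 mm,
stenosis length L/5 centered at L/2), blood-like Williamson parameters and
an inlet mean speed of 2 cm/s.  Every output is parameter-stamped through
the resolved-config echo.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field as dfield, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .energy import default_thermal_bc, solve_energy
from .flow import FlowField, SolverSettings, solve_steady
from .geometry import LumenGeometry, StenosisSpec
from .grid import Grid, build_grid
from .groups import DimensionlessGroups, dimensionless_groups
from .postprocess import (derived_fields, extract_line, pressure_drop,
                          write_profile_csv)
from .rheology import FluidProperties
from .vtkio import write_vtk

__all__ = [
    "CaseConfig",
    "CANONICAL_DEGREES",
    "make_case",
    "run_case",
    "run_sweep",
]

CANONICAL_DEGREES = {"healthy": 0.0, "s40": 0.4, "s60": 0.6, "s80": 0.8}

# fixture defaults (the study prints no dimensional values)
DEFAULT_R0 = 2.0e-3       # m
DEFAULT_L = 20.0e-3       # m
DEFAULT_U = 0.02          # m/s inlet mean speed
DEFAULT_TI = 310.0        # K
DEFAULT_TB = 313.0        # K


@dataclass
class CaseConfig:
    """A fully-specified runnable study case.

    Either ``groups`` is given explicitly (dimensionless-first) or it is
    resolved from the fluid properties and the scales (u0 = inlet_speed,
    L = segment length, Ti, Tb); exactly one source is authoritative and
    :meth:`resolved_groups` settles it before solving.
    """

    name: str = "healthy"
    geometry: LumenGeometry = dfield(
        default_factory=lambda: LumenGeometry(DEFAULT_R0, DEFAULT_L))
    fluid: FluidProperties = dfield(default_factory=FluidProperties)
    inlet_speed: float = DEFAULT_U
    Ti: float = DEFAULT_TI
    Tb: float = DEFAULT_TB
    groups: Optional[DimensionlessGroups] = None
    solver: SolverSettings = dfield(default_factory=SolverSettings)
    mode: str = "axisym"
    resolution: Tuple[int, ...] = (32, 128)
    clustering: float = 1.0
    theta_wall: float = 1.0
    dissipation_form: str = "standard"
    outdir: str = "out"
    grid: Optional[Grid] = None

    def build_grid(self) -> Grid:
        if self.grid is None:
            self.grid = build_grid(self.geometry, self.resolution,
                                   mode=self.mode, clustering=self.clustering)
        return self.grid

    def resolved_groups(self) -> DimensionlessGroups:
        if self.groups is not None:
            return self.groups
        return dimensionless_groups(
            self.fluid, self.inlet_speed, self.geometry.segment_length,
            self.Ti, self.Tb)


def make_case(name: str, **overrides) -> CaseConfig:
    """One of the four canonical cases: healthy, s40, s60, s80.

    Keyword overrides replace any CaseConfig field; geometry sub-fields
    ``degree``, ``ellipse_ratio``, ``base_radius``, ``segment_length`` are
    also accepted directly.
    """
    if name not in CANONICAL_DEGREES:
        raise ValueError(
            f"unknown case {name!r}; valid cases: "
            + ", ".join(sorted(CANONICAL_DEGREES)))
    degree = overrides.pop("degree", CANONICAL_DEGREES[name])
    R0 = overrides.pop("base_radius", DEFAULT_R0)
    L = overrides.pop("segment_length", DEFAULT_L)
    kappa = overrides.pop("ellipse_ratio", 1.0)
    sten = None
    if degree > 0:
        sten = StenosisSpec(degree=degree, length=L / 5.0, center=L / 2.0)
    geom = LumenGeometry(base_radius=R0, segment_length=L,
                         ellipse_ratio=kappa, stenosis=sten)
    cfg = CaseConfig(name=name, geometry=geom, **overrides)
    if degree > 0 and cfg.clustering == 1.0 and cfg.mode == "axisym":
        cfg.clustering = 2.0
    return cfg


PROFILE_QUANTITIES = (
    "velocity_magnitude", "radial_velocity", "static_pressure",
    "dynamic_pressure", "pressure_coefficient", "cell_reynolds",
    "temperature",
)


def _case_profiles(cfg, grid, flow, temp) -> Dict[str, object]:
    der = derived_fields(flow, cfg.fluid)
    speed = flow.speed()
    if grid.mode == "axisym":
        radial = 0.5 * (flow.v[:-1, :] + flow.v[1:, :])
    else:
        radial = 0.5 * (flow.u[:-1] + flow.u[1:])  # transverse (x) component
    profs = {
        "velocity_magnitude": extract_line(
            speed, grid, "centerline", quantity="velocity_magnitude",
            units="m/s"),
        "radial_velocity": extract_line(
            radial, grid, "axial-at-r", r=grid.geom.base_radius / 2.0,
            quantity="radial_velocity", units="m/s")
        if grid.mode == "axisym" else extract_line(
            radial, grid, "centerline", quantity="radial_velocity",
            units="m/s"),
        "static_pressure": extract_line(
            der["static_pressure"], grid, "centerline",
            quantity="static_pressure", units="Pa"),
        "dynamic_pressure": extract_line(
            der["dynamic_pressure"], grid, "centerline",
            quantity="dynamic_pressure", units="Pa"),
        "pressure_coefficient": extract_line(
            der["pressure_coefficient"], grid, "centerline",
            quantity="pressure_coefficient", units="-"),
        "cell_reynolds": extract_line(
            der["cell_reynolds"], grid, "centerline",
            quantity="cell_reynolds", units="-"),
        "temperature": extract_line(
            temp.theta, grid, "radial-at-z",
            z=0.75 * grid.geom.segment_length, quantity="temperature",
            units="-"),
    }
    return profs


def run_case(config: CaseConfig, write_outputs: bool = True) -> Dict:
    """Solve flow + temperature and export the study's plotted quantities.

    Returns a manifest: output paths, a machine-readable summary (pressure
    drop, peak velocity, iterations) and the converged flag.  Outputs are
    written even when unconverged; callers should branch on
    ``manifest["converged"]`` (the CLI exits nonzero).
    """
    cfg = config
    grid = cfg.build_grid()
    flow, hist = solve_steady(cfg)
    groups = cfg.resolved_groups()
    temp = solve_energy(flow, grid, cfg.fluid, groups,
                        bc=default_thermal_bc(cfg.theta_wall),
                        dissipation=cfg.dissipation_form)
    pd = pressure_drop(flow, grid)
    profs = _case_profiles(cfg, grid, flow, temp)
    speed = flow.speed()

    summary = {
        "case": cfg.name,
        "converged": bool(hist.converged),
        "iterations": hist.iterations,
        "dp_Pa": pd["dp"],
        "pre_stenotic_mean_Pa": pd["pre_stenotic_mean"],
        "post_stenotic_mean_Pa": pd["post_stenotic_mean"],
        "peak_velocity_m_per_s": float(speed.max()),
        "inlet_flow_rate_m3_per_s": flow.flow_rate(0),
        "Re": groups.Re,
        "Pr": groups.Pr,
        "Br": groups.Br,
        "degree": cfg.geometry.stenosis.degree if cfg.geometry.stenosis
        else 0.0,
        "ellipse_ratio": cfg.geometry.ellipse_ratio,
        "resolution": list(cfg.resolution),
        "mode": cfg.mode,
    }
    manifest = {"summary": summary, "converged": bool(hist.converged),
                "profiles": profs, "flow": flow, "temperature": temp,
                "history": hist, "files": []}

    if write_outputs:
        os.makedirs(cfg.outdir, exist_ok=True)
        base = os.path.join(cfg.outdir, cfg.name)
        vtk_path = write_vtk(base + "_fields.vtk", grid, flow, temp)
        manifest["files"].append(vtk_path)
        for qty in PROFILE_QUANTITIES:
            path = f"{base}_{qty}.csv"
            write_profile_csv(profs[qty], path)
            manifest["files"].append(path)
        spath = base + "_summary.json"
        with open(spath, "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest["files"].append(spath)
        from .config import save_config
        cpath = base + "_config.yaml"
        save_config(cfg, cpath)
        manifest["files"].append(cpath)
        hpath = base + "_convergence.csv"
        with open(hpath, "w") as fh:
            fh.write("iteration,momentum_residual,continuity_residual\n")
            for i, (rm, rc) in enumerate(zip(hist.momentum, hist.continuity)):
                fh.write(f"{i},{rm!r},{rc!r}\n")
        manifest["files"].append(hpath)
    return manifest


def _set_path(cfg: CaseConfig, path: str, value):
    """Set a dotted attribute path on a (copied) config, e.g. 'groups.Pr' or
    'geometry.stenosis.degree'."""
    parts = path.split(".")
    if parts[0] == "groups" and cfg.groups is None:
        cfg.groups = cfg.resolved_groups()
    obj = cfg
    for name in parts[:-1]:
        if not hasattr(obj, name):
            raise ValueError(f"cannot resolve parameter path {path!r}")
        obj = getattr(obj, name)
    leaf = parts[-1]
    if obj is None or not hasattr(obj, leaf):
        # special geometry shortcuts
        if path == "degree" or leaf == "degree":
            geom = cfg.geometry
            sten = StenosisSpec(
                degree=value, length=geom.segment_length / 5.0,
                center=geom.segment_length / 2.0) if value > 0 else None
            cfg.geometry = replace(geom, stenosis=sten)
            cfg.grid = None
            return
        raise ValueError(f"cannot resolve parameter path {path!r}")
    try:
        setattr(obj, leaf, value)
    except Exception:
        # frozen dataclass: rebuild along the path
        parent = cfg
        for name in parts[:-2]:
            parent = getattr(parent, name)
        frozen = getattr(parent, parts[-2]) if len(parts) > 1 else cfg
        setattr(parent, parts[-2], replace(frozen, **{leaf: value}))
    if parts[0] == "geometry":
        cfg.grid = None


def run_sweep(base: CaseConfig, parameter: str, values: Sequence,
              write_outputs: bool = False, outdir: Optional[str] = None
              ) -> Dict:
    """Run one full case per parameter value and collect aligned profiles.

    Default sweeps of the study: Pr in {0.7, 2, 5}, Br in {0.1, 0.5, 1.0,
    2.0}, stenosis degree in {0, 0.4, 0.6, 0.8}.  Returns per-value
    summaries and (for thermal sweeps) radial temperature profiles on
    identical coordinates.
    """
    if len(values) == 0:
        raise ValueError("sweep needs at least one value")
    results = {"parameter": parameter, "values": list(values),
               "summaries": [], "profiles": [], "manifests": []}
    for val in values:
        cfg = copy.deepcopy(base)
        cfg.grid = None
        _set_path(cfg, parameter, val)
        cfg.name = f"{base.name}_{parameter.split('.')[-1]}_{val}"
        if outdir:
            cfg.outdir = outdir
        man = run_case(cfg, write_outputs=write_outputs)
        results["summaries"].append(man["summary"])
        results["profiles"].append(man["profiles"]["temperature"])
        results["manifests"].append(man)
    if write_outputs and outdir:
        os.makedirs(outdir, exist_ok=True)
        path = os.path.join(
            outdir, f"sweep_{parameter.replace('.', '_')}.csv")
        profs = results["profiles"]
        with open(path, "w") as fh:
            header = "coordinate," + ",".join(
                f"{parameter}={v}" for v in values)
            fh.write(header + "\n")
            for row in zip(profs[0].coords, *(p.values for p in profs)):
                fh.write(",".join(repr(float(x)) for x in row) + "\n")
        results["comparison_csv"] = path
    return results
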