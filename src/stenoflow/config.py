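"""Declarative YAML case configuration (round-trippable).

The file mirrors CaseConfig with sections for geometry / fluid / groups /
solver / outputs; a config saved from a resolved case re-runs to identical
outputs (the pipeline is deterministic end to end).
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional

import yaml

from .cases import CaseConfig
from .flow import SolverSettings
from .geometry import LumenGeometry, StenosisSpec
from .groups import DimensionlessGroups
from .rheology import FluidProperties

__all__ = ["save_config", "load_config", "case_to_dict", "case_from_dict"]


def case_to_dict(cfg: CaseConfig) -> dict:
    d = {
        "name": cfg.name,
        "mode": cfg.mode,
        "resolution": list(cfg.resolution),
        "clustering": cfg.clustering,
        "inlet_speed": cfg.inlet_speed,
        "Ti": cfg.Ti,
        "Tb": cfg.Tb,
        "theta_wall": cfg.theta_wall,
        "dissipation_form": cfg.dissipation_form,
        "outdir": cfg.outdir,
        "geometry": {
            "base_radius": cfg.geometry.base_radius,
            "segment_length": cfg.geometry.segment_length,
            "ellipse_ratio": cfg.geometry.ellipse_ratio,
            "stenosis": None if cfg.geometry.stenosis is None else
            asdict(cfg.geometry.stenosis),
        },
        "fluid": asdict(cfg.fluid),
        "solver": asdict(cfg.solver),
        "groups": None if cfg.groups is None else asdict(cfg.groups),
    }
    return d


def case_from_dict(d: dict) -> CaseConfig:
    geom = d.get("geometry", {})
    sten = geom.get("stenosis")
    geometry = LumenGeometry(
        base_radius=geom.get("base_radius", 2e-3),
        segment_length=geom.get("segment_length", 20e-3),
        ellipse_ratio=geom.get("ellipse_ratio", 1.0),
        stenosis=None if sten is None else StenosisSpec(**sten),
    )
    groups = d.get("groups")
    return CaseConfig(
        name=d.get("name", "case"),
        geometry=geometry,
        fluid=FluidProperties(**d.get("fluid", {})),
        inlet_speed=d.get("inlet_speed", 0.02),
        Ti=d.get("Ti", 310.0),
        Tb=d.get("Tb", 313.0),
        groups=None if groups is None else DimensionlessGroups(**groups),
        solver=SolverSettings(**d.get("solver", {})),
        mode=d.get("mode", "axisym"),
        resolution=tuple(d.get("resolution", (32, 128))),
        clustering=d.get("clustering", 1.0),
        theta_wall=d.get("theta_wall", 1.0),
        dissipation_form=d.get("dissipation_form", "standard"),
        outdir=d.get("outdir", "out"),
    )


def save_config(cfg: CaseConfig, path) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump(case_to_dict(cfg), fh, sort_keys=False)
    return str(path)


def load_config(path) -> CaseConfig:
    with open(path) as fh:
        return case_from_dict(yaml.safe_load(fh))
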