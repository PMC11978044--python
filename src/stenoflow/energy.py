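"""Temperature transport with viscous dissipation (one-way coupled).

Solves the steady dimensionless energy equation on a converged flow field,

    u . grad(theta) = 1/(Re*Pr) lap(theta) + Br/(Re*Pr) * Phi,

where theta = (T - Ti)/(Tb - Ti) and Phi is the viscous-dissipation
function built from the discrete velocity gradients.  Working in the grid's
dimensional coordinates with velocity scale u0 and length scale L this
becomes u . grad(theta) = D lap(theta) + B Phi with D = u0*L/(Re*Pr) and
B = Br*L/(u0*Re*Pr); Phi carries 1/s^2.

The flow field is not altered (no temperature-dependent viscosity is
modeled), so the Prandtl and dissipation-group sweeps are temperature-field
responses at a fixed velocity field.

Discretization: first-order upwind advection and central diffusion on the
open cells, walls entering through cut links at the geometric wall
distance.  With dissipation off the scheme satisfies the discrete maximum
principle: theta is bounded by its boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Dict, Optional, Tuple

import numpy as np

from .flow import FlowField
from .grid import Grid
from .groups import DimensionlessGroups
from .rheology import FluidProperties

__all__ = ["TemperatureField", "solve_energy", "default_thermal_bc"]

BC = Dict[str, Tuple[str, float]]


@dataclass
class TemperatureField:
    """Cell-centered dimensionless temperature and its reference scales."""

    grid: Grid
    theta: np.ndarray
    Ti: float
    Tb: float
    groups: DimensionlessGroups
    bc: BC = dfield(default_factory=dict)

    def temperature(self) -> np.ndarray:
        """Dimensional temperature field T = Ti + theta*(Tb - Ti) [K]."""
        return self.Ti + self.theta * (self.Tb - self.Ti)


def default_thermal_bc(theta_wall: float = 1.0) -> BC:
    """Heated walls at fixed theta, cold inlet, advective outlet."""
    return {
        "inlet": ("dirichlet", 0.0),
        "outlet": ("neumann", 0.0),
        "wall": ("dirichlet", theta_wall),
    }


def _backend(grid: Grid):
    if grid.mode == "axisym":
        from . import _axisym as mod
    else:
        from . import _cart3d as mod
    return mod


def dissipation_source(flow: FlowField, grid: Grid,
                       groups: DimensionlessGroups,
                       props: Optional[FluidProperties] = None,
                       form: str = "standard") -> np.ndarray:
    """Per-cell integrated dissipation source B*Phi*V (>= 0 pointwise).

    ``form`` selects the dissipation function: "standard" (the full second
    invariant, Phi = gamma_dot^2) or "printed" (the study's grouping, 3D
    mode only; identical to standard in the axisymmetric reduction).
    """
    be = _backend(grid)
    Phi = be.dissipation_field(flow, grid, form=form)
    alpha_switch = props.alpha if props is not None else 1.0
    B = alpha_switch * groups.Br * groups.L / (groups.u0 * groups.Re * groups.Pr)
    if grid.mode == "axisym":
        V = grid.axial_face_area()[:, None] * np.asarray(grid.dz)[None, :]
    else:
        dx, dy = grid.spacings["x"], grid.spacings["y"]
        V = dx * dy * np.asarray(grid.spacings["z"])[None, None, :]
        V = np.broadcast_to(V, grid.shape)
    return np.where(grid.open_, B * Phi * V, 0.0)


def solve_energy(flow: FlowField, grid: Grid, props: FluidProperties,
                 groups: DimensionlessGroups, bc: Optional[BC] = None,
                 dissipation: str = "standard") -> TemperatureField:
    """Solve the steady temperature equation on a converged flow field.

    Requires Re, Pr > 0 and Br >= 0 (Br = 0 turns dissipation off exactly).
    Returns the cell-centered theta field (zero in masked cells).
    """
    bc = bc if bc is not None else default_thermal_bc()
    be = _backend(grid)
    D = groups.u0 * groups.L / (groups.Re * groups.Pr)
    source = None
    if groups.Br > 0 and (props is None or props.alpha != 0):
        source = dissipation_source(flow, grid, groups, props,
                                    form=dissipation)
    theta = be.solve_scalar(flow, grid, D, bc, source=source)
    return TemperatureField(grid=grid, theta=theta, Ti=groups.Ti,
                            Tb=groups.Tb, groups=groups, bc=dict(bc))


def wall_heat_balance(flow: FlowField, grid: Grid, temp: TemperatureField
                      ) -> Dict[str, float]:
    """Diffusive wall heat inflow vs net advective enthalpy outflow
    (dimensionless, per unit rho*Cp*(Tb-Ti)); at Br = 0 and convergence the
    two agree."""
    g = temp.groups
    D = g.u0 * g.L / (g.Re * g.Pr)
    th = temp.theta
    if grid.mode != "axisym":
        raise NotImplementedError("heat balance audit is axisymmetric-only")
    from ._axisym import _work
    w = _work(grid)
    kind_wall, val_wall = temp.bc.get("wall", ("dirichlet", 1.0))
    q_wall = 0.0
    if kind_wall == "dirichlet":
        for i in range(w.nz):
            mi = int(w.m[i])
            if mi == 0:
                continue
            d = np.clip(w.R_zc[i] - w.r_c[mi - 1], 0.05 * w.dr, 1.5 * w.dr)
            A_n = w.r_f[mi] * w.dz[i]
            q_wall += D * A_n * (val_wall - th[mi - 1, i]) / d
    # advective enthalpy through inlet and outlet planes (upwinded values)
    kind_in, val_in = temp.bc.get("inlet", ("dirichlet", 0.0))
    F_in = w.A_z * flow.u[:, 0]
    adv_in = float((F_in * val_in * w.open[:, 0]).sum())
    F_out = w.A_z * flow.u[:, w.nz]
    adv_out = float((F_out * th[:, w.nz - 1] * w.open[:, w.nz - 1]).sum())
    # diffusive exchange through the inlet plane (Dirichlet inlet allows
    # conduction against the flow)
    q_inlet = 0.0
    if kind_in == "dirichlet":
        q_inlet = float((D * w.A_z / (0.5 * w.dz[0])
                         * (val_in - th[:, 0]) * w.open[:, 0]).sum())
    return {"wall_in": q_wall + q_inlet,
            "advected_net": adv_out - adv_in}
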