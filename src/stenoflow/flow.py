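"""Steady incompressible generalized-Newtonian flow solver.

Finite-volume, fully staggered (velocities on faces, pressure at cell
centers), with SIMPLE pressure-velocity coupling.  The momentum equations are
the dimensional ones,

    rho (u . grad) u = -grad p + div( mu(gamma_dot) (grad u + grad u^T) ),

with the Williamson apparent viscosity recomputed from the discrete shear
rate every outer iteration.  Diffusion is implicit in the div(mu grad u)
part; the transpose-stress part is added as an explicit deferred correction
(exactly zero for constant viscosity with an incompressible field) and can be
switched off.  Convection is first-order upwind by default with an optional
central deferred correction.

Boundary conditions follow the study setup: no-slip walls, a parabolic
(fully developed) inlet profile normalized so the *discrete* inlet flux is
U times the discrete open inlet area, a zero-gauge-pressure outlet with
zero-gradient velocity rescaled to the inlet flow rate, and symmetry on the
axis (axisymmetric mode).

After every pressure-correction step the discrete per-cell divergence is
zero to linear-solver precision, so cross-section flow rates match the inlet
flow rate by construction at convergence; this is the solver's conservation
guarantee, not a tuned property.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import List, Optional

import numpy as np

from .grid import Grid
from .rheology import FluidProperties

__all__ = [
    "SolverSettings",
    "ConvergenceHistory",
    "FlowField",
    "apply_boundary_conditions",
    "simple_iterate",
    "solve_steady",
]


@dataclass
class SolverSettings:
    """Numerical controls for the SIMPLE outer loop.

    relax_u / relax_p are momentum / pressure under-relaxation factors in
    (0, 1]; tolerances are relative, scaled residuals (momentum by the
    equation magnitude sum |a_P u_P|, continuity by the inlet flow rate).
    """

    relax_u: float = 0.7
    relax_p: float = 0.3
    tol_momentum: float = 1e-6
    tol_continuity: float = 1e-7
    max_outer: int = 800
    advection: str = "upwind"  # "upwind" | "central" (deferred correction)
    full_stress: bool = True
    pseudo_transient: bool = False
    pseudo_dt: float = 0.05  # [s], only used when pseudo_transient
    initial: str = "profile"  # "profile" | "zero"

    def __post_init__(self) -> None:
        for name in ("relax_u", "relax_p"):
            val = getattr(self, name)
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {val}")
        if self.tol_momentum <= 0 or self.tol_continuity <= 0:
            raise ValueError("tolerances must be positive")
        if self.advection not in ("upwind", "central"):
            raise ValueError(f"unknown advection scheme {self.advection!r}")


@dataclass
class ConvergenceHistory:
    """Per-outer-iteration residual norms and the final verdict."""

    momentum: List[float] = dfield(default_factory=list)
    continuity: List[float] = dfield(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.momentum)


@dataclass
class FlowField:
    """Staggered velocity + cell-centered pressure on a :class:`Grid`.

    Axisymmetric: ``u`` axial on z-faces (nr, nz+1), ``v`` radial on r-faces
    (nr+1, nz).  Cartesian 3D: ``u`` (nx+1, ny, nz), ``v`` (nx, ny+1, nz),
    ``w`` axial (nx, ny, nz+1).  ``p`` [Pa] and apparent viscosity ``mu``
    [Pa s] are cell-centered.
    """

    grid: Grid
    inlet_speed: float
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    mu: np.ndarray
    w: Optional[np.ndarray] = None
    history: ConvergenceHistory = dfield(default_factory=ConvergenceHistory)

    @property
    def mode(self) -> str:
        return self.grid.mode

    def axial_velocity(self) -> np.ndarray:
        """Cell-centered axial velocity."""
        ax = self.u if self.mode == "axisym" else self.w
        return 0.5 * (ax[..., :-1] + ax[..., 1:])

    def speed(self) -> np.ndarray:
        """Cell-centered velocity magnitude."""
        if self.mode == "axisym":
            uc = 0.5 * (self.u[:, :-1] + self.u[:, 1:])
            vc = 0.5 * (self.v[:-1, :] + self.v[1:, :])
            return np.hypot(uc, vc)
        uc = 0.5 * (self.u[:-1, :, :] + self.u[1:, :, :])
        vc = 0.5 * (self.v[:, :-1, :] + self.v[:, 1:, :])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return np.sqrt(uc**2 + vc**2 + wc**2)

    def flow_rate(self, i: int) -> float:
        """Volumetric flow rate through the axial face plane i (2*pi included
        in axisym mode so both modes return m^3/s)."""
        if self.mode == "axisym":
            A = self.grid.axial_face_area()
            return float(2.0 * np.pi * (A * self.u[:, i]).sum())
        dx, dy = self.grid.spacings["x"], self.grid.spacings["y"]
        return float((self.w[:, :, i] * dx * dy).sum())


def _backend(grid: Grid):
    if grid.mode == "axisym":
        from . import _axisym as mod
    else:
        from . import _cart3d as mod
    return mod


def make_field(grid: Grid, props: FluidProperties, U: float,
               settings: Optional[SolverSettings] = None) -> FlowField:
    """Allocate and initialize a FlowField with boundary conditions applied."""
    settings = settings or SolverSettings()
    if U <= 0:
        raise ValueError("inlet mean speed must be positive")
    return _backend(grid).make_field(grid, props, U, settings)


def apply_boundary_conditions(field: FlowField, grid: Grid,
                              U: Optional[float] = None) -> FlowField:
    """Enforce wall no-slip, the normalized parabolic inlet, the rescaled
    zero-gradient outlet and axis symmetry on ``field`` in place."""
    if grid.shape != field.p.shape:
        raise ValueError("grid and field shapes disagree")
    _backend(grid).apply_bcs(field, grid, U if U is not None else field.inlet_speed)
    return field


def simple_iterate(field: FlowField, grid: Grid, props: FluidProperties,
                   settings: SolverSettings):
    """One SIMPLE outer iteration (in place).

    Recomputes the apparent-viscosity field, solves the relaxed momentum
    equations, solves the pressure correction and corrects velocities and
    pressure.  Returns ``(field, residuals)`` where residuals maps
    "momentum" and "continuity" to the relative norms *entering* the
    iteration.
    """
    res = _backend(grid).iterate(field, grid, props, settings)
    return field, res


def solve_steady(case) -> tuple:
    """Solve a study case to steady state.

    ``case`` provides ``grid`` (a built :class:`Grid` or buildable via
    ``case.build_grid()``), ``fluid`` (:class:`FluidProperties`),
    ``solver`` (:class:`SolverSettings`) and ``inlet_speed``.  Returns
    ``(FlowField, ConvergenceHistory)``; non-convergence is flagged in the
    history, not raised.
    """
    grid = case.grid if isinstance(getattr(case, "grid", None), Grid) \
        else case.build_grid()
    props: FluidProperties = case.fluid
    settings: SolverSettings = getattr(case, "solver", None) or SolverSettings()
    U = float(case.inlet_speed)

    field = make_field(grid, props, U, settings)
    hist = field.history
    for _ in range(settings.max_outer):
        _, res = simple_iterate(field, grid, props, settings)
        hist.momentum.append(res["momentum"])
        hist.continuity.append(res["continuity"])
        if (res["momentum"] <= settings.tol_momentum
                and res["continuity"] <= settings.tol_continuity):
            hist.converged = True
            break
    return field, hist
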