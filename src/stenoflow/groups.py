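"""Dimensionless groups of the nondimensionalized problem.

Re = rho*u0*L/mu0 (Reynolds), Pr = Cp*mu0/k (Prandtl), and the
dissipation group Br = rho*Cp*mu0*u0^2 / (k*(Tb - Ti)) — a Brinkman-type
number scaling viscous heating against conduction, defined here exactly as
in the study's variable list.  beta = k/(rho*Cp) is the thermal diffusivity,
so the identity Re*Pr = u0*L/beta holds for every constructed instance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rheology import FluidProperties

__all__ = ["DimensionlessGroups", "dimensionless_groups"]


@dataclass(frozen=True)
class DimensionlessGroups:
    Re: float
    Pr: float
    Br: float
    beta: float       # thermal diffusivity k/(rho*Cp) [m^2/s]
    u0: float         # velocity scale [m/s]
    L: float          # length scale [m]
    Ti: float = 310.0  # inlet reference temperature [K]
    Tb: float = 313.0  # wall/bulk reference temperature [K]

    def __post_init__(self) -> None:
        for name in ("Re", "Pr", "beta", "u0", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Br < 0:
            raise ValueError("Br must be >= 0")


def dimensionless_groups(props: FluidProperties, u0: float, L: float,
                         Ti: float, Tb: float) -> DimensionlessGroups:
    """Build the groups from dimensional properties and scales."""
    if u0 <= 0 or L <= 0:
        raise ValueError("scales u0 and L must be positive")
    if Tb == Ti:
        raise ValueError("degenerate temperature scale: Tb must differ from Ti")
    rho, mu0 = props.density, props.mu0
    k, Cp = props.conductivity, props.specific_heat
    return DimensionlessGroups(
        Re=rho * u0 * L / mu0,
        Pr=Cp * mu0 / k,
        Br=rho * Cp * mu0 * u0**2 / (k * (Tb - Ti)),
        beta=k / (rho * Cp),
        u0=u0,
        L=L,
        Ti=Ti,
        Tb=Tb,
    )
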