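"""Independent analytic / semi-analytic reference solutions.

These closed forms and quadrature solutions are the verification oracles for
the finite-volume solvers; they share no code with the discrete operators.

* Hagen-Poiseuille pipe flow:  u(r) = 2U(1 - r^2/R^2), dp = 8 mu L U / R^2.
* Elliptic-duct Poiseuille:    u(x,y) = 2U(1 - x^2/a^2 - y^2/b^2).
* Fully developed Williamson pipe flow at fixed flow rate, obtained by
  pointwise root-finding of the shear balance mu(gd)*gd = G*r/2 followed by
  radial quadrature, with an outer root-find on the pressure gradient G to
  match the target flow rate.
* Plane Couette flow with viscous dissipation between equal-temperature
  walls: theta(eta) = Br * eta (1 - eta) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .rheology import FluidProperties, williamson_viscosity

__all__ = [
    "poiseuille_velocity",
    "poiseuille_pressure_drop",
    "elliptic_poiseuille_velocity",
    "williamson_shear_rate",
    "WilliamsonPipeSolution",
    "williamson_pipe_flow",
    "couette_dissipation_theta",
]


def poiseuille_velocity(r, R: float, U: float):
    """Axial velocity of Newtonian pipe flow with mean speed U."""
    return 2.0 * U * (1.0 - (np.asarray(r) / R) ** 2)


def poiseuille_pressure_drop(mu: float, L: float, U: float, R: float) -> float:
    """Pressure drop over length L of Newtonian pipe flow, 8 mu L U / R^2."""
    return 8.0 * mu * L * U / R**2


def elliptic_poiseuille_velocity(x, y, a: float, b: float, U: float):
    """Axial velocity in a straight elliptic duct with mean speed U (clipped at 0)."""
    s = 1.0 - (np.asarray(x) / a) ** 2 - (np.asarray(y) / b) ** 2
    return 2.0 * U * np.maximum(s, 0.0)


def williamson_shear_rate(tau, props: FluidProperties, *, pointwise: bool = False):
    """Invert the Williamson flow curve tau = mu(gd)*gd for gd >= 0.

    With ``pointwise=True`` each entry is solved by bracketed root-finding
    (brentq); otherwise the closed-form positive root of the underlying
    quadratic  mu_inf*lam*gd^2 + (mu0 - lam*tau)*gd - tau = 0  is used.
    Both agree to solver precision; the root-finding path exists so the
    oracle can be exercised without trusting the algebra.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("shear stress magnitude must be >= 0")
    if props.lam == 0.0 or props.mu0 == props.mu_inf:
        return tau / props.mu0
    if pointwise:
        def solve_one(t):
            if t == 0.0:
                return 0.0
            f = lambda gd: williamson_viscosity(gd, props) * gd - t
            hi = t / props.mu_inf + 1.0
            return brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14)
        return np.vectorize(solve_one)(tau)
    a = props.mu_inf * props.lam
    b = props.mu0 - props.lam * tau
    c = -tau
    return (-b + np.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)


@dataclass(frozen=True)
class WilliamsonPipeSolution:
    """Fully developed Williamson pipe-flow profile at a fixed flow rate."""

    r: np.ndarray          # radial stations, 0 .. R
    u: np.ndarray          # axial velocity at r [m/s]
    pressure_gradient: float  # G = -dp/dz > 0 [Pa/m]
    mean_velocity: float

    @property
    def centerline_velocity(self) -> float:
        return float(self.u[0])


def _pipe_profile(G: float, R: float, props: FluidProperties, n: int):
    r = np.linspace(0.0, R, n)
    gd = williamson_shear_rate(G * r / 2.0, props)
    # u(r) = int_r^R gd ds  (no-slip at R)
    I = cumulative_trapezoid(gd, r, initial=0.0)
    u = I[-1] - I
    Q = np.trapezoid(u * 2.0 * np.pi * r, r)
    return r, u, Q


def williamson_pipe_flow(
    U: float, R: float, props: FluidProperties, n: int = 4001
) -> WilliamsonPipeSolution:
    """Solve fully developed pipe flow of a Williamson fluid at mean speed U.

    The momentum balance gives the shear stress tau(r) = G*r/2 for axial
    pressure gradient magnitude G; the flow curve is inverted pointwise for
    the shear rate, the velocity follows by radial quadrature, and G is
    root-found (brentq) so the flow rate matches pi R^2 U.
    """
    Q_target = np.pi * R**2 * U
    G_newt_lo = 8.0 * props.mu_inf * U / R**2
    G_newt_hi = 8.0 * props.mu0 * U / R**2

    def mismatch(G):
        return _pipe_profile(G, R, props, n)[2] - Q_target

    G = brentq(mismatch, 0.5 * G_newt_lo, 2.0 * G_newt_hi, xtol=1e-14, rtol=1e-13)
    r, u, Q = _pipe_profile(G, R, props, n)
    return WilliamsonPipeSolution(
        r=r, u=u, pressure_gradient=G, mean_velocity=Q / (np.pi * R**2)
    )


def couette_dissipation_theta(eta, Br: float):
    """Plane Couette flow, both walls at theta = 0, dissipation on.

    With linear shear u = U*y/H and Brinkman-type group Br, the steady
    dimensionless temperature is theta(eta) = Br*eta*(1 - eta)/2 with peak
    Br/8 at mid-gap (eta = y/H).
    """
    eta = np.asarray(eta, dtype=float)
    return 0.5 * Br * eta * (1.0 - eta)
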