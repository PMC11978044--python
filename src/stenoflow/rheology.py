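"""Williamson shear-thinning rheology.

Blood is treated as a generalized-Newtonian Williamson fluid: the apparent
viscosity falls from the zero-shear value ``mu0`` toward the infinite-shear
value ``mu_inf`` with a characteristic time constant ``lam``,

    mu(gamma_dot) = mu_inf + (mu0 - mu_inf) / (1 + lam * gamma_dot).

The scalar shear rate is the standard second invariant of the rate-of-strain
tensor, gamma_ij = du_i/dx_j + du_j/dx_i and
gamma_dot = sqrt(1/2 * sum_ij gamma_ij^2), which is frame-indifferent and
reduces to the imposed rate in simple shear.

An alternative linear extra-stress form

    delta_ij = eta0 * (1 + Gamma * gamma_dot) * gamma_ij

is provided as a separate mode; it is a first-order (small Gamma*gamma_dot)
shear-thickening-looking expansion and is *not* algebraically consistent with
the rational viscosity law above, so the two parameter sets (mu0, mu_inf,
lam) and (eta0, Gamma) are kept independent.  The momentum solver uses the
rational law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluidProperties",
    "shear_rate_magnitude",
    "williamson_viscosity",
    "extra_stress_tensor",
]


@dataclass(frozen=True)
class FluidProperties:
    """Physical properties of the working fluid (blood-like defaults).

    density [kg/m^3]; mu0 >= mu_inf > 0 [Pa s]; lam >= 0 [s];
    conductivity k [W/m/K]; specific heat Cp [J/kg/K]; alpha is the on/off
    multiplier of the viscous-dissipation term in the energy equation;
    (eta0 [Pa s], Gamma [s]) parameterize the alternative linear stress form.
    """

    density: float = 1060.0
    mu0: float = 0.056
    mu_inf: float = 0.00345
    lam: float = 3.313
    conductivity: float = 0.52
    specific_heat: float = 3617.0
    alpha: float = 1.0
    eta0: float = 0.056
    Gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.density <= 0.0:
            raise ValueError("density must be positive")
        if not (self.mu0 >= self.mu_inf > 0.0):
            raise ValueError("require mu0 >= mu_inf > 0")
        if self.lam < 0.0:
            raise ValueError("time constant lam must be >= 0")
        if self.conductivity <= 0.0 or self.specific_heat <= 0.0:
            raise ValueError("conductivity and specific heat must be positive")

    @classmethod
    def newtonian(cls, mu: float = 0.00345, **kw) -> "FluidProperties":
        """A Newtonian fluid of viscosity mu (lam = 0 makes mu(gd) = mu0 = mu)."""
        return cls(mu0=mu, mu_inf=mu, lam=0.0, eta0=mu, **kw)


def _strain_tensor(grad_u: np.ndarray) -> np.ndarray:
    g = np.asarray(grad_u, dtype=float)
    if g.shape[-2:] != (3, 3):
        raise ValueError("velocity gradient must have trailing shape (3, 3)")
    return g + np.swapaxes(g, -1, -2)


def shear_rate_magnitude(grad_u: np.ndarray) -> float:
    """Scalar shear rate gamma_dot [1/s] from a (…,3,3) velocity-gradient tensor.

    gamma_dot = sqrt(1/2 * gamma:gamma) with gamma = grad u + (grad u)^T.
    Zero for rigid rotation; equals the applied rate kappa in simple shear.
    """
    gam = _strain_tensor(grad_u)
    if not np.all(np.isfinite(gam)):
        raise ValueError("velocity gradient must be finite")
    return np.sqrt(0.5 * np.sum(gam * gam, axis=(-2, -1)))


def williamson_viscosity(gamma_dot, props: FluidProperties):
    """Apparent viscosity mu(gamma_dot) [Pa s] of the Williamson law.

    Strictly decreasing from mu0 at rest toward mu_inf at infinite shear
    (identically mu0 when lam == 0).
    """
    gd = np.asarray(gamma_dot, dtype=float)
    if np.any(gd < 0.0):
        raise ValueError("shear rate must be non-negative")
    mu = props.mu_inf + (props.mu0 - props.mu_inf) / (1.0 + props.lam * gd)
    return mu if mu.ndim else float(mu)


def extra_stress_tensor(grad_u: np.ndarray, eta0: float, Gamma: float) -> np.ndarray:
    """Linear Williamson extra-stress delta_ij = eta0*(1 + Gamma*gd)*gamma_ij [Pa].

    Symmetric by construction; traceless for an incompressible gradient.
    Emits a warning outside the model's stated validity range Gamma*gd < 1.
    """
    gam = _strain_tensor(grad_u)
    gd = shear_rate_magnitude(grad_u)
    if np.any(np.asarray(Gamma * gd) >= 1.0):
        warnings.warn(
            "Gamma*gamma_dot >= 1: linear Williamson stress outside its "
            "stated validity range",
            RuntimeWarning,
            stacklevel=2,
        )
    return eta0 * (1.0 + Gamma * np.asarray(gd)[..., None, None]) * gam
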