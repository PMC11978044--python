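"""Parametric stenosed-lumen geometry.

An arterial segment is modeled as a straight tube of base radius ``R0`` and
length ``L`` whose local *equivalent* radius ``r(z)`` may be narrowed by a
smooth cosine-bump stenosis.  The cross-section at axial position ``z`` is
either a circle of radius ``r(z)`` or an ellipse with minor/major axis ratio
``kappa``; the elliptic section is constructed at *equal area* to the circular
one (``pi*a*b == pi*r(z)**2``) so that comparisons between circular and
elliptic lumens isolate the effect of shape at fixed flow rate.

The stenosis axial profile is a C1 cosine bump,

    r(z) = R0 - (s*R0/2) * (1 + cos(2*pi*(z - zc)/Ls))   for |z - zc| <= Ls/2

with fractional diameter reduction ``s`` at the throat ``zc`` and axial extent
``Ls``; outside the bump the vessel is unnarrowed.  The profile family is
pluggable through :attr:`StenosisSpec.shape`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import quad

__all__ = [
    "StenosisSpec",
    "LumenGeometry",
    "radius_profile",
    "ellipse_section",
    "lumen_volume",
]


@dataclass(frozen=True)
class StenosisSpec:
    """Parametric description of a single axisymmetric narrowing.

    Parameters
    ----------
    degree:
        Fractional reduction of the lumen *diameter* at the throat,
        ``0 <= degree < 1``.  The canonical study cases use 0, 0.4, 0.6, 0.8.
    length:
        Axial extent of the narrowing [m].
    center:
        Axial position of the throat [m].
    shape:
        Profile family tag; only ``"cosine"`` is built in.
    """

    degree: float
    length: float
    center: float
    shape: str = "cosine"

    def __post_init__(self) -> None:
        if not (0.0 <= self.degree < 1.0):
            raise ValueError(f"stenosis degree must be in [0, 1), got {self.degree}")
        if self.length <= 0.0:
            raise ValueError("stenosis length must be positive")
        if self.shape != "cosine":
            raise ValueError(f"unknown stenosis profile family {self.shape!r}")


@dataclass(frozen=True)
class LumenGeometry:
    """Lumen of one arterial segment.

    ``base_radius`` is the unnarrowed equivalent radius R0 [m],
    ``segment_length`` the axial length L [m], and ``ellipse_ratio``
    the minor/major axis ratio kappa in (0, 1] of the cross-section
    (1 = circular).
    """

    base_radius: float
    segment_length: float
    ellipse_ratio: float = 1.0
    stenosis: Optional[StenosisSpec] = None

    def __post_init__(self) -> None:
        if self.base_radius <= 0.0:
            raise ValueError("base_radius must be positive")
        if self.segment_length <= 0.0:
            raise ValueError("segment_length must be positive")
        if not (0.0 < self.ellipse_ratio <= 1.0):
            raise ValueError(
                f"ellipse_ratio must lie in (0, 1], got {self.ellipse_ratio}"
            )
        s = self.stenosis
        if s is not None:
            lo, hi = s.center - s.length / 2.0, s.center + s.length / 2.0
            if lo < 0.0 or hi > self.segment_length:
                raise ValueError(
                    "stenotic window [{:.4g}, {:.4g}] must lie inside [0, {:.4g}]".format(
                        lo, hi, self.segment_length
                    )
                )

    # convenience accessors -------------------------------------------------
    @property
    def throat_radius(self) -> float:
        if self.stenosis is None:
            return self.base_radius
        return self.base_radius * (1.0 - self.stenosis.degree)

    def radius(self, z):
        return radius_profile(z, self)

    def section(self, z):
        return ellipse_section(z, self)


def radius_profile(z, geom: LumenGeometry):
    """Local equivalent lumen radius r(z) [m].

    Accepts a scalar or array of axial positions; every entry must lie inside
    ``[0, L]``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < -1e-12) or np.any(z > geom.segment_length * (1 + 1e-12)):
        raise ValueError("axial position outside segment [0, L]")
    r = np.full_like(z, geom.base_radius, dtype=float)
    s = geom.stenosis
    if s is not None and s.degree > 0.0:
        xi = z - s.center
        inside = np.abs(xi) <= s.length / 2.0
        bump = (s.degree * geom.base_radius / 2.0) * (
            1.0 + np.cos(2.0 * np.pi * xi / s.length)
        )
        r = np.where(inside, geom.base_radius - bump, r)
    return r if r.ndim else float(r)


def ellipse_section(z, geom: LumenGeometry) -> Tuple[np.ndarray, np.ndarray]:
    """Semi-axes (a, b) of the cross-section at z, at equal area.

    a = r(z)/sqrt(kappa) (major, along x), b = r(z)*sqrt(kappa) (minor,
    along y), so pi*a*b == pi*r(z)**2 for every kappa.
    """
    if geom.ellipse_ratio <= 0.0:
        raise ValueError("ellipse ratio must be positive")
    r = radius_profile(z, geom)
    rk = np.sqrt(geom.ellipse_ratio)
    return r / rk, r * rk


def contains(x, y, a, b):
    """Ellipse containment indicator x^2/a^2 + y^2/b^2 <= 1 (boundary = 1)."""
    return (np.asarray(x) / a) ** 2 + (np.asarray(y) / b) ** 2 <= 1.0 + 1e-14


def lumen_volume(geom: LumenGeometry) -> float:
    """Analytic lumen volume by quadrature of pi*r(z)^2 dz (kappa-independent)."""
    val, _ = quad(lambda z: np.pi * radius_profile(z, geom) ** 2,
                  0.0, geom.segment_length, limit=200)
    return val
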