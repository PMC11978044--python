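"""Structured computational grids over parametric lumens.

Two discretizations are provided, both staggered (velocities on faces,
pressure at cell centers):

* ``axisym`` — a tensor-product (r, z) grid on [0, R0] x [0, L] with the
  symmetry axis at r = 0.  Cells whose center lies outside the local lumen
  radius r(z) are masked solid; the no-slip wall is recovered at
  second-order accuracy by the solvers through cut links that use the exact
  geometric wall distance instead of the half-cell stair-step distance.
* ``cart3d`` — a uniform Cartesian box bounding the widest elliptic
  cross-section, with a per-cell lumen mask from the ellipse containment
  test (equal-area elliptic sections, see :mod:`stenoflow.geometry`).

Axial grid clustering concentrates cells inside the stenotic window using a
smooth density function, so the throat is resolved without a global
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .geometry import LumenGeometry, ellipse_section, radius_profile

__all__ = ["Grid", "build_grid"]

Resolution = Union[int, Sequence[int]]


@dataclass
class Grid:
    """Structured staggered grid (axisymmetric or masked-Cartesian 3D).

    Axisymmetric arrays are indexed ``[j_r, i_z]``; Cartesian arrays
    ``[ix, iy, iz]`` with z the axial direction.  ``open_`` flags lumen
    cells.  All azimuthal (2*pi) factors are dropped consistently from
    axisymmetric areas and volumes.
    """

    mode: str
    geom: LumenGeometry
    # face/center coordinates per axis (axisym: axes = ("r", "z"))
    faces: dict
    centers: dict
    spacings: dict
    open_: np.ndarray

    # ------------------------------------------------------------------ #
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.open_.shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_open(self) -> int:
        return int(self.open_.sum())

    # axisymmetric helpers ------------------------------------------------
    @property
    def r_f(self):
        return self.faces["r"]

    @property
    def r_c(self):
        return self.centers["r"]

    @property
    def z_f(self):
        return self.faces["z"]

    @property
    def z_c(self):
        return self.centers["z"]

    @property
    def dr(self):
        return self.spacings["r"]

    @property
    def dz(self):
        return self.spacings["z"]

    def axial_face_area(self) -> np.ndarray:
        """Axisym: annular area (per radian) of each radial cell row."""
        rf = self.r_f
        return 0.5 * (rf[1:] ** 2 + 0.0) - 0.5 * rf[:-1] ** 2

    def local_radius(self, z):
        return radius_profile(z, self.geom)

    def section_semi_axes(self, z):
        return ellipse_section(z, self.geom)

    def open_section_area(self, i: int) -> float:
        """Discrete open cross-section area at axial cell column i."""
        if self.mode == "axisym":
            return float(self.axial_face_area()[self.open_[:, i]].sum())
        dx, dy = self.spacings["x"], self.spacings["y"]
        return float(self.open_[:, :, i].sum() * dx * dy)

    def open_volume(self) -> float:
        """Total open (lumen) volume of the mask."""
        if self.mode == "axisym":
            A = self.axial_face_area()[:, None]
            return float((2.0 * np.pi * A * self.dz[None, :] * self.open_).sum())
        dx, dy = self.spacings["x"], self.spacings["y"]
        dz = np.asarray(self.spacings["z"])
        return float((self.open_.sum(axis=(0, 1)) * dz).sum() * dx * dy)


def _clustered_faces(L: float, n: int, geom: LumenGeometry, clustering: float):
    """Axial face positions with smooth refinement inside the stenotic window."""
    s = geom.stenosis
    if clustering <= 1.0 or s is None or s.degree == 0.0:
        return np.linspace(0.0, L, n + 1)
    zf_fine = np.linspace(0.0, L, 40 * n + 1)
    xi = zf_fine - s.center
    bump = np.where(
        np.abs(xi) <= s.length / 2.0,
        0.5 * (1.0 + np.cos(2.0 * np.pi * xi / s.length)),
        0.0,
    )
    density = 1.0 + (clustering - 1.0) * bump
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (density[1:] + density[:-1]))])
    cdf /= cdf[-1]
    return np.interp(np.linspace(0.0, 1.0, n + 1), cdf, zf_fine)


def build_grid(
    geom: LumenGeometry,
    resolution: Resolution,
    mode: str = "axisym",
    clustering: float = 1.0,
) -> Grid:
    """Build a staggered structured grid over the lumen.

    ``resolution`` is (nr, nz) for axisym or (nx, ny, nz) for cart3d; a bare
    int n is expanded to (n, 4n) and (n, n, 2n) respectively.  ``clustering``
    >= 1 increases axial cell density inside the stenotic window by that
    factor.  Raises if any axis has fewer than 4 cells or if fewer than 3
    cells span the throat radius.
    """
    if mode not in ("axisym", "cart3d"):
        raise ValueError(f"unknown grid mode {mode!r}")
    if clustering < 1.0:
        raise ValueError("clustering must be >= 1")
    if isinstance(resolution, (int, np.integer)):
        resolution = (resolution, 4 * resolution) if mode == "axisym" else (
            resolution, resolution, 2 * resolution)
    res = tuple(int(n) for n in resolution)
    expected = 2 if mode == "axisym" else 3
    if len(res) != expected:
        raise ValueError(f"{mode} resolution needs {expected} entries, got {res}")
    if any(n < 4 for n in res):
        raise ValueError("resolution must be at least 4 cells per axis")

    L, R0 = geom.segment_length, geom.base_radius

    if mode == "axisym":
        nr, nz = res
        r_f = np.linspace(0.0, R0, nr + 1)
        z_f = _clustered_faces(L, nz, geom, clustering)
        r_c = 0.5 * (r_f[:-1] + r_f[1:])
        z_c = 0.5 * (z_f[:-1] + z_f[1:])
        dr = np.diff(r_f)
        dz = np.diff(z_f)
        R_c = radius_profile(z_c, geom)
        if np.count_nonzero(r_c < geom.throat_radius) < 3:
            raise ValueError(
                "grid too coarse: fewer than 3 radial cells across the throat "
                f"radius {geom.throat_radius:.3g} m; increase radial resolution"
            )
        open_ = r_c[:, None] < R_c[None, :]
        return Grid(
            mode="axisym",
            geom=geom,
            faces={"r": r_f, "z": z_f},
            centers={"r": r_c, "z": z_c},
            spacings={"r": float(dr[0]), "z": dz},
            open_=open_,
        )

    nx, ny, nz = res
    a0, b0 = ellipse_section(0.0, geom)  # widest section is the unnarrowed one
    x_f = np.linspace(-a0, a0, nx + 1)
    y_f = np.linspace(-b0, b0, ny + 1)
    # the 3D solver requires uniform axial spacing; clustering is an
    # axisymmetric-mode feature
    z_f = np.linspace(0.0, L, nz + 1)
    x_c = 0.5 * (x_f[:-1] + x_f[1:])
    y_c = 0.5 * (y_f[:-1] + y_f[1:])
    z_c = 0.5 * (z_f[:-1] + z_f[1:])
    a_c, b_c = ellipse_section(z_c, geom)
    _, b_th = ellipse_section(
        geom.stenosis.center if geom.stenosis else 0.0, geom)
    dy = float(y_f[1] - y_f[0])
    if b_th / dy < 3.0:
        raise ValueError(
            "grid too coarse: fewer than 3 cells across the throat semi-minor "
            f"axis {b_th:.3g} m; increase transverse resolution"
        )
    open_ = (
        (x_c[:, None, None] / a_c[None, None, :]) ** 2
        + (y_c[None, :, None] / b_c[None, None, :]) ** 2
    ) < 1.0
    return Grid(
        mode="cart3d",
        geom=geom,
        faces={"x": x_f, "y": y_f, "z": z_f},
        centers={"x": x_c, "y": y_c, "z": z_c},
        spacings={"x": float(x_f[1] - x_f[0]), "y": dy, "z": np.diff(z_f)},
        open_=open_,
    )
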