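"""Derived quantities, line profiles, stream function and exports.

Conventions (the study never names its reference scales, so the only two it
defines are used): the pressure reference is the outlet-plane mean pressure
and the velocity reference is the inlet mean speed.  The local cell size
entering the cell Reynolds number is the geometric mean of the local grid
spacings, an isotropic measure on anisotropic grids.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .flow import FlowField
from .grid import Grid
from .rheology import FluidProperties

__all__ = [
    "LineProfile",
    "derived_fields",
    "stream_function",
    "pathlines",
    "extract_line",
    "pressure_drop",
    "write_profile_csv",
    "plot_case_panels",
]


@dataclass
class LineProfile:
    """1D sampled profile of a scalar field along a named line."""

    coords: np.ndarray
    values: np.ndarray
    quantity: str
    units: str
    axis: str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.shape != self.values.shape:
            raise ValueError("coordinate and value arrays differ in length")
        if len(self.coords) > 1 and not np.all(np.diff(self.coords) > 0):
            raise ValueError("coordinates must be strictly increasing")


def write_profile_csv(profile: LineProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["coordinate", "value", "units"])
        for c, v in zip(profile.coords, profile.values):
            wr.writerow([repr(float(c)), repr(float(v)), profile.units])


# --------------------------------------------------------------------- #

def _plane_mean_pressure(flow: FlowField, grid: Grid, which: str) -> float:
    """Area-weighted mean pressure extrapolated to the inlet/outlet plane."""
    p = flow.p
    if grid.mode == "axisym":
        A = grid.axial_face_area()
        op = grid.open_
        if which == "inlet":
            cols, d0, d1 = (0, 1), grid.dz[0], grid.z_c[1] - grid.z_c[0]
        else:
            nz = p.shape[1]
            cols, d0, d1 = (nz - 1, nz - 2), grid.dz[-1], \
                grid.z_c[-1] - grid.z_c[-2]
        w0 = A * op[:, cols[0]]
        m0 = float((p[:, cols[0]] * w0).sum() / w0.sum())
        w1 = A * op[:, cols[1]]
        m1 = float((p[:, cols[1]] * w1).sum() / w1.sum())
        return m0 + (m0 - m1) * (0.5 * d0) / d1
    op = grid.open_
    nz = p.shape[2]
    if which == "inlet":
        cols, d0, d1 = (0, 1), grid.spacings["z"][0], \
            grid.centers["z"][1] - grid.centers["z"][0]
    else:
        cols, d0, d1 = (nz - 1, nz - 2), grid.spacings["z"][-1], \
            grid.centers["z"][-1] - grid.centers["z"][-2]
    w0 = op[:, :, cols[0]]
    m0 = float((p[:, :, cols[0]] * w0).sum() / w0.sum())
    w1 = op[:, :, cols[1]]
    m1 = float((p[:, :, cols[1]] * w1).sum() / w1.sum())
    return m0 + (m0 - m1) * (0.5 * d0) / d1


def derived_fields(flow: FlowField, props: FluidProperties,
                   U_ref: Optional[float] = None,
                   p_ref: Optional[float] = None) -> Dict[str, np.ndarray]:
    """Static/dynamic pressure, pressure coefficient and cell Reynolds number.

    p_dyn = rho |u|^2 / 2;  Cp = (p - p_ref) / (rho U_ref^2 / 2);
    cell Re = rho |u| Delta / mu(gamma_dot) with Delta the geometric mean of
    the local spacings.  Defaults: U_ref = inlet mean speed, p_ref = outlet
    plane mean (so Cp vanishes at the outlet reference section).
    """
    grid = flow.grid
    if U_ref is None:
        U_ref = flow.inlet_speed
    if U_ref <= 0:
        raise ValueError("reference speed must be positive")
    if p_ref is None:
        p_ref = _plane_mean_pressure(flow, grid, "outlet")
    rho = props.density
    speed = flow.speed()
    if grid.mode == "axisym":
        delta = np.sqrt(grid.dr * np.asarray(grid.dz))[None, :] \
            * np.ones(grid.shape)
    else:
        dx, dy = grid.spacings["x"], grid.spacings["y"]
        dz = np.asarray(grid.spacings["z"])
        delta = np.cbrt(dx * dy * dz)[None, None, :] * np.ones(grid.shape)
    mu = flow.mu
    out = {
        "static_pressure": np.where(grid.open_, flow.p - p_ref, 0.0),
        "dynamic_pressure": np.where(grid.open_, 0.5 * rho * speed**2, 0.0),
        "pressure_coefficient": np.where(
            grid.open_, (flow.p - p_ref) / (0.5 * rho * U_ref**2), 0.0),
        "cell_reynolds": np.where(grid.open_, rho * speed * delta / mu, 0.0),
    }
    return out


def stream_function(flow: FlowField, grid: Grid) -> np.ndarray:
    """Stokes stream function psi(r, z) on the (nr+1, nz+1) node lattice.

    psi(r, z) = int_0^r u_z(r', z) r' dr' (density-free convention), so
    psi = 0 on the axis and the wall value is Q/(2*pi) at every z.
    Iso-contours of psi are streamlines.
    """
    if grid.mode != "axisym":
        raise ValueError(
            "stream function is defined in axisymmetric mode only; "
            "use pathlines() for 3D fields")
    r_c, dr = grid.r_c, grid.dr
    nr, nz = grid.shape
    psi = np.zeros((nr + 1, nz + 1))
    incr = flow.u * (r_c[:, None] * dr)   # (nr, nz+1)
    psi[1:, :] = np.cumsum(incr, axis=0)
    return psi


def pathlines(flow: FlowField, seeds, n_steps: int = 200,
              dt: Optional[float] = None) -> list:
    """Integrate pathlines through a (3D) velocity field, forward Euler with
    midpoint correction and nearest-cell velocity sampling; companion to
    :func:`stream_function` for the Cartesian mode."""
    grid = flow.grid
    if grid.mode != "cart3d":
        raise ValueError("pathlines are for cart3d fields")
    xc, yc, zc = (grid.centers[k] for k in ("x", "y", "z"))
    uc = 0.5 * (flow.u[:-1] + flow.u[1:])
    vc = 0.5 * (flow.v[:, :-1] + flow.v[:, 1:])
    wc = 0.5 * (flow.w[:, :, :-1] + flow.w[:, :, 1:])
    if dt is None:
        dt = 0.25 * float(np.min(np.asarray(grid.spacings["z"]))) \
            / max(flow.inlet_speed, 1e-12)

    def vel(pt):
        i = int(np.clip(np.searchsorted(xc, pt[0]), 0, len(xc) - 1))
        j = int(np.clip(np.searchsorted(yc, pt[1]), 0, len(yc) - 1))
        k = int(np.clip(np.searchsorted(zc, pt[2]), 0, len(zc) - 1))
        if not grid.open_[i, j, k]:
            return None
        return np.array([uc[i, j, k], vc[i, j, k], wc[i, j, k]])

    lines = []
    for seed in np.atleast_2d(np.asarray(seeds, dtype=float)):
        pts = [seed.copy()]
        pt = seed.copy()
        for _ in range(n_steps):
            v1 = vel(pt)
            if v1 is None:
                break
            mid = pt + 0.5 * dt * v1
            v2 = vel(mid)
            pt = pt + dt * (v2 if v2 is not None else v1)
            if pt[2] >= grid.faces["z"][-1] or pt[2] <= grid.faces["z"][0]:
                break
            pts.append(pt.copy())
        lines.append(np.array(pts))
    return lines


# --------------------------------------------------------------------- #

def extract_line(values: np.ndarray, grid: Grid, axis: str = "centerline",
                 z: Optional[float] = None, r: Optional[float] = None,
                 quantity: str = "scalar", units: str = "-") -> LineProfile:
    """Sample a cell-centered scalar onto a named line (linear interpolation).

    axis: "centerline" (along z at r = 0), "radial-at-z" (needs z),
    "axial-at-r" (along z at fixed radius r), "wall-adjacent" (last open
    cell per column).  Axisymmetric mode; for cart3d, "centerline" samples
    along z at (x, y) = (0, 0) and "radial-at-z" along x at y = 0.
    """
    if grid.mode == "axisym":
        r_c, z_c = grid.r_c, grid.z_c
        if axis == "centerline":
            # quadratic-consistent linear extrapolation from the two
            # innermost rows to the axis
            vals = values[0, :] + (values[0, :] - values[1, :]) * 0.5
            return LineProfile(z_c, vals, quantity, units, axis)
        if axis == "axial-at-r":
            if r is None:
                raise ValueError("axial-at-r needs r")
            if not (0 <= r <= grid.geom.base_radius):
                raise ValueError("requested radius outside domain")
            vals = np.array([np.interp(r, r_c, values[:, i])
                             for i in range(len(z_c))])
            return LineProfile(z_c, vals, quantity, units, axis)
        if axis == "radial-at-z":
            if z is None:
                raise ValueError("radial-at-z needs z")
            if not (grid.z_f[0] <= z <= grid.z_f[-1]):
                raise ValueError("requested z outside domain")
            i = int(np.clip(np.searchsorted(z_c, z) - 1, 0, len(z_c) - 2))
            t = (z - z_c[i]) / (z_c[i + 1] - z_c[i])
            t = float(np.clip(t, 0.0, 1.0))
            vals = (1 - t) * values[:, i] + t * values[:, i + 1]
            m = int(min(grid.open_[:, i].sum(), grid.open_[:, i + 1].sum()))
            return LineProfile(r_c[:m], vals[:m], quantity, units, axis)
        if axis == "wall-adjacent":
            m = grid.open_.sum(axis=0)
            vals = np.array([values[max(mi - 1, 0), i]
                             for i, mi in enumerate(m)])
            return LineProfile(z_c, vals, quantity, units, axis)
        raise ValueError(f"unknown line axis {axis!r}")

    x_c, y_c, z_c = (grid.centers[k] for k in ("x", "y", "z"))
    if axis == "centerline":
        i = np.argmin(np.abs(x_c))
        j = np.argmin(np.abs(y_c))
        # average the 4 cells around the axis for symmetry
        ii = [i, i - 1] if x_c[i] > 0 or i + 1 >= len(x_c) else [i, i + 1]
        jj = [j, j - 1] if y_c[j] > 0 or j + 1 >= len(y_c) else [j, j + 1]
        vals = np.mean([values[a, b, :] for a in ii for b in jj], axis=0)
        return LineProfile(z_c, vals, quantity, units, axis)
    if axis == "radial-at-z":
        if z is None:
            raise ValueError("radial-at-z needs z")
        k = int(np.argmin(np.abs(z_c - z)))
        j = int(np.argmin(np.abs(y_c)))
        op = grid.open_[:, j, k]
        return LineProfile(x_c[op], values[op, j, k], quantity, units, axis)
    raise ValueError(f"unknown line axis {axis!r} for cart3d")


def pressure_drop(flow: FlowField, grid: Grid) -> Dict[str, float]:
    """Inlet-to-outlet pressure drop and pre-/post-stenotic section means.

    dp = mean p over the inlet plane minus mean p over the outlet plane
    (area-weighted, extrapolated to the planes).  The pre- and post-stenotic
    means are averages over the first and last axial thirds of the segment.
    """
    dp = _plane_mean_pressure(flow, grid, "inlet") \
        - _plane_mean_pressure(flow, grid, "outlet")
    if grid.mode == "axisym":
        z_c = grid.z_c
        A = grid.axial_face_area()[:, None] * np.ones_like(flow.p)
    else:
        z_c = grid.centers["z"]
        A = np.ones_like(flow.p)
    L = grid.geom.segment_length
    axisn = tuple(range(flow.p.ndim - 1))
    pre_cols = z_c < L / 3.0
    post_cols = z_c > 2.0 * L / 3.0
    w = A * grid.open_
    pm = (flow.p * w).sum(axis=axisn)
    wm = w.sum(axis=axisn)
    pre = float(pm[pre_cols].sum() / wm[pre_cols].sum())
    post = float(pm[post_cols].sum() / wm[post_cols].sum())
    return {"dp": float(dp), "pre_stenotic_mean": pre,
            "post_stenotic_mean": post}


def plot_case_panels(flow: FlowField, grid: Grid,
                     props: FluidProperties, temperature=None,
                     path=None, title: Optional[str] = None):
    """Four-panel case figure: velocity magnitude, static pressure,
    temperature and streamlines (stream-function contours), matching the
    study's per-case panel layout.  Axisymmetric mode only; returns the
    matplotlib figure (and saves it when ``path`` is given)."""
    if grid.mode != "axisym":
        raise ValueError("panel plot supports axisymmetric fields only")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = grid.z_c * 1e3
    r = grid.r_c * 1e3
    der = derived_fields(flow, props)
    fig, axes = plt.subplots(2, 2, figsize=(10, 6), constrained_layout=True)
    panels = [
        ("velocity magnitude [m/s]", np.where(grid.open_, flow.speed(),
                                              np.nan)),
        ("static pressure [Pa]", np.where(grid.open_,
                                          der["static_pressure"], np.nan)),
    ]
    if temperature is not None:
        panels.append(("temperature theta [-]",
                       np.where(grid.open_, temperature.theta, np.nan)))
    else:
        panels.append(("dynamic pressure [Pa]",
                       np.where(grid.open_, der["dynamic_pressure"],
                                np.nan)))
    for ax, (label, data) in zip(axes.flat, panels):
        pc = ax.pcolormesh(z, r, data, shading="auto")
        fig.colorbar(pc, ax=ax)
        ax.set_title(label)
        ax.set_xlabel("z [mm]")
        ax.set_ylabel("r [mm]")
    ax = axes.flat[3]
    psi = stream_function(flow, grid)
    ax.contour(grid.z_f * 1e3, grid.r_f * 1e3, psi, levels=15,
               linewidths=0.8)
    ax.plot(grid.z_c * 1e3, grid.local_radius(grid.z_c) * 1e3, "k-", lw=1.5)
    ax.set_title("streamlines (psi contours)")
    ax.set_xlabel("z [mm]")
    ax.set_ylabel("r [mm]")
    if title:
        fig.suptitle(title)
    if path is not None:
        fig.savefig(path, dpi=110)
    return fig
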