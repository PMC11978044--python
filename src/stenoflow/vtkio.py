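"""Minimal legacy-ASCII VTK structured-grid writer.

Writes converged fields for inspection in ParaView/VisIt.  Axisymmetric
fields are written as a 2D structured grid in the (z, r) plane; Cartesian
fields as the full 3D box.  Cell data: pressure, velocity vector, apparent
viscosity, lumen mask and (optionally) dimensionless temperature.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk"]


def _write_points(fh, pts):
    fh.write(f"POINTS {len(pts)} float\n")
    for x, y, z in pts:
        fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def _write_scalar(fh, name, data):
    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
    for v in np.asarray(data).ravel(order="F"):
        fh.write(f"{v:.9g}\n")


def _write_vector(fh, name, comps):
    fh.write(f"VECTORS {name} float\n")
    flat = [np.asarray(c).ravel(order="F") for c in comps]
    for vals in zip(*flat):
        fh.write(" ".join(f"{v:.9g}" for v in vals) + "\n")


def write_vtk(path, grid, flow=None, temperature=None) -> str:
    """Write grid (+ optional flow / temperature fields) to a legacy VTK file."""
    path = str(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("stenoflow structured fields\nASCII\n")
        fh.write("DATASET STRUCTURED_GRID\n")
        if grid.mode == "axisym":
            nr, nz = grid.shape
            fh.write(f"DIMENSIONS {nz + 1} {nr + 1} 1\n")
            pts = [(z, r, 0.0) for r in grid.r_f for z in grid.z_f]
            _write_points(fh, pts)
            ncell = nr * nz
            fh.write(f"\nCELL_DATA {ncell}\n")
            _write_scalar(fh, "mask", grid.open_.astype(float).T)
            if flow is not None:
                _write_scalar(fh, "pressure", flow.p.T)
                _write_scalar(fh, "viscosity", flow.mu.T)
                uc = 0.5 * (flow.u[:, :-1] + flow.u[:, 1:])
                vc = 0.5 * (flow.v[:-1, :] + flow.v[1:, :])
                _write_vector(fh, "velocity",
                              (uc.T, vc.T, np.zeros_like(uc).T))
            if temperature is not None:
                _write_scalar(fh, "theta", temperature.theta.T)
        else:
            nx, ny, nz = grid.shape
            fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
            xf, yf, zf = (grid.faces[k] for k in ("x", "y", "z"))
            pts = [(x, y, z) for z in zf for y in yf for x in xf]
            _write_points(fh, pts)
            ncell = nx * ny * nz
            fh.write(f"\nCELL_DATA {ncell}\n")
            _write_scalar(fh, "mask", grid.open_.astype(float))
            if flow is not None:
                _write_scalar(fh, "pressure", flow.p)
                _write_scalar(fh, "viscosity", flow.mu)
                uc = 0.5 * (flow.u[:-1] + flow.u[1:])
                vc = 0.5 * (flow.v[:, :-1] + flow.v[:, 1:])
                wc = 0.5 * (flow.w[:, :, :-1] + flow.w[:, :, 1:])
                _write_vector(fh, "velocity", (uc, vc, wc))
            if temperature is not None:
                _write_scalar(fh, "theta", temperature.theta)
    return path
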