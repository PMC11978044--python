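"""Build the four canonical lumen geometries and inspect their grids.

Constructs the healthy and 40/60/80%-stenosed segments, prints the throat
radius and the discrete area ratio each grid resolves, and writes one VTK
file for inspection.  The area ratio (A_throat/A_inlet) is what forces the
continuity speed-up at the throat.
"""

import os

import numpy as np

from stenoflow import build_grid, make_case
from stenoflow.vtkio import write_vtk

for name in ("healthy", "s40", "s60", "s80"):
    cfg = make_case(name, resolution=(32, 128))
    grid = cfg.build_grid()
    geom = cfg.geometry
    i_th = int(np.argmin(grid.local_radius(grid.z_c)))
    A_ratio = grid.open_section_area(i_th) / grid.open_section_area(0)
    print(f"{name:8s} throat radius {geom.throat_radius*1e3:.2f} mm, "
          f"discrete area ratio {A_ratio:.3f} "
          f"(analytic {(geom.throat_radius/geom.base_radius)**2:.3f})")

os.makedirs("scratch", exist_ok=True)
path = write_vtk("scratch/s60_grid.vtk", build_grid(
    make_case("s60").geometry, (32, 128)))
print(f"wrote {path} (open in ParaView to see the masked lumen)")
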