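"""Temperature response to the Prandtl and dissipation-group sweeps.

With the flow field held fixed (one-way coupling), higher Pr thins the
thermal boundary layer at the heated wall — the wall-adjacent temperature
gradient grows — while a larger dissipation group Br heats the interior
through viscous friction.  These are the temperature-level analogues of
the study's Pr and "Brownian motion parameter" sweeps.
"""

import numpy as np

from stenoflow import DimensionlessGroups, make_case, solve_energy, \
    solve_steady
from stenoflow.energy import default_thermal_bc

cfg = make_case("s40", resolution=(24, 96))
flow, hist = solve_steady(cfg)
grid = cfg.grid
g0 = cfg.resolved_groups()
print(f"flow solved ({hist.iterations} iterations); Re = {g0.Re:.2f}")

print("\nPrandtl sweep (heated wall, Br = 0): wall theta-gradient 1/m")
for Pr in (0.7, 2.0, 5.0):
    g = DimensionlessGroups(Re=g0.Re, Pr=Pr, Br=0.0,
                            beta=g0.u0 * g0.L / (g0.Re * Pr),
                            u0=g0.u0, L=g0.L, Ti=g0.Ti, Tb=g0.Tb)
    temp = solve_energy(flow, grid, cfg.fluid, g, bc=default_thermal_bc(1.0))
    i = grid.shape[1] // 2
    mi = int(grid.open_[:, i].sum())
    d = grid.local_radius(grid.z_c[i]) - grid.r_c[mi - 1]
    grad = (1.0 - temp.theta[mi - 1, i]) / d
    print(f"  Pr = {Pr:4.1f}: {grad:10.1f}")

print("\nDissipation sweep (cold walls): peak theta from viscous heating")
for Br in (0.1, 0.5, 1.0, 2.0):
    g = DimensionlessGroups(Re=g0.Re, Pr=2.0, Br=Br,
                            beta=g0.u0 * g0.L / (g0.Re * 2.0),
                            u0=g0.u0, L=g0.L, Ti=g0.Ti, Tb=g0.Tb)
    temp = solve_energy(flow, grid, cfg.fluid, g,
                        bc={"inlet": ("dirichlet", 0.0),
                            "outlet": ("neumann", 0.0),
                            "wall": ("dirichlet", 0.0)})
    print(f"  Br = {Br:4.1f}: peak theta = {temp.theta.max():.5f}")
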