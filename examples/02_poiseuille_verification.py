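"""Verify the flow solver against Hagen-Poiseuille pipe flow.

Runs the axisymmetric solver on a straight tube with a Newtonian fluid
(lam = 0 makes the Williamson law constant) and compares the centerline
velocity and the pressure drop with the exact solution: u_max = 2U and
dp = 8 mu L U / R^2.  Errors of a fraction of a percent show the
discretization is consistent; they shrink under refinement.
"""

from stenoflow.verification import poiseuille_errors

err_u, err_dp, flow, hist = poiseuille_errors(resolution=(32, 128))
print(f"converged in {hist.iterations} outer iterations")
print(f"centerline velocity error vs 2U:      {100*err_u:.4f} %")
print(f"pressure drop error vs 8*mu*L*U/R^2:  {100*err_dp:.4f} %")
Q0 = flow.flow_rate(0)
print(f"flow rate: {Q0:.4e} m^3/s, conserved through every section to "
      f"{max(abs(flow.flow_rate(i)-Q0)/Q0 for i in range(129)):.1e} relative")
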