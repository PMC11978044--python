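# Methods

## The physical model

The package simulates steady, laminar, incompressible flow of blood through
a short arterial segment whose lumen may be narrowed by a stenosis and
whose cross-section may be elliptic, together with the temperature field
the flow carries and the heat it generates by viscous friction.

Blood is treated as a **generalized-Newtonian Williamson fluid**: the
stress is the Newtonian form with a scalar apparent viscosity that decays
from the zero-shear value `mu0` toward the infinite-shear value `mu_inf`
with a time constant `lam`,

    mu(gd) = mu_inf + (mu0 - mu_inf) / (1 + lam * gd),

where the scalar shear rate `gd` is the standard second invariant
`sqrt(1/2 gamma:gamma)` of `gamma_ij = du_i/dx_j + du_j/dx_i`.  This
rational law is what the momentum equations use.  A second, *linear* stress
form `delta_ij = eta0 (1 + Gamma*gd) gamma_ij` circulating in the Williamson
literature is provided as a separate mode in `rheology.extra_stress_tensor`;
the two forms are not algebraically consistent with each other, so their
parameter sets are kept independent and the linear form is never used by
the solver.

Momentum is solved in the dimensional variable-viscosity stress form
`div( mu(gd) (grad u + grad u^T) )`.  The axisymmetric backend carries the
transpose-stress part as an explicit deferred correction (switch
`SolverSettings.full_stress`, default on; the term vanishes identically for
constant viscosity with an incompressible field).  The 3D backend uses the
`div(mu grad u)` form only; for the Newtonian verification cases the two
coincide, and the 3D non-Newtonian runs are qualitative.

Temperature is **one-way coupled** (no temperature-dependent viscosity is
modeled): the steady dimensionless energy equation

    u . grad(theta) = 1/(Re*Pr) lap(theta) + Br/(Re*Pr) * Phi

is solved on the converged flow field, with `theta = (T-Ti)/(Tb-Ti)`.
`Phi` is the viscous-dissipation function of the discrete velocity
gradients; the default is the full second invariant (`Phi = gd^2`), and the
3D backend also offers the study's printed grouping
(`2(u_x^2+v_y^2+w_z^2) + (u_y+v_x+w_z)^2`) behind
`CaseConfig.dissipation_form = "printed"` — in the axisymmetric reduction
the two coincide.  The dissipation prefactor uses the constant viscosity
scale absorbed into `Br` (no local `mu(gd)/mu0` weighting), matching the
dimensionless formulation.  The group `Br` is implemented exactly as the
study's variable list defines it, `Br = rho*Cp*mu0*u0^2/(k*(Tb-Ti))`;
note this differs from the textbook Brinkman number `mu u0^2/(k dT)` by a
factor `rho*Cp/k` and is dimensionally heterogeneous — it only ever enters
as a dimensionless knob of the dimensionless equation, so the package
treats it as such and documents the discrepancy here.

A consequence of one-way coupling worth stating: sweeping `Pr` or `Br`
cannot change the velocity field.  The sweeps are therefore reported as
*temperature-field* responses (wall-gradient steepening with `Pr`,
interior heating with `Br`), which is what the governing equations as
printed actually admit.

## Geometry and grids

The lumen is a straight segment of base radius `R0` and length `L`; a
stenosis is a smooth C1 cosine bump in the equivalent radius,

    r(z) = R0 - (s*R0/2) (1 + cos(2 pi (z - zc)/Ls)),  |z - zc| <= Ls/2,

with fractional *diameter* reduction `s` at the throat (the canonical study
degrees are 0, 0.4, 0.6, 0.8).  The profile family is a pluggable tag; the
cosine bump is the default because it is standard in stenosis CFD and
differentiable.  Elliptic cross-sections use the **equal-area convention**:
semi-axes `a = r/sqrt(kappa)`, `b = r*sqrt(kappa)` so `pi a b = pi r^2` for
every aspect ratio `kappa`; comparisons between circular and elliptic
lumens at the same flow rate then isolate shape, not size.

Both solver modes use structured staggered grids with a binary lumen mask:

* **axisymmetric** — tensor-product `(r, z)`, axis at `r = 0`, optional
  smooth axial clustering inside the stenotic window (density factor
  `clustering`);
* **cart3d** — a uniform Cartesian box bounding the widest elliptic
  section, cells open where the ellipse containment test holds; axial
  spacing must be uniform in this mode (clustering is an axisymmetric
  feature).

A plain stair-step mask would cost first-order wall accuracy.  Instead the
no-slip wall enters every diffusion stencil through a **cut link**: when a
velocity node's neighbor is masked solid, the conductance uses the exact
geometric distance from the node to the wall (`r = R(z)` or the ellipse)
along the stencil axis, clipped to `[0.05h, 1.5h]`.  This restores
near-second-order behavior at the wall for the dominant (axial-velocity)
equations; the elliptic-duct verification error at 48x48x96 is a few
tenths of a percent.  The same cut links serve the temperature wall
condition.  At the Cartesian box boundary (tangent cells) the half-cell
distance is used.

## Discretization and the SIMPLE loop

Fully staggered arrangement (velocities on faces, pressure and theta at
centers), chosen over collocated + Rhie-Chow because it conserves mass
exactly by construction.  Convection is first-order upwind (robust at the
low Reynolds numbers of interest, Re ~ 10 on the segment length); a
central-difference deferred correction is available in the axisymmetric
mode.  Diffusion is implicit with the apparent viscosity recomputed from
the discrete shear rate every outer iteration (corner viscosities are
open-cell-weighted averages).

One outer iteration: update boundary values (the outlet copies the last
interior plane and is rescaled to the inlet flow rate), update `mu(gd)`,
solve the relaxed `u`(, `v`, `w`) momentum systems sequentially, then solve
the SIMPLE pressure-correction equation and correct velocities fully and
pressure by `relax_p`.  Because the correction system is solved accurately
(sparse direct in axisym; conjugate gradients with a symmetric reference
pin at relative tolerance 1e-9 in 3D), the post-correction divergence of
every cell is at solver precision *at every iteration* — mass conservation
is structural, not asymptotic.  Cross-section flow rates therefore match
the inlet flow rate by telescoping, which is what the conservation checks
measure (~1e-16 axisym, ~1e-9 3D).

The parabolic inlet profile is normalized so the *discrete* inlet flux
equals `U` times the discrete open inlet area; this makes the
continuity-implied throat speed-up `A_in/A_throat` an exact identity of
the solution and keeps all flux bookkeeping exact.

Residuals are Patankar-style scaled: the momentum residual is the L1 norm
of the unrelaxed equation imbalance divided by `sum |a_P u_P|`, the
continuity residual the pre-correction mass imbalance relative to the
inlet flow rate.  Defaults: `relax_u = 0.7`, `relax_p = 0.3` (0.5 for the
diffusion-dominated straight-duct verification, which it converges in ~25
iterations), `tol_momentum = 1e-6`, `tol_continuity = 1e-7`.  All solves
start from a deterministic warm start (the inlet parabola replicated
per-column at the local radius, so every column already carries the inlet
flow rate); reruns are bitwise reproducible, and a zero start is available
behind `SolverSettings.initial = "zero"`.

The governing equations are solved steady; the inertial terms carry no
time derivative, and an optional pseudo-transient diagonal augmentation
(`pseudo_transient`, `pseudo_dt`) is available as a continuation device
for stiff cases.

Inner linear solves: sparse direct (SuperLU) up to ~30k unknowns;
beyond that diagonal-preconditioned BiCGStab (momentum, rtol 1e-8) and CG
(pressure, rtol 1e-9).  The contract is the residual, not the algorithm.

## Fixture parameters (the study prints none)

No dimensional vessel size, fluid property, inlet speed, Reynolds number
or temperature is printed in the source study, so the defaults are
fixtures chosen once to be blood-like and are stamped into every output:

| quantity | default | note |
|---|---|---|
| `R0` | 2 mm | small artery |
| `L` | 20 mm | 10 radii; also the Eq.-scale length |
| `Ls`, `zc` | `L/5`, `L/2` | stenosis window |
| `rho` | 1060 kg/m^3 | blood |
| `mu0`, `mu_inf` | 0.056, 0.00345 Pa s | Williamson blood fit |
| `lam` | 3.313 s | Williamson blood fit |
| `k`, `Cp` | 0.52 W/m/K, 3617 J/kg/K | blood |
| `U` | 0.02 m/s | inlet mean speed; Re = rho U L / mu0 ≈ 7.6 |
| `Ti`, `Tb` | 310, 313 K | heated wall, `theta_wall = 1` |

Consequently the study's unit-less figure-axis numbers (velocities
"0.002 -> 0.001", cell-Reynolds "-0.25 .. 0.8") are not reproducible and
are treated as qualitative shape references; a negative cell Reynolds
number cannot arise under the definition `rho |u| Delta / mu >= 0`.  The
reference scales for derived fields are the only two the study defines:
`U_ref` = inlet mean speed and `p_ref` = outlet-plane mean pressure (so the
pressure coefficient vanishes at the outlet reference section).  The cell
size in the cell Reynolds number is the geometric mean of the local grid
spacings.

## Verification battery and what it shows

Every solver claim is checked against an independent oracle
(`stenoflow.oracles`, shared with `validate_suite` and the test suite):

* Hagen-Poiseuille (centerline 2U, `dp = 8 mu L U/R^2`) — exact Newtonian
  limit of the axisymmetric solver; errors ~0.01 % / 0.1 % at 64x256.
* Elliptic-duct Poiseuille — exact Newtonian limit of the masked-cell 3D
  solver; L_inf error ~0.3 % at 48x48x96.
* Fully developed Williamson pipe flow — 1D pointwise inversion of the
  flow curve (closed-form root of the underlying quadratic, cross-checked
  against bracketed root-finding) plus radial quadrature, with the pressure
  gradient root-found to match the flow rate; the 2D solver profile agrees
  to ~0.1 % away from the entrance.
* Plane Couette flow with dissipation — closed form
  `theta = Br eta (1-eta)/2` reproduced to <1 % by the energy solver on an
  imposed linear shear (isolates scalar transport + dissipation).
* Conservation and throat-speed-up identities on the canonical cases.
* Grid independence — the mesh-refinement procedure on the Poiseuille
  case: monotone error reduction, <1 % change between the two finest
  grids.

The problem sizes used by the default test run and the acceptance script
(24-64 radial cells, 96-256 axial, 48^2 x 96 in 3D) were chosen as the
coarsest grids at which the oracle errors sit comfortably inside their
tolerances; the grid-independence report documents the refinement behavior.

**What the synthetic cases do and do not show.**  The generator emulates
idealized, rigid, steady-flow stenosed segments with smooth symmetric
narrowings and fixture properties.  Passing tests demonstrate the solver
reproduces known laminar solutions and the qualitative severity/shape
trends under these conditions.  They do not validate against in-vivo data:
real stenoses are asymmetric and compliant, real flow is pulsatile, and
the inlet is not perfectly developed.  Turbulence, fluid-structure
interaction, pulsatile waveforms, nanoparticle transport and wall-shear
clinical indices are out of scope.

## Numerical edge cases and limitations

* Wall-distance clipping `[0.05h, 1.5h]` guards degenerate cut links when
  a cell center sits very close to the wall.
* The outlet imposes zero-gradient velocity rescaled to the inlet flow
  rate; transverse velocity at the 3D outlet is pinned to zero at the
  half-cell distance (exact for developed flow, approximate within one
  cell of the outlet otherwise).
* The throat must be resolved by at least 3 cells (radially / across the
  semi-minor axis); `build_grid` refuses otherwise.
* First-order upwinding smears steep post-stenotic gradients at coarse
  resolution; the severity trends are robust to this, the exact
  recirculation-zone extent is not.
* Pressure is defined up to a constant (pinned in the correction solve and
  reported relative to the outlet-plane mean).
* The 3D mode requires uniform axial spacing and upwind convection.
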