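"""Masked-cell Cartesian 3D staggered finite-volume backend.

Arrays are indexed [ix, iy, iz] with z the axial direction; u, v, w sit on
x-, y-, z-faces.  Cells outside the (possibly stenosed) elliptic lumen are
masked solid; the no-slip wall enters the lateral diffusion stencils through
cut links using the exact distance from the velocity node to the ellipse
x^2/a(z)^2 + y^2/b(z)^2 = 1 along the stencil axis.

The three momentum equations share one assembly routine: each component's
arrays are transposed so its staggered axis is the local last axis, which
makes the stencil bookkeeping identical for u, v and w.  The 3D solver uses
the div(mu grad u) diffusion form and first-order upwind convection; z
spacing must be uniform in this mode.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .rheology import williamson_viscosity

_DCLIP = (0.05, 1.5)

# local-frame permutations: component -> axes order moving its staggered
# axis last; _PERM_INV undoes it
_PERM = {"u": (1, 2, 0), "v": (2, 0, 1), "w": (0, 1, 2)}
_PERM_INV = {"u": (2, 0, 1), "v": (1, 2, 0), "w": (0, 1, 2)}
# global axis of each local axis, per component: local (xi, eta, zeta)
_GAX = {"u": (1, 2, 0), "v": (2, 0, 1), "w": (0, 1, 2)}


class _Work:
    def __init__(self, grid):
        g = grid
        self.nx, self.ny, self.nz = g.shape
        self.x_f, self.y_f, self.z_f = (g.faces[k] for k in ("x", "y", "z"))
        self.x_c, self.y_c, self.z_c = (g.centers[k] for k in ("x", "y", "z"))
        self.dx = float(g.spacings["x"])
        self.dy = float(g.spacings["y"])
        dz = np.asarray(g.spacings["z"], dtype=float)
        if not np.allclose(dz, dz[0]):
            raise ValueError("cart3d mode requires uniform axial spacing")
        self.dzc = float(dz[0])
        self.h = {"x": self.dx, "y": self.dy, "z": self.dzc}
        self.open = g.open_
        self.a_c, self.b_c = g.section_semi_axes(self.z_c)
        self.a_f, self.b_f = g.section_semi_axes(self.z_f)

        nx, ny, nz = self.nx, self.ny, self.nz
        act_u = np.zeros((nx + 1, ny, nz), bool)
        act_u[1:nx] = self.open[:-1] & self.open[1:]
        act_v = np.zeros((nx, ny + 1, nz), bool)
        act_v[:, 1:ny] = self.open[:, :-1] & self.open[:, 1:]
        act_w = np.zeros((nx, ny, nz + 1), bool)
        act_w[:, :, 1:nz] = self.open[:, :, :-1] & self.open[:, :, 1:]
        self.act = {"u": act_u, "v": act_v, "w": act_w}

        self.ipm = -np.ones(self.open.shape, np.int64)
        self.ncell = int(self.open.sum())
        self.ipm[self.open] = np.arange(self.ncell)
        self.Jp = np.nonzero(self.open)
        ii = np.nonzero(self.open[:, :, nz - 1])
        self.pin = int(self.ipm[ii[0][0], ii[1][0], nz - 1])

        self.idx = {}
        for c in ("u", "v", "w"):
            m = -np.ones(self.act[c].shape, np.int64)
            m[self.act[c]] = np.arange(int(self.act[c].sum()))
            self.idx[c] = m
        self._pc_ilu = None
        self._pc_count = 0


def _work(grid) -> "_Work":
    w = getattr(grid, "_c3_work", None)
    if w is None:
        w = _Work(grid)
        grid._c3_work = w
    return w


# --------------------------------------------------------------------- #
# fields and boundary conditions

def inlet_profile(grid, U):
    """Elliptic-paraboloid inlet axial velocity, discrete-flux-normalized."""
    w = _work(grid)
    a0, b0 = grid.section_semi_axes(0.0)
    s = 1.0 - (w.x_c[:, None] / a0) ** 2 - (w.y_c[None, :] / b0) ** 2
    s = np.maximum(s, 0.0) * grid.open_[:, :, 0]
    q = s.sum()
    return s * (U * grid.open_[:, :, 0].sum() / q)


def make_field(grid, props, U, settings):
    from .flow import FlowField

    w = _work(grid)
    u = np.zeros((w.nx + 1, w.ny, w.nz))
    v = np.zeros((w.nx, w.ny + 1, w.nz))
    wv = np.zeros((w.nx, w.ny, w.nz + 1))
    p = np.zeros((w.nx, w.ny, w.nz))
    wv[:, :, 0] = inlet_profile(grid, U)
    if settings.initial == "profile":
        Q = wv[:, :, 0].sum()
        for k in range(1, w.nz + 1):
            kc = min(k, w.nz - 1)
            a, b = w.a_f[k], w.b_f[k]
            s = 1.0 - (w.x_c[:, None] / a) ** 2 - (w.y_c[None, :] / b) ** 2
            op = grid.open_[:, :, kc] if k == w.nz else (
                grid.open_[:, :, k - 1] & grid.open_[:, :, kc])
            s = np.maximum(s, 0.0) * op
            qs = s.sum()
            if qs > 0:
                wv[:, :, k] = s * (Q / qs)
    mu = np.full((w.nx, w.ny, w.nz), props.mu0)
    fld = FlowField(grid=grid, inlet_speed=U, u=u, v=v, w=wv, p=p, mu=mu)
    apply_bcs(fld, grid, U)
    return fld


def apply_bcs(field, grid, U):
    w = _work(grid)
    field.w[:, :, 0] = inlet_profile(grid, U)
    field.u[~w.act["u"]] = 0.0
    field.v[~w.act["v"]] = 0.0
    field.w[:, :, 1:w.nz][~w.act["w"][:, :, 1:w.nz]] = 0.0
    Q_in = float(field.w[:, :, 0].sum())
    out = field.w[:, :, w.nz - 1] * grid.open_[:, :, w.nz - 1]
    q = float(out.sum())
    if q > 1e-30 * max(Q_in, 1.0):
        field.w[:, :, w.nz] = out * (Q_in / q)
    else:
        field.w[:, :, w.nz] = field.w[:, :, 0]
    field.inlet_speed = U
    return field


# --------------------------------------------------------------------- #
# mask-aware gradients, shear rate, dissipation

def _masked_gradient(fc, open_, axis, h):
    """d(fc)/dx_axis at cell centers: central where both neighbors open,
    one-sided toward the open side at mask edges, zero in closed cells."""
    op = open_.astype(float)
    fp = np.roll(fc * op, -1, axis=axis)
    fm = np.roll(fc * op, 1, axis=axis)
    opp = np.roll(op, -1, axis=axis)
    opm = np.roll(op, 1, axis=axis)
    # kill wrap-around
    sl_lo = [slice(None)] * fc.ndim
    sl_lo[axis] = 0
    sl_hi = [slice(None)] * fc.ndim
    sl_hi[axis] = -1
    opm[tuple(sl_lo)] = 0.0
    fm[tuple(sl_lo)] = 0.0
    opp[tuple(sl_hi)] = 0.0
    fp[tuple(sl_hi)] = 0.0
    both = (opp > 0) & (opm > 0)
    grad = np.zeros_like(fc)
    grad[both] = (fp[both] - fm[both]) / (2.0 * h)
    onlyp = (opp > 0) & (opm == 0)
    grad[onlyp] = (fp[onlyp] - fc[onlyp]) / h
    onlym = (opm > 0) & (opp == 0)
    grad[onlym] = (fc[onlym] - fm[onlym]) / h
    return grad * open_


def velocity_gradients(field, grid):
    w = _work(grid)
    op = grid.open_
    uc = 0.5 * (field.u[:-1] + field.u[1:]) * op
    vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:]) * op
    wc = 0.5 * (field.w[:, :, :-1] + field.w[:, :, 1:]) * op
    dudx = (field.u[1:] - field.u[:-1]) / w.dx * op
    dvdy = (field.v[:, 1:] - field.v[:, :-1]) / w.dy * op
    dwdz = (field.w[:, :, 1:] - field.w[:, :, :-1]) / w.dzc * op
    dudy = _masked_gradient(uc, op, 1, w.dy)
    dudz = _masked_gradient(uc, op, 2, w.dzc)
    dvdx = _masked_gradient(vc, op, 0, w.dx)
    dvdz = _masked_gradient(vc, op, 2, w.dzc)
    dwdx = _masked_gradient(wc, op, 0, w.dx)
    dwdy = _masked_gradient(wc, op, 1, w.dy)
    return dudx, dudy, dudz, dvdx, dvdy, dvdz, dwdx, dwdy, dwdz


def shear_rate_field(field, grid):
    (dudx, dudy, dudz, dvdx, dvdy, dvdz,
     dwdx, dwdy, dwdz) = velocity_gradients(field, grid)
    return np.sqrt(
        2.0 * (dudx**2 + dvdy**2 + dwdz**2)
        + (dudy + dvdx) ** 2 + (dudz + dwdx) ** 2 + (dvdz + dwdy) ** 2
    )


def dissipation_field(field, grid, form="standard"):
    """Viscous dissipation Phi [1/s^2]: 'standard' = gamma_dot^2, 'printed'
    follows the study's grouping 2*(du/dx^2+dv/dy^2+dw/dz^2)
    + (du/dy + dv/dx + dw/dz)^2."""
    if form == "standard":
        return shear_rate_field(field, grid) ** 2
    (dudx, dudy, dudz, dvdx, dvdy, dvdz,
     dwdx, dwdy, dwdz) = velocity_gradients(field, grid)
    return (2.0 * (dudx**2 + dvdy**2 + dwdz**2)
            + (dudy + dvdx + dwdz) ** 2)


def update_viscosity(field, grid, props):
    gd = shear_rate_field(field, grid)
    field.mu = np.where(grid.open_, williamson_viscosity(gd, props), props.mu0)
    return field.mu


# --------------------------------------------------------------------- #
# wall distances

def _wall_distance(w: _Work, comp: str, gax: int, XI, YI, ZI, hloc: float):
    """Distance from component nodes (local-frame indices) to the ellipse
    wall along global axis gax (0=x, 1=y); z (gax=2) falls back to h/2."""
    if gax == 2:
        return np.full(XI.shape, 0.5 * hloc)
    # node global coordinates
    p = _GAX[comp]  # local axis -> global axis
    loc_idx = (XI, YI, ZI)
    gidx = [None, None, None]
    for la, ga in enumerate(p):
        gidx[ga] = loc_idx[la]
    stag = p[2]
    coords = []
    for ga, arr in enumerate(gidx):
        if ga == stag:
            c = (w.x_f, w.y_f, w.z_f)[ga][arr]
        else:
            c = (w.x_c, w.y_c, w.z_c)[ga][arr]
        coords.append(c)
    xg, yg, zg = coords
    if stag == 2:
        a = np.interp(zg, w.z_f, w.a_f)
        b = np.interp(zg, w.z_f, w.b_f)
    else:
        a = np.interp(zg, w.z_c, w.a_c)
        b = np.interp(zg, w.z_c, w.b_c)
    if gax == 0:
        s = np.sqrt(np.maximum(1.0 - (yg / b) ** 2, 0.0))
        d = a * s - np.abs(xg)
    else:
        s = np.sqrt(np.maximum(1.0 - (xg / a) ** 2, 0.0))
        d = b * s - np.abs(yg)
    return np.clip(d, _DCLIP[0] * hloc, _DCLIP[1] * hloc)


# --------------------------------------------------------------------- #
# momentum: one generic component solve in the transposed local frame

def _avg4(mu_t, open_t, I0, I1, I2, d_axis):
    """Open-weighted viscosity average over the 4 cells around a lateral
    edge: cells (zeta-1, zeta) x (d, d+1) in local-frame cell indices."""
    n0, n1, n2 = mu_t.shape
    num = np.zeros(I0.shape)
    den = np.zeros(I0.shape)
    for dz_ in (-1, 0):
        for dd in (0, 1):
            a0 = I0 + (dd if d_axis == 0 else 0)
            a1 = I1 + (dd if d_axis == 1 else 0)
            a2 = I2 + dz_
            ok = ((a0 >= 0) & (a0 < n0) & (a1 >= 0) & (a1 < n1)
                  & (a2 >= 0) & (a2 < n2))
            a0c, a1c, a2c = (np.clip(a0, 0, n0 - 1), np.clip(a1, 0, n1 - 1),
                             np.clip(a2, 0, n2 - 1))
            opn = open_t[a0c, a1c, a2c] & ok
            num += mu_t[a0c, a1c, a2c] * opn
            den += opn
    return num, den


def _solve_component(comp, field, grid, props, settings):
    w = _work(grid)
    perm = _PERM[comp]
    gax = _GAX[comp]                     # local (xi, eta, zeta) -> global
    h = [w.h["xyz"[g]] for g in gax]     # local spacings
    hx, he, hz = h
    A = (he * hz, hx * hz, hx * he)      # face areas per local axis
    rho = props.density

    arr_g = {"u": field.u, "v": field.v, "w": field.w}
    C = np.transpose(arr_g[comp], perm)
    comp_of_gax = {0: "u", 1: "v", 2: "w"}
    Vxi = np.transpose(arr_g[comp_of_gax[gax[0]]], perm)
    Vet = np.transpose(arr_g[comp_of_gax[gax[1]]], perm)
    mu_t = np.transpose(field.mu, perm)
    open_t = np.transpose(grid.open_, perm)
    p_t = np.transpose(field.p, perm)
    act = np.transpose(w.act[comp], perm)
    # index map must follow the local-frame enumeration order
    idx = -np.ones(act.shape, np.int64)
    idx[act] = np.arange(int(act.sum()))

    I0, I1, I2 = np.nonzero(act)
    n = len(I0)
    if n == 0:
        return 0.0, 1.0, np.zeros_like(C)
    cP = C[I0, I1, I2]

    n0, n1, n2 = C.shape

    def getC(d0, d1, d2):
        a0, a1, a2 = I0 + d0, I1 + d1, I2 + d2
        ok = ((a0 >= 0) & (a0 < n0) & (a1 >= 0) & (a1 < n1)
              & (a2 >= 0) & (a2 < n2))
        a0c = np.clip(a0, 0, n0 - 1)
        a1c = np.clip(a1, 0, n1 - 1)
        a2c = np.clip(a2, 0, n2 - 1)
        val = np.where(ok, C[a0c, a1c, a2c], 0.0)
        activ = np.where(ok, act[a0c, a1c, a2c], False)
        ind = np.where(ok & activ, idx[a0c, a1c, a2c], -1)
        return val, ind, ok

    def lat_flux(V_lat, d_axis, sign):
        # flux through the lateral CV face in +/- local direction d_axis
        sh = [0, 0, 0]
        sh[d_axis] = 1 if sign > 0 else 0
        a0 = I0 + sh[0]
        a1 = I1 + sh[1]
        a2 = I2 + sh[2]
        b0, b1, b2 = a0.copy(), a1.copy(), a2.copy()
        b2 = b2 - 1  # minus e_zeta (cell below the face)
        m0, m1, m2 = V_lat.shape
        va = V_lat[np.clip(a0, 0, m0 - 1), np.clip(a1, 0, m1 - 1),
                   np.clip(a2, 0, m2 - 1)]
        oka = (a0 < m0) & (a1 < m1) & (a2 >= 0) & (a2 < m2)
        vb = V_lat[np.clip(b0, 0, m0 - 1), np.clip(b1, 0, m1 - 1),
                   np.clip(b2, 0, m2 - 1)]
        okb = (b0 < m0) & (b1 < m1) & (b2 >= 0) & (b2 < m2)
        return A[d_axis] * 0.5 * (np.where(oka, va, 0.0)
                                  + np.where(okb, vb, 0.0))

    # convective volumetric fluxes through the 6 CV faces
    Fz_p = A[2] * 0.5 * (cP + getC(0, 0, 1)[0])
    Fz_m = A[2] * 0.5 * (getC(0, 0, -1)[0] + cP)
    Fx_p = lat_flux(Vxi, 0, +1)
    Fx_m = lat_flux(Vxi, 0, -1)
    Fe_p = lat_flux(Vet, 1, +1)
    Fe_m = lat_flux(Vet, 1, -1)

    # viscosity at CV faces
    mz0, mz1, mz2 = mu_t.shape
    mu_zp = mu_t[np.clip(I0, 0, mz0 - 1), np.clip(I1, 0, mz1 - 1),
                 np.clip(I2, 0, mz2 - 1)]
    mu_zm = mu_t[np.clip(I0, 0, mz0 - 1), np.clip(I1, 0, mz1 - 1),
                 np.clip(I2 - 1, 0, mz2 - 1)]

    entries_rows = [np.arange(n)]
    entries_cols = [np.arange(n)]
    entries_vals = [np.zeros(n)]  # diagonal filled later
    b0 = A[2] * (p_t[I0, I1, np.clip(I2 - 1, 0, mz2 - 1)]
                 - p_t[I0, I1, np.clip(I2, 0, mz2 - 1)])
    b = b0.copy()
    aP0 = np.zeros(n)
    dF = rho * (Fz_p - Fz_m + Fx_p - Fx_m + Fe_p - Fe_m)

    specs = [
        # (offset, F_signed_out, area, local axis)
        ((0, 0, 1), Fz_p, A[2], 2, +1),
        ((0, 0, -1), -Fz_m, A[2], 2, -1),
        ((1, 0, 0), Fx_p, A[0], 0, +1),
        ((-1, 0, 0), -Fx_m, A[0], 0, -1),
        ((0, 1, 0), Fe_p, A[1], 1, +1),
        ((0, -1, 0), -Fe_m, A[1], 1, -1),
    ]
    sum_anb_times_nb = np.zeros(n)
    for off, F_out, Af, lax, sgn in specs:
        val, ind, inb = getC(*off)
        if lax == 2:
            mu_f = mu_zp if sgn > 0 else mu_zm
            dist = np.full(n, hz)
        else:
            num, den = _avg4(mu_t, open_t, I0 + min(off[0], 0),
                             I1 + min(off[1], 0), I2, lax)
            mu_f = np.where(den > 0, num / np.maximum(den, 1.0), props.mu0)
            hl = hx if lax == 0 else he
            need_cut = ~(ind >= 0)
            dist = np.full(n, hl)
            if need_cut.any():
                dcut = _wall_distance(
                    w, comp, gax[lax], I0[need_cut], I1[need_cut],
                    I2[need_cut], hl)
                dist[need_cut] = dcut
        D = mu_f * Af / dist
        a_nb = D + np.maximum(-rho * F_out, 0.0)
        aP0 += a_nb
        active = ind >= 0
        entries_rows.append(np.nonzero(active)[0])
        entries_cols.append(ind[active])
        entries_vals.append(-a_nb[active])
        b[~active] += (a_nb * val)[~active]
        sum_anb_times_nb += a_nb * val

    aP0 += dF
    if settings.pseudo_transient:
        tr = rho * hx * he * hz / settings.pseudo_dt
        aP0 += tr
        b += tr * cP
        b0 += tr * cP

    # residual of the unrelaxed equation at the incoming state; b0 excludes
    # the known-neighbor contributions already counted in sum_anb_times_nb
    resid = float(np.abs(aP0 * cP - sum_anb_times_nb - b0).sum())
    scale = float(np.abs(aP0 * cP).sum())

    alpha = settings.relax_u
    aP = aP0 / alpha
    b = b + (1.0 - alpha) * aP * cP
    entries_vals[0] = aP

    Am = sp.coo_matrix(
        (np.concatenate(entries_vals),
         (np.concatenate(entries_rows), np.concatenate(entries_cols))),
        shape=(n, n)).tocsr()
    if n <= 4000:
        x = spla.spsolve(Am, b)
    else:
        # inner momentum solves can be moderately tight: the SIMPLE outer
        # loop only needs the fixed point to satisfy the discrete momentum
        # equations to the outer tolerance
        M = sp.diags(1.0 / Am.diagonal())
        x, info = spla.bicgstab(Am, b, x0=cP, M=M, rtol=1e-8,
                                atol=0.0, maxiter=400)
        if info != 0:
            x = spla.gmres(Am, b, x0=cP, M=M, rtol=1e-8, atol=0.0,
                           restart=60, maxiter=200)[0]

    C[act] = x
    arr_g[comp][...] = np.transpose(C, _PERM_INV[comp])

    d_map = np.zeros_like(C)
    d_map[act] = A[2] / aP
    return resid, scale, np.transpose(d_map, _PERM_INV[comp])


# --------------------------------------------------------------------- #
# pressure correction

def divergence(field, grid):
    w = _work(grid)
    div = (w.dy * w.dzc * (field.u[1:] - field.u[:-1])
           + w.dx * w.dzc * (field.v[:, 1:] - field.v[:, :-1])
           + w.dx * w.dy * (field.w[:, :, 1:] - field.w[:, :, :-1]))
    return np.where(w.open, div, 0.0)


def pressure_correction(field, grid, props, settings, d_maps):
    w = _work(grid)
    du, dv, dw = d_maps
    div = divergence(field, grid)
    resid = float(np.abs(div[w.open]).sum())

    IX, IY, IZ = w.Jp
    n = w.ncell
    A_x, A_y, A_z = w.dy * w.dzc, w.dx * w.dzc, w.dx * w.dy
    cXp = A_x * du[IX + 1, IY, IZ]
    cXm = A_x * du[IX, IY, IZ]
    cYp = A_y * dv[IX, IY + 1, IZ]
    cYm = A_y * dv[IX, IY, IZ]
    cZp = A_z * dw[IX, IY, np.clip(IZ + 1, 0, w.nz)]
    cZm = A_z * dw[IX, IY, IZ]
    aP = cXp + cXm + cYp + cYm + cZp + cZm
    b = -div[w.open]

    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [aP]
    nx, ny, nz = w.nx, w.ny, w.nz
    for c_nb, ox, oy, oz in (
        (cXp, 1, 0, 0), (cXm, -1, 0, 0),
        (cYp, 0, 1, 0), (cYm, 0, -1, 0),
        (cZp, 0, 0, 1), (cZm, 0, 0, -1),
    ):
        a0, a1, a2 = IX + ox, IY + oy, IZ + oz
        ok = ((a0 >= 0) & (a0 < nx) & (a1 >= 0) & (a1 < ny)
              & (a2 >= 0) & (a2 < nz))
        col = np.where(
            ok,
            w.ipm[np.clip(a0, 0, nx - 1), np.clip(a1, 0, ny - 1),
                  np.clip(a2, 0, nz - 1)],
            -1)
        take = (col >= 0) & (c_nb != 0.0)
        rows.append(np.nonzero(take)[0])
        cols.append(col[take])
        vals.append(-c_nb[take])

    # symmetric pin: drop every entry in the pinned row/column (p'_pin = 0
    # is exact since the rhs is compatible), unit diagonal there
    rows_a = np.concatenate(rows)
    cols_a = np.concatenate(cols)
    vals_a = np.concatenate(vals)
    keep = ~((rows_a == w.pin) | (cols_a == w.pin))
    rows_a, cols_a, vals_a = rows_a[keep], cols_a[keep], vals_a[keep]
    rows_a = np.append(rows_a, w.pin)
    cols_a = np.append(cols_a, w.pin)
    vals_a = np.append(vals_a, 1.0)
    Am = sp.coo_matrix((vals_a, (rows_a, cols_a)), shape=(n, n)).tocsr()
    b = b.copy()
    b[w.pin] = 0.0

    if n <= 4000:
        pc = spla.spsolve(Am, b)
    else:
        # SPD Poisson-type system: diagonal-preconditioned CG at tight
        # tolerance keeps the post-correction divergence at solver precision
        M = sp.diags(1.0 / Am.diagonal())
        pc, info = spla.cg(Am, b, M=M, rtol=1e-9, atol=0.0, maxiter=3000)
        if info != 0:
            pc = spla.spsolve(Am, b)

    pg = np.zeros((w.nx, w.ny, w.nz))
    pg[w.open] = pc

    au = w.act["u"]
    ju = np.nonzero(au)
    field.u[au] += du[au] * (pg[ju[0] - 1, ju[1], ju[2]]
                             - pg[ju[0], ju[1], ju[2]])
    av = w.act["v"]
    jv = np.nonzero(av)
    field.v[av] += dv[av] * (pg[jv[0], jv[1] - 1, jv[2]]
                             - pg[jv[0], jv[1], jv[2]])
    aw = w.act["w"]
    jw = np.nonzero(aw)
    field.w[aw] += dw[aw] * (pg[jw[0], jw[1], jw[2] - 1]
                             - pg[jw[0], jw[1], jw[2]])
    field.p[w.open] += settings.relax_p * pc
    return resid


def iterate(field, grid, props, settings):
    if settings.advection != "upwind":
        raise NotImplementedError(
            "cart3d mode supports upwind convection only")
    w = _work(grid)
    apply_bcs(field, grid, field.inlet_speed)
    update_viscosity(field, grid, props)

    res_u, sc_u, du = _solve_component("u", field, grid, props, settings)
    res_v, sc_v, dv = _solve_component("v", field, grid, props, settings)
    res_w, sc_w, dw = _solve_component("w", field, grid, props, settings)
    res_c = pressure_correction(field, grid, props, settings, (du, dv, dw))

    Q_in = float(field.w[:, :, 0].sum()) * w.dx * w.dy
    # scaled residuals: momentum relative to sum |a_P u_P| over components
    return {
        "momentum": (res_u + res_v + res_w)
        / (sc_u + sc_v + sc_w + 1e-300),
        "continuity": res_c / (Q_in / (w.dx * w.dy) + 1e-300),
    }


# --------------------------------------------------------------------- #
# scalar transport (energy)

def solve_scalar(field, grid, D, bc, source=None):
    """Steady upwind advection-diffusion for a cell-centered scalar on the
    masked Cartesian grid.  ``bc`` keys: inlet, outlet (z ends) and wall
    (lateral; overridable per axis with wall_x / wall_y), each
    ("dirichlet", value) or ("neumann", 0.0)."""
    w = _work(grid)
    IX, IY, IZ = w.Jp
    n = w.ncell
    A_x, A_y, A_z = w.dy * w.dzc, w.dx * w.dzc, w.dx * w.dy

    kind_in, val_in = bc.get("inlet", ("dirichlet", 0.0))
    kind_out, val_out = bc.get("outlet", ("neumann", 0.0))
    wall_default = bc.get("wall", ("dirichlet", 1.0))
    kind_wx, val_wx = bc.get("wall_x", wall_default)
    kind_wy, val_wy = bc.get("wall_y", wall_default)
    kind_wz, val_wz = bc.get("wall_z", wall_default)  # stenosis shoulders

    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = []
    b = np.zeros(n)
    if source is not None:
        b += source[w.open]
    aP = np.zeros(n)

    F = {
        (0, +1): A_x * field.u[IX + 1, IY, IZ],
        (0, -1): -A_x * field.u[IX, IY, IZ],
        (1, +1): A_y * field.v[IX, IY + 1, IZ],
        (1, -1): -A_y * field.v[IX, IY, IZ],
        (2, +1): A_z * field.w[IX, IY, IZ + 1],
        (2, -1): -A_z * field.w[IX, IY, IZ],
    }
    nx, ny, nz = w.nx, w.ny, w.nz
    hs = (w.dx, w.dy, w.dzc)
    As = (A_x, A_y, A_z)
    dF = np.zeros(n)
    for key, Fo in F.items():
        dF += Fo

    for ax, sgn in F:
        off = [0, 0, 0]
        off[ax] = sgn
        a0, a1, a2 = IX + off[0], IY + off[1], IZ + off[2]
        inb = ((a0 >= 0) & (a0 < nx) & (a1 >= 0) & (a1 < ny)
               & (a2 >= 0) & (a2 < nz))
        col = np.where(
            inb,
            w.ipm[np.clip(a0, 0, nx - 1), np.clip(a1, 0, ny - 1),
                  np.clip(a2, 0, nz - 1)],
            -1)
        is_open_nb = col >= 0
        F_out = F[(ax, sgn)]
        hl = hs[ax]
        Df = D * As[ax] / hl

        if ax == 2:
            at_in = (IZ == 0) & (sgn < 0)
            at_out = (IZ == nz - 1) & (sgn > 0)
            kind_b = np.where(at_in, 0, np.where(at_out, 1, 2))
            # boundary distances are half-cell at z ends
            Db = D * As[ax] / (0.5 * hl)
            a_nb = np.where(is_open_nb, Df + np.maximum(-F_out, 0.0), 0.0)
            bval = np.zeros(n)
            bcoef = np.zeros(n)
            for mask, kind, val in (
                (at_in, kind_in, val_in), (at_out, kind_out, val_out),
                ((~is_open_nb) & ~at_in & ~at_out, kind_wz, val_wz),
            ):
                if kind == "dirichlet":
                    coef = np.where(mask, Db + np.maximum(-F_out, 0.0), 0.0)
                else:
                    coef = np.zeros(n)
                bcoef += coef
                bval += coef * val
            a_tot = a_nb + bcoef
        else:
            kind_w, val_w = (kind_wx, val_wx) if ax == 0 else (kind_wy, val_wy)
            a_nb = np.where(is_open_nb, Df + np.maximum(-F_out, 0.0), 0.0)
            if kind_w == "dirichlet":
                # masked-interior neighbors use the geometric ellipse
                # distance; box-boundary neighbors the half-cell distance
                need = (~is_open_nb) & inb
                dist = np.full(n, 0.5 * hl)
                if need.any():
                    xg = w.x_c[IX[need]]
                    yg = w.y_c[IY[need]]
                    a_ = w.a_c[IZ[need]]
                    b_ = w.b_c[IZ[need]]
                    if ax == 0:
                        s = np.sqrt(np.maximum(1 - (yg / b_) ** 2, 0.0))
                        dd = a_ * s - np.abs(xg)
                    else:
                        s = np.sqrt(np.maximum(1 - (xg / a_) ** 2, 0.0))
                        dd = b_ * s - np.abs(yg)
                    dist[need] = np.clip(dd, _DCLIP[0] * hl, _DCLIP[1] * hl)
                bcoef = np.where(~is_open_nb, D * As[ax] / dist, 0.0)
                bval = bcoef * val_w
            else:
                bcoef = np.zeros(n)
                bval = np.zeros(n)
            a_tot = a_nb + bcoef

        aP += a_tot
        take = is_open_nb
        rows.append(np.nonzero(take)[0])
        cols.append(col[take])
        vals.append(-a_nb[take])
        b += bval

    aP += np.maximum(dF, 0.0)
    vals = [aP] + vals

    Am = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    if n <= 60000:
        x = spla.spsolve(Am, b)
    else:
        M = sp.diags(1.0 / Am.diagonal())
        x, info = spla.bicgstab(Am, b, M=M, rtol=1e-12, atol=1e-300,
                                maxiter=5000)
        if info != 0:
            x = spla.spsolve(Am, b)
    out = np.zeros((w.nx, w.ny, w.nz))
    out[w.open] = x
    return out
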