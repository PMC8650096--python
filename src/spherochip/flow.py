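"""Steady Stokes–Brinkman flow through the unit cell.

The momentum balance solved in every non-solid voxel is

    0 = -grad(p) + mu * lap(u) - (mu / kappa) * u,

i.e. creeping (Stokes) flow with a Brinkman drag restricted to the porous
spheroid, where the Darcy permeability ``kappa`` follows from the spheroid
porosity via the Kozeny–Carman relation.  At the flow rates and length
scales of these chips the Reynolds number is ~1e-2, so the inertial terms
of the full momentum equation are negligible; dropping them makes the
problem linear, which the test suite exploits (scaling both inlet rates by
``alpha`` scales the whole field by ``alpha``).

Discretization: marker-and-cell (MAC) staggered finite volumes on the
isotropic voxel grid.  Velocity components live on cell faces, pressure at
cell centres.  Solid walls are enforced exactly: normal velocities on
fluid/solid faces are zero and tangential components see a ghost value
reflected across the wall (second-order no-slip).  Inlet faces carry the
fully developed rectangular-duct profile scaled to the prescribed flow
rate; channel outlets are held at the reference pressure with a
zero-gradient velocity condition.  The coupled velocity/pressure
saddle-point system is solved with a sparse direct factorization, so the
residual drop criterion (four orders of magnitude) is met by construction
and verified a posteriori.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .analytic import duct_profile
from .geometry import UM, DomainGrid, Region

#: m^3/s per ml/h.
ML_PER_H = 1e-6 / 3600.0


class FlowConvergenceError(RuntimeError):
    """The linear solve failed to reach the residual tolerance."""

    def __init__(self, msg: str, residual_history: list[float]):
        super().__init__(msg)
        self.residual_history = residual_history


class TopologyError(ValueError):
    """No open path connects an inlet to an outlet."""


@dataclass(frozen=True)
class FluidProperties:
    """Aqueous culture medium; the body force is identically zero."""

    density: float = 1000.0            # kg/m^3
    dynamic_viscosity: float = 1.0e-3  # Pa s
    body_force: float = 0.0            # N/m^3, fixed 0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")
        if self.body_force != 0.0:
            raise ValueError("the model assumes zero body force")


def permeability_from_porosity(porosity: float, grain_d_um: float = 15.0) -> float:
    """Kozeny–Carman permeability (m^2) of the cellular matrix.

    ``kappa = d^2 eps^3 / (180 (1 - eps)^2)`` with grain diameter ``d`` the
    typical cell size.  Strictly increasing in porosity.
    """
    if not (0.0 < porosity < 1.0):
        raise ValueError("porosity must lie strictly in (0, 1)")
    if grain_d_um <= 0:
        raise ValueError("grain diameter must be positive")
    d = grain_d_um * UM
    return d * d * porosity**3 / (180.0 * (1.0 - porosity) ** 2)


@dataclass(frozen=True)
class SpheroidProperties:
    """Porous-matrix properties of the spheroid; no internal mass source."""

    GRAIN_D_UM = 15.0  # typical epithelial cell diameter

    porosity: float = 0.5
    cell_grain_diameter_um: float = GRAIN_D_UM
    mass_source: float = 0.0  # kg/m^3/s, fixed 0

    @property
    def permeability(self) -> float:
        return permeability_from_porosity(self.porosity, self.cell_grain_diameter_um)


@dataclass(frozen=True)
class FlowBC:
    """Volumetric inlet flow rates; outlets are at the reference pressure."""

    q1_ml_h: float = 0.0   # left supply channel (absent in SSC devices)
    q2_ml_h: float = 0.0   # right supply channel
    outlet_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.q1_ml_h < 0 or self.q2_ml_h < 0:
            raise ValueError("flow rates must be non-negative")

    @property
    def q1_m3_s(self) -> float:
        return self.q1_ml_h * ML_PER_H

    @property
    def q2_m3_s(self) -> float:
        return self.q2_ml_h * ML_PER_H


# face type codes
_UNKNOWN, _DIRICHLET, _WALL, _REFLECT, _OUTLET, _NEUMANN = 0, 1, 2, 3, 4, 5


@dataclass
class FlowField:
    """Converged staggered velocity field and cell pressures (SI units)."""

    grid: DomainGrid
    u: np.ndarray          # (nx+1, ny, nz) x-face velocities, m/s
    v: np.ndarray          # (nx, ny+1, nz)
    w: np.ndarray          # (nx, ny, nz+1)
    p: np.ndarray          # (nx, ny, nz) cell pressures, Pa (0 in solid)
    residual: float = 0.0
    residual_history: list[float] = field(default_factory=list)

    def cell_velocity(self) -> np.ndarray:
        """Cell-centred velocity vectors, shape (nx, ny, nz, 3)."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        out = np.stack([uc, vc, wc], axis=-1)
        out[self.grid.solid] = 0.0
        return out

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.cell_velocity(), axis=-1)

    def divergence(self) -> np.ndarray:
        """Discrete divergence (1/s) in every cell; ~0 in fluid cells."""
        h = self.grid.spacing_m
        div = ((self.u[1:] - self.u[:-1])
               + (self.v[:, 1:] - self.v[:, :-1])
               + (self.w[:, :, 1:] - self.w[:, :, :-1])) / h
        div[self.grid.solid] = 0.0
        return div

    def flow_rate_x(self, i: int) -> float:
        """Net volumetric flux (m^3/s) through the x-face plane ``i``."""
        h = self.grid.spacing_m
        return float(self.u[i].sum()) * h * h


def _inlet_channels(grid: DomainGrid, bc: FlowBC) -> list[tuple[Region, float]]:
    out = []
    for region, q in ((Region.CHANNEL_L, bc.q1_m3_s), (Region.CHANNEL_R, bc.q2_m3_s)):
        if np.any(grid.labels[0] == region):
            out.append((region, q))
    return out


def _inlet_values(grid: DomainGrid, region: Region, q_m3_s: float) -> np.ndarray:
    """Duct-profile x-velocities (m/s) on the inlet faces of one channel.

    The analytic profile is sampled at face centres and renormalized so the
    *discrete* flux equals the prescribed flow rate exactly.
    """
    mask = grid.labels[0] == region
    js, ks = np.nonzero(mask)
    h = grid.spacing_um
    y0 = js.min() * h
    z0 = ks.min() * h
    width = (js.max() + 1) * h - y0
    height = (ks.max() + 1) * h - z0
    y = (js + 0.5) * h - y0
    z = (ks + 0.5) * h - z0
    shape = duct_profile(y, z, width, height)
    vals = np.zeros(mask.shape)
    area = (grid.spacing_m) ** 2
    total = shape.sum() * area
    if total > 0 and q_m3_s > 0:
        vals[js, ks] = shape * (q_m3_s / total)
    return vals


def _check_topology(grid: DomainGrid, inlets: list[tuple[Region, float]]) -> None:
    fluid = grid.fluid
    comp, _ = ndimage.label(fluid)
    outlet_comps = set(np.unique(comp[-1][grid.labels[-1] != Region.SOLID])) - {0}
    if not outlet_comps:
        raise TopologyError("domain has no channel outlet")
    for region, q in inlets:
        if q <= 0:
            continue
        inlet_comps = set(np.unique(comp[0][grid.labels[0] == region])) - {0}
        if not (inlet_comps & outlet_comps):
            raise TopologyError(f"no open path from {region.name} inlet to an outlet")


def _classify_faces(grid: DomainGrid, bc: FlowBC):
    """Face type/value arrays for the three staggered components."""
    nx, ny, nz = grid.shape
    SP = np.pad(grid.solid, 1, constant_values=True)

    def base(axis: int, shp: tuple[int, int, int]) -> np.ndarray:
        # adjacent-cell solidity along `axis` in padded coordinates
        sl_a = [slice(1, -1)] * 3
        sl_b = [slice(1, -1)] * 3
        sl_a[axis] = slice(0, shp[axis])
        sl_b[axis] = slice(1, shp[axis] + 1)
        SA = SP[tuple(sl_a)]
        SB = SP[tuple(sl_b)]
        ft = np.full(shp, _WALL, dtype=np.int8)
        ft[~SA & ~SB] = _UNKNOWN
        ft[SA & SB] = _REFLECT
        return ft

    ft_u = base(0, (nx + 1, ny, nz))
    ft_v = base(1, (nx, ny + 1, nz))
    ft_w = base(2, (nx, ny, nz + 1))

    fv_u = np.zeros_like(ft_u, dtype=float)
    inlets = _inlet_channels(grid, bc)
    for region, q in inlets:
        mask0 = grid.labels[0] == region
        ft_u[0][mask0] = _DIRICHLET
        fv_u[0] += _inlet_values(grid, region, q)
        maskN = grid.labels[-1] == region
        ft_u[-1][maskN] = _OUTLET
    return (ft_u, ft_v, ft_w), fv_u, inlets


def solve_flow(grid: DomainGrid, fluid: FluidProperties | None = None,
               sph: SpheroidProperties | None = None,
               bc: FlowBC | None = None, tol: float = 1e-4) -> FlowField:
    """Solve steady Stokes–Brinkman flow on the labelled voxel grid.

    Returns a divergence-free :class:`FlowField`; raises
    :class:`TopologyError` when an active inlet has no open path to an
    outlet, and :class:`FlowConvergenceError` if the verified relative
    residual exceeds ``tol``.
    """
    fluid = fluid or FluidProperties()
    if sph is None:
        phi = grid.design.phi if grid.design is not None else 0.5
        sph = SpheroidProperties(porosity=phi)
    bc = bc or FlowBC()

    nx, ny, nz = grid.shape
    h = grid.spacing_m
    mu = fluid.dynamic_viscosity

    (ft_u, ft_v, ft_w), fv_u, inlets = _classify_faces(grid, bc)
    _check_topology(grid, inlets)

    ftypes = [ft_u, ft_v, ft_w]
    fvals = [fv_u, np.zeros_like(ft_v, float), np.zeros_like(ft_w, float)]

    # unknown numbering: velocity components then pressure
    fidx, n_unknown = [], 0
    for ft in ftypes:
        idx = np.full(ft.shape, -1, dtype=np.int64)
        m = (ft == _UNKNOWN) | (ft == _OUTLET)
        idx[m] = n_unknown + np.arange(np.count_nonzero(m))
        n_unknown += np.count_nonzero(m)
        fidx.append(idx)
    cell_idx = np.full(grid.shape, -1, dtype=np.int64)
    fl = grid.fluid
    n_p = int(np.count_nonzero(fl))
    cell_idx[fl] = np.arange(n_p)

    # Brinkman drag per cell, averaged to faces
    drag = np.zeros(grid.shape)
    drag[grid.porous] = mu / sph.permeability
    dragp = np.pad(drag, 1)

    # blocks of the saddle-point system  [A G; D 0] [u p] = [rhs_u; rhs_div]
    # (momentum rows negated and scaled by h^2/mu so A is SPD; D = -(mu/h) G^T)
    a_rows, a_cols, a_vals = [], [], []
    g_rows, g_cols, g_vals = [], [], []
    d_rows, d_cols, d_vals = [], [], []
    rhs_u = np.zeros(n_unknown)
    rhs_div = np.zeros(n_p)
    c_p = h / mu        # pressure-gradient coefficient after row scaling h^2/mu

    # ghost codes beyond the array: zero-gradient across the open x planes,
    # reflected (no-slip) across the closed y/z walls
    pad_code_for = [tuple(_NEUMANN if ax == 0 else _REFLECT for ax in range(3))
                    for _ in range(3)]

    for d in range(3):
        ft, fv, idx = ftypes[d], fvals[d], fidx[d]
        rowmask = (ft == _UNKNOWN) | (ft == _OUTLET)
        rid = idx[rowmask]
        diag = np.zeros(ft.shape)

        for ax in range(3):
            code = pad_code_for[d][ax]
            pw = [(0, 0)] * 3
            pw[ax] = (1, 1)
            ftp = np.pad(ft, pw, constant_values=code)
            fvp = np.pad(fv, pw)
            idxp = np.pad(idx, pw, constant_values=-1)
            for shift in (-1, 1):
                sl = [slice(1, -1) if a == ax else slice(None) for a in range(3)]
                sl[ax] = slice(1 + shift, ftp.shape[ax] - 1 + shift)
                nt = ftp[tuple(sl)]
                nval = fvp[tuple(sl)]
                nidx = idxp[tuple(sl)]

                active = rowmask & ((nt == _UNKNOWN) | (nt == _OUTLET))
                a_rows.append(idx[active])
                a_cols.append(nidx[active])
                a_vals.append(np.full(np.count_nonzero(active), -1.0))

                diag[rowmask & (nt != _NEUMANN) & (nt != _REFLECT)] += 1.0
                diag[rowmask & (nt == _REFLECT)] += 2.0

                dmask = rowmask & (nt == _DIRICHLET)
                np.add.at(rhs_u, idx[dmask], nval[dmask])

        # face drag (mean of adjacent cell drags), scaled by h^2/mu
        sl_a = [slice(1, -1)] * 3
        sl_b = [slice(1, -1)] * 3
        sl_a[d] = slice(0, ft.shape[d])
        sl_b[d] = slice(1, ft.shape[d] + 1)
        sigma_f = 0.5 * (dragp[tuple(sl_a)] + dragp[tuple(sl_b)])
        diag[rowmask] += sigma_f[rowmask] * h * h / mu

        a_rows.append(rid)
        a_cols.append(rid)
        a_vals.append(diag[rowmask])

        # pressure gradient +c(pB - pA) in the negated momentum rows; an
        # outlet face sees a reference-pressure ghost cell beyond the plane
        cp = np.pad(cell_idx, 1, constant_values=-1)
        pA = cp[tuple(sl_a)]
        pB = cp[tuple(sl_b)]
        normal = ft == _UNKNOWN
        outlet = ft == _OUTLET
        for mask, pidx, coef in (((normal | outlet), pA, -c_p), (normal, pB, +c_p)):
            m = mask & (pidx >= 0)
            g_rows.append(idx[m])
            g_cols.append(pidx[m])
            g_vals.append(np.full(np.count_nonzero(m), coef))
        if np.any(outlet) and bc.outlet_pressure != 0.0:
            np.add.at(rhs_u, idx[outlet], -c_p * bc.outlet_pressure)

    # continuity rows: sum of signed face velocities = 0 in every fluid cell
    for d in range(3):
        ft, fv, idx = ftypes[d], fvals[d], fidx[d]
        for side, sign in ((0, -1.0), (1, +1.0)):
            sl = [slice(None)] * 3
            sl[d] = slice(side, grid.shape[d] + side)
            nt = ft[tuple(sl)]
            nidx = idx[tuple(sl)]
            nval = fv[tuple(sl)]
            m = fl & ((nt == _UNKNOWN) | (nt == _OUTLET))
            d_rows.append(cell_idx[m])
            d_cols.append(nidx[m])
            d_vals.append(np.full(np.count_nonzero(m), sign))
            dm = fl & (nt == _DIRICHLET)
            np.add.at(rhs_div, cell_idx[dm], -sign * nval[dm])

    A = sp.csc_matrix((np.concatenate(a_vals),
                       (np.concatenate(a_rows), np.concatenate(a_cols))),
                      shape=(n_unknown, n_unknown))
    G = sp.csr_matrix((np.concatenate(g_vals),
                       (np.concatenate(g_rows), np.concatenate(g_cols))),
                      shape=(n_unknown, n_p))
    Dv = sp.csr_matrix((np.concatenate(d_vals),
                        (np.concatenate(d_rows), np.concatenate(d_cols))),
                       shape=(n_p, n_unknown))

    # pressure Schur complement, SPD since D is -(mu/h) G^T: solve
    # (D A^-1 G) p = D A^-1 rhs_u - rhs_div by preconditioned CG, with the
    # SIMPLE-style sparse approximation D diag(A)^-1 G as preconditioner
    lu_A = spla.splu(A)
    Shat = (-(Dv @ sp.diags(1.0 / A.diagonal()) @ G)).tocsc()
    lu_S = spla.splu(Shat)

    def s_pos(pvec: np.ndarray) -> np.ndarray:
        return -(Dv @ lu_A.solve(G @ pvec))

    Sop = spla.LinearOperator((n_p, n_p), matvec=s_pos)
    Mop = spla.LinearOperator((n_p, n_p), matvec=lu_S.solve)
    b_s = -(Dv @ lu_A.solve(rhs_u) - rhs_div)
    scale = max(float(np.linalg.norm(b_s)), 1e-300)
    p_vec, info = spla.cg(Sop, b_s, rtol=1e-10, atol=1e-12 * scale,
                          maxiter=500, M=Mop)
    if info != 0:
        raise FlowConvergenceError(
            f"pressure Schur solve did not converge (info={info})", [np.nan])
    u_vec = lu_A.solve(rhs_u - G @ p_vec)

    r_mom = A @ u_vec + G @ p_vec - rhs_u
    r_div = Dv @ u_vec - rhs_div
    bnorm = np.sqrt(np.linalg.norm(rhs_u) ** 2 + np.linalg.norm(rhs_div) ** 2)
    res = float(np.sqrt(np.linalg.norm(r_mom) ** 2 + np.linalg.norm(r_div) ** 2)
                / bnorm) if bnorm > 0 else 0.0
    if not np.isfinite(res) or res > tol:
        raise FlowConvergenceError(
            f"flow solve residual {res:.2e} exceeds tolerance {tol:.0e}", [res])

    out_faces = []
    for d in range(3):
        arr = np.array(fvals[d])  # Dirichlet values prefilled; walls 0
        m = fidx[d] >= 0
        arr[m] = u_vec[fidx[d][m]]
        arr[ftypes[d] == _REFLECT] = 0.0
        out_faces.append(arr)
    p = np.zeros(grid.shape)
    p[fl] = p_vec[cell_idx[fl]]

    return FlowField(grid=grid, u=out_faces[0], v=out_faces[1], w=out_faces[2],
                     p=p, residual=res, residual_history=[1.0, res])


def shear_rate_field(flow: FlowField, fluid: FluidProperties | None = None) -> np.ndarray:
    """Shear-rate magnitude (1/s): ``sqrt(2 D:D)`` from central differences
    of the cell-centred velocity; zero in solid cells."""
    h = flow.grid.spacing_m
    vel = flow.cell_velocity()
    grads = [np.gradient(vel[..., c], h) for c in range(3)]  # grads[c][a] = d u_c / d x_a
    gam2 = np.zeros(flow.grid.shape)
    for a in range(3):
        for b in range(3):
            Dab = 0.5 * (grads[a][b] + grads[b][a])
            gam2 += 2.0 * Dab * Dab
    out = np.sqrt(gam2)
    out[flow.grid.solid] = 0.0
    return out
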