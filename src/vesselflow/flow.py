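"""Steady free/porous flow over a labeled voxel domain.

One unified momentum equation is discretized on a MAC staggered grid
(pressures at cell centers, face-normal velocities on faces):

* lumen (free flow):          0 = -grad p + mu lap(v)            [+ rho (v.grad)v]
* endothelium / interstitium: 0 = -grad p + (mu/eps) lap(v)
                                  - (mu/kappa) v
                                  [- rho eps Cf/sqrt(kappa) |v| v]

with continuity div(v) = 0 in every cell. Velocity and stress continuity
at free/porous interfaces are implicit in the single-equation form; the
face resistivity 1/kappa is averaged across region interfaces. The default
``stokes_brinkman_linear`` mode drops the convective and Forchheimer terms
(the device operates at Re << 1); ``picard_full`` retains them with lagged
coefficients.

Boundary pressures are imposed at ghost cell centers half a cell outside
tagged block faces; untagged boundary and all EXTERIOR voxels are no-slip
walls. Post-processing provides wall shear stress, per-link flow
statistics (axial velocity, end fluxes, transmural leakage), streamlines,
and the WSS multivariate regression.

Internally SI units are used (m, Pa, m/s); geometry enters in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse import linalg as spla
from scipy.spatial import cKDTree

from .geometry import ENDOTHELIUM, EXTERIOR, INTERSTITIUM, LUMEN, LabelField
from .network import VesselGraph
from .permeability import hydraulic_from_diffusive

UM = 1e-6                     # um -> m

# fluid and porous-region constants (culture medium at 37 C; fibrin gel and
# endothelial monolayer porosity/permeability as configured for the device)
RHO_MEDIA = 1000.0            # kg/m^3
MU_MEDIA = 1.002e-3           # Pa s
MU_ENDOTHELIUM = 3e-3         # Pa s (taken similar to whole blood)
EPS_POROUS = 0.265            # porosity of fibrin gel and endothelium
KAPPA_FIBRIN = 1.2e-7         # m^2 (configured literature value)
PD_CONTROL = 5e-8             # m/s, diffusive permeability, control
PD_IL1B = 50e-8               # m/s, after IL-1beta treatment
L_CHARACTERISTIC = 1e-3       # m, distance between parent channels

# pressure boundary sets (Pa): vessel lumen inlet / interstitial inlet
P_VESSEL_CONTROL = 3.15
P_GEL_CONTROL = 1.75
P_VESSEL_TREATED = 0.35
P_GEL_TREATED = 0.075

def friction_factor(eps_p: float) -> float:
    """Forchheimer friction factor Cf = 1.75 / sqrt(150 eps_p^3)."""
    if not (0 < eps_p <= 1):
        raise ValueError("porosity must lie in (0, 1]")
    return 1.75 / np.sqrt(150.0 * eps_p**3)


@dataclass
class RegionProps:
    eps_p: float                   # porosity (1 in the lumen)
    kappa: float | None            # m^2; None for free-flow regions
    mu: float                      # dynamic viscosity, Pa s

    def __post_init__(self):
        if not (0 < self.eps_p <= 1):
            raise ValueError("porosity must lie in (0, 1]")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("permeability must be positive")
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")


@dataclass
class MaterialProps:
    """Fluid density plus per-region porosity/permeability/viscosity."""
    rho: float = RHO_MEDIA
    regions: dict = field(default_factory=dict)   # label -> RegionProps

    @classmethod
    def control(cls, kappa_endo: float | None = None,
                kappa_fibrin: float = KAPPA_FIBRIN) -> "MaterialProps":
        if kappa_endo is None:
            kappa_endo = hydraulic_from_diffusive(
                PD_CONTROL, MU_ENDOTHELIUM, L_CHARACTERISTIC, EPS_POROUS)
        return cls(regions={
            LUMEN: RegionProps(1.0, None, MU_MEDIA),
            ENDOTHELIUM: RegionProps(EPS_POROUS, kappa_endo, MU_ENDOTHELIUM),
            INTERSTITIUM: RegionProps(EPS_POROUS, kappa_fibrin, MU_MEDIA),
        })

    @classmethod
    def il1b(cls, kappa_fibrin: float = KAPPA_FIBRIN) -> "MaterialProps":
        kappa_endo = hydraulic_from_diffusive(
            PD_IL1B, MU_ENDOTHELIUM, L_CHARACTERISTIC, EPS_POROUS)
        return cls.control(kappa_endo=kappa_endo, kappa_fibrin=kappa_fibrin)

    def cf(self, label: int) -> float:
        return friction_factor(self.regions[label].eps_p)


@dataclass
class BoundaryConditions:
    """Per-tag, per-region boundary pressures (Pa). Faces and regions not
    listed are no-slip walls."""
    pressures: dict = field(default_factory=dict)  # tag -> {label: Pa}

    @classmethod
    def control(cls) -> "BoundaryConditions":
        return cls({"inlet": {LUMEN: P_VESSEL_CONTROL,
                              INTERSTITIUM: P_GEL_CONTROL},
                    "outlet": {LUMEN: 0.0, INTERSTITIUM: 0.0}})

    @classmethod
    def treated(cls) -> "BoundaryConditions":
        return cls({"inlet": {LUMEN: P_VESSEL_TREATED,
                              INTERSTITIUM: P_GEL_TREATED},
                    "outlet": {LUMEN: 0.0, INTERSTITIUM: 0.0}})

    def validate(self):
        if not any(v for v in self.pressures.values()):
            raise ValueError("at least one pressure boundary is required")
        for tag, d in self.pressures.items():
            for lab, p in d.items():
                if not np.isfinite(p):
                    raise ValueError(f"non-finite pressure for {tag}/{lab}")


@dataclass
class FlowProblem:
    field: LabelField
    props: MaterialProps
    bcs: BoundaryConditions
    K: sparse.csr_matrix
    b: np.ndarray
    uidx: list                    # per-axis face-grid unknown index arrays
    pbc: list                     # per-axis ghost-pressure arrays (NaN = none)
    cell_id: np.ndarray
    n_u: int
    n_p: int
    h_m: float
    eps_c: np.ndarray
    invk_c: np.ndarray
    mu_c: np.ndarray
    cf_c: np.ndarray

    @property
    def n_unknowns(self) -> int:
        return self.n_u + self.n_p


@dataclass
class FlowField:
    """Solved staggered velocities (m/s) and cell pressures (Pa)."""
    u: tuple                       # 3 face-grid arrays
    p: np.ndarray                  # cell grid, NaN outside fluid
    labels: LabelField
    residual: float
    div_max: float
    boundary_flux_imbalance: float
    mode: str
    iterations: int = 1
    converged: bool = True
    iteration_log: list = field(default_factory=list)

    @property
    def h_m(self) -> float:
        return self.labels.h * UM

    def cell_velocity(self) -> np.ndarray:
        """Cell-centered velocity vectors, shape (nx, ny, nz, 3), m/s."""
        out = np.zeros(self.labels.shape + (3,))
        for a in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[a] = slice(0, -1)
            sl_hi[a] = slice(1, None)
            out[..., a] = 0.5 * (self.u[a][tuple(sl_lo)]
                                 + self.u[a][tuple(sl_hi)])
        return out

    def face_flux(self, axis: int) -> np.ndarray:
        """Volumetric flux through each face of ``axis`` in m^3/s."""
        return self.u[axis] * self.h_m**2


@dataclass
class WSSField:
    """Wall shear stress at lumen cells adjacent to the wall (Pa)."""
    wss: np.ndarray               # cell grid, NaN off the wall
    wall_cells: np.ndarray        # (n, 3) indices
    mean: float
    mean_dyn_cm2: float

    def values(self) -> np.ndarray:
        w = self.wall_cells
        return self.wss[w[:, 0], w[:, 1], w[:, 2]]


@dataclass
class LinkFlowStats:
    link_id: int
    radius_um: float
    mean_axial_velocity: float    # m/s
    inflow: float                 # m^3/s through end faces
    outflow: float
    leakage: float                # net transmural outflow, m^3/s
    closure: float                # inflow - outflow - leakage
    mean_wss: float               # Pa
    n_voxels: int


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

def _face_pressure_tables(field: LabelField, bcs: BoundaryConditions):
    """(axis, side) -> {label: pressure}; side is 0 for '-', 1 for '+'."""
    out = {}
    for face, tag in field.face_tags.items():
        ax = "xyz".index(face[0])
        side = 0 if face[1] == "-" else 1
        table = bcs.pressures.get(tag, {})
        if table:
            out[(ax, side)] = table
    return out


def assemble_problem(field: LabelField, props: MaterialProps,
                     bcs: BoundaryConditions) -> FlowProblem:
    """Build the symmetric saddle-point system for the labeled block."""
    bcs.validate()
    labels = field.labels
    shape = np.array(labels.shape)
    h = field.h * UM
    V = h**3
    A_face = h**2

    for lab in np.unique(labels):
        if lab == EXTERIOR:
            continue
        rp = props.regions.get(int(lab))
        if rp is None:
            raise ValueError(f"no material properties for region {lab}")
        if lab != LUMEN and rp.kappa is None:
            raise ValueError(f"porous region {lab} has no permeability")

    fluid = labels != EXTERIOR
    cell_id = np.full(labels.shape, -1, np.int64)
    n_p = int(fluid.sum())
    cell_id[fluid] = np.arange(n_p)

    eps_c = np.ones(labels.shape)
    invk_c = np.zeros(labels.shape)
    mu_c = np.zeros(labels.shape)
    cf_c = np.zeros(labels.shape)
    for lab, rp in props.regions.items():
        sel = labels == lab
        if not sel.any():
            continue
        eps_c[sel] = rp.eps_p
        mu_c[sel] = rp.mu
        if rp.kappa is not None:
            invk_c[sel] = 1.0 / rp.kappa
            cf_c[sel] = friction_factor(rp.eps_p)
    mu_eff_c = np.where(fluid, mu_c / eps_c, 0.0)
    drag_c = mu_c * invk_c

    ptab = _face_pressure_tables(field, bcs)
    open_side = {(a, s): bool(ptab.get((a, s))) for a in range(3)
                 for s in (0, 1)}

    # classify faces per axis
    uidx, unknown_m, pbc_m, bothsolid_m = [], [], [], []
    n_u = 0
    n_bc_faces = 0
    for a in range(3):
        fshape = shape.copy()
        fshape[a] += 1
        padded = np.pad(labels, 1, constant_values=EXTERIOR)
        slL = [slice(1, s + 1) for s in shape]
        slR = [slice(1, s + 1) for s in shape]
        slL[a] = slice(0, shape[a] + 1)
        slR[a] = slice(1, shape[a] + 2)
        Llbl = padded[tuple(slL)]
        Rlbl = padded[tuple(slR)]
        fl = Llbl != EXTERIOR
        fr = Rlbl != EXTERIOR
        unknown = fl & fr
        pbc = np.full(tuple(fshape), np.nan)
        # boundary faces with a ghost pressure for the adjacent region
        for side, lbl_arr, fluid_arr in ((0, Rlbl, fr), (1, Llbl, fl)):
            table = ptab.get((a, side))
            if not table:
                continue
            sl = [slice(None)] * 3
            sl[a] = 0 if side == 0 else shape[a]
            sl = tuple(sl)
            for lab, pres in table.items():
                hit = fluid_arr[sl] & (lbl_arr[sl] == lab)
                tmp = pbc[sl]
                tmp[hit] = pres
                pbc[sl] = tmp
                tmp = unknown[sl]
                tmp |= hit
                unknown[sl] = tmp
                n_bc_faces += int(hit.sum())
        idx = np.full(tuple(fshape), -1, np.int64)
        cnt = int(unknown.sum())
        idx[unknown] = n_u + np.arange(cnt)
        n_u += cnt
        uidx.append(idx)
        unknown_m.append(unknown)
        pbc_m.append(pbc)
        bothsolid_m.append(~fl & ~fr)
    if n_bc_faces == 0:
        raise ValueError("no pressure boundary reaches a fluid region; "
                         "the system would be singular")

    rows, cols, vals = [], [], []
    bvec = np.zeros(n_u + n_p)

    def gather(arr, cells, valid):
        cc = np.clip(cells, 0, shape - 1)
        out = arr[cc[:, 0], cc[:, 1], cc[:, 2]].astype(float)
        out[~valid] = 0.0
        return out

    for a in range(3):
        U = np.argwhere(unknown_m[a])
        if U.size == 0:
            continue
        uid = uidx[a][U[:, 0], U[:, 1], U[:, 2]]
        m = len(U)
        ea = np.zeros(3, int)
        ea[a] = 1
        Lc = U - ea
        Rc = U
        inL = (Lc[:, a] >= 0)
        inL &= gather(fluid.astype(float), Lc, inL) > 0
        inR = (Rc[:, a] < shape[a])
        inR &= gather(fluid.astype(float), Rc, inR) > 0

        diag = np.zeros(m)
        # Darcy drag: face resistivity is the average of the adjacent cell
        # resistivities (ghost side mirrors the interior value)
        dragL = gather(drag_c, Lc, inL)
        dragR = gather(drag_c, Rc, inR)
        cnt = inL.astype(float) + inR.astype(float)
        diag += (dragL + dragR) / np.maximum(cnt, 1.0) * V

        for b_ax in range(3):
            eb = np.zeros(3, int)
            eb[b_ax] = 1
            for s in (-1, 1):
                if b_ax == a:
                    cmid = Rc if s > 0 else Lc
                    valid = inR if s > 0 else inL
                    mu_l = gather(mu_eff_c, cmid, valid)
                    g = U + s * ea
                    gi = np.clip(g, 0, np.array(uidx[a].shape) - 1)
                    nuid = uidx[a][gi[:, 0], gi[:, 1], gi[:, 2]]
                    is_unk = valid & (nuid >= 0)
                    diag += np.where(valid, mu_l * h, 0.0)
                    if is_unk.any():
                        rows.append(uid[is_unk])
                        cols.append(nuid[is_unk])
                        vals.append(-mu_l[is_unk] * h)
                else:
                    c1, c2 = Lc + s * eb, Rc + s * eb
                    v1 = np.all((c1 >= 0) & (c1 < shape), axis=1)
                    v1 &= gather(fluid.astype(float), c1, v1) > 0
                    v2 = np.all((c2 >= 0) & (c2 < shape), axis=1)
                    v2 &= gather(fluid.astype(float), c2, v2) > 0
                    tot = (gather(mu_eff_c, Lc, inL) + gather(mu_eff_c, Rc, inR)
                           + gather(mu_eff_c, c1, v1) + gather(mu_eff_c, c2, v2))
                    nvc = (inL.astype(float) + inR.astype(float)
                           + v1.astype(float) + v2.astype(float))
                    mu_l = tot / np.maximum(nvc, 1.0)
                    g = U + s * eb
                    inb = (g[:, b_ax] >= 0) & (g[:, b_ax] < uidx[a].shape[b_ax])
                    gi = np.clip(g, 0, np.array(uidx[a].shape) - 1)
                    nuid = uidx[a][gi[:, 0], gi[:, 1], gi[:, 2]]
                    is_unk = inb & (nuid >= 0)
                    both_solid = np.zeros(m, bool)
                    bs = bothsolid_m[a][gi[:, 0], gi[:, 1], gi[:, 2]]
                    both_solid = inb & bs
                    # in-grid connections
                    diag += np.where(is_unk, mu_l * h, 0.0)
                    known_zero = inb & ~is_unk
                    diag += np.where(known_zero & both_solid,
                                     2.0 * mu_l * h, 0.0)
                    diag += np.where(known_zero & ~both_solid,
                                     mu_l * h, 0.0)
                    # out-of-grid: open block face -> free slip, else wall
                    side = 0 if s < 0 else 1
                    if not open_side[(b_ax, side)]:
                        diag += np.where(~inb, 2.0 * mu_l * h, 0.0)
                    if is_unk.any():
                        rows.append(uid[is_unk])
                        cols.append(nuid[is_unk])
                        vals.append(-mu_l[is_unk] * h)

        rows.append(uid)
        cols.append(uid)
        vals.append(diag)

        # pressure gradient + continuity (symmetric off-diagonal blocks)
        pid_R = gather(cell_id.astype(float), Rc, inR).astype(np.int64)
        pid_L = gather(cell_id.astype(float), Lc, inL).astype(np.int64)
        ghost = pbc_m[a][U[:, 0], U[:, 1], U[:, 2]]
        selR = inR
        rows.append(uid[selR])
        cols.append(n_u + pid_R[selR])
        vals.append(np.full(selR.sum(), A_face))
        rows.append(n_u + pid_R[selR])
        cols.append(uid[selR])
        vals.append(np.full(selR.sum(), A_face))
        selL = inL
        rows.append(uid[selL])
        cols.append(n_u + pid_L[selL])
        vals.append(np.full(selL.sum(), -A_face))
        rows.append(n_u + pid_L[selL])
        cols.append(uid[selL])
        vals.append(np.full(selL.sum(), -A_face))
        # ghost pressures to RHS: +(p_R - p_L) h^2 moved across
        gR = ~inR & np.isfinite(ghost)
        np.add.at(bvec, uid[gR], -A_face * ghost[gR])
        gL = ~inL & np.isfinite(ghost)
        np.add.at(bvec, uid[gL], A_face * ghost[gL])

    N = n_u + n_p
    K = sparse.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N)).tocsr()
    return FlowProblem(field, props, bcs, K, bvec, uidx,
                       pbc_m, cell_id, n_u, n_p, h, eps_c, invk_c,
                       mu_c, cf_c)


# --------------------------------------------------------------------------
# Solve
# --------------------------------------------------------------------------

def _linear_solve(K, b, n_u):
    """Solve the saddle-point system by pressure-Schur-complement CG.

    The velocity block A is symmetric positive definite and decouples per
    component, so it factorizes cheaply (sparse LU in symmetric mode);
    the Schur complement G^T A^-1 G is then solved by conjugate gradients
    with a diagonal (SIMPLE-type) preconditioner. The CG residual is the
    discrete continuity residual, so mass conservation is enforced
    directly to the solver tolerance. Falls back to a monolithic sparse
    direct solve if CG stagnates.
    """
    N = K.shape[0]
    n_pp = N - n_u
    Kr = K.tocsr()
    A = Kr[:n_u, :n_u].tocsc()
    G = Kr[:n_u, n_u:].tocsr()
    bu, bp = b[:n_u], b[n_u:]
    try:
        lu = spla.splu(A, permc_spec="COLAMD",
                       options={"SymmetricMode": True})
    except RuntimeError:
        return spla.spsolve(K.tocsc(), b), "direct"
    GT = G.T.tocsr()
    dA = A.diagonal()
    Sd = np.asarray((GT.multiply(GT)) @ (1.0 / dA)).ravel()
    Sd[Sd == 0] = 1.0
    Sop = spla.LinearOperator((n_pp, n_pp),
                              matvec=lambda q: GT @ lu.solve(G @ q))
    M = spla.LinearOperator((n_pp, n_pp), matvec=lambda q: q / Sd)
    rhs = GT @ lu.solve(bu) - bp
    p, info = spla.cg(Sop, rhs, M=M, rtol=1e-12, atol=0.0, maxiter=10_000)
    if info != 0:
        warnings.warn(f"Schur CG stalled (info={info}); "
                      "falling back to a direct solve")
        return spla.spsolve(K.tocsc(), b), "direct"
    u = lu.solve(bu - G @ p)
    return np.concatenate([u, p]), "schur-cg"


def _unpack(problem: FlowProblem, x: np.ndarray):
    u = []
    for a in range(3):
        arr = np.zeros(problem.uidx[a].shape)
        sel = problem.uidx[a] >= 0
        arr[sel] = x[problem.uidx[a][sel]]
        u.append(arr)
    p = np.full(problem.field.labels.shape, np.nan)
    sel = problem.cell_id >= 0
    p[sel] = x[problem.n_u + problem.cell_id[sel]]
    return tuple(u), p


def _divergence_max(problem: FlowProblem, u) -> float:
    shape = problem.field.labels.shape
    div = np.zeros(shape)
    for a in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(0, -1)
        sl_hi[a] = slice(1, None)
        div += u[a][tuple(sl_hi)] - u[a][tuple(sl_lo)]
    fluid = problem.cell_id >= 0
    scale = np.mean([np.abs(ua).max() for ua in u]) + 1e-300
    return float(np.abs(div[fluid]).max() / scale)


def boundary_flux_report(field_or_problem, flow: "FlowField"):
    """Signed boundary fluxes per tagged face and the global imbalance."""
    problem = field_or_problem
    h2 = flow.h_m**2
    net = 0.0
    gross = 0.0
    per_face = {}
    for a in range(3):
        pbc = problem.pbc[a]
        for side, pos in ((0, 0), (1, pbc.shape[a] - 1)):
            sl = [slice(None)] * 3
            sl[a] = pos
            sel = np.isfinite(pbc[tuple(sl)])
            if not sel.any():
                continue
            uvals = flow.u[a][tuple(sl)][sel]
            outward = uvals * h2 * (1 if side == 1 else -1)
            key = ("xyz"[a] + ("-" if side == 0 else "+"))
            per_face[key] = float(outward.sum())
            net += outward.sum()
            gross += np.abs(uvals * h2).sum()
    imbalance = abs(net) / (gross + 1e-300)
    return per_face, float(imbalance)


def _lagged_terms(problem: FlowProblem, u):
    """Forchheimer diagonal and upwind convective entries for a lagged
    velocity field. Returns (rows, cols, vals) to add to K."""
    shape = np.array(problem.field.labels.shape)
    h = problem.h_m
    V = h**3
    rho = problem.props.rho
    fluid = problem.cell_id >= 0
    # cell-centered lagged velocity and speed
    vc = np.zeros(tuple(shape) + (3,))
    for a in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(0, -1)
        sl_hi[a] = slice(1, None)
        vc[..., a] = 0.5 * (u[a][tuple(sl_lo)] + u[a][tuple(sl_hi)])
    speed = np.linalg.norm(vc, axis=-1)

    rows, cols, vals = [], [], []

    def gather(arr, cells, valid):
        cc = np.clip(cells, 0, shape - 1)
        out = arr[cc[:, 0], cc[:, 1], cc[:, 2]].astype(float)
        out[~valid] = 0.0
        return out

    for a in range(3):
        U = np.argwhere(problem.uidx[a] >= 0)
        if U.size == 0:
            continue
        uid = problem.uidx[a][U[:, 0], U[:, 1], U[:, 2]]
        ea = np.zeros(3, int)
        ea[a] = 1
        Lc, Rc = U - ea, U
        inL = (Lc[:, a] >= 0)
        inL &= gather(fluid.astype(float), Lc, inL) > 0
        inR = (Rc[:, a] < shape[a])
        inR &= gather(fluid.astype(float), Rc, inR) > 0
        cnt = np.maximum(inL.astype(float) + inR.astype(float), 1.0)

        # Forchheimer: rho eps Cf / sqrt(kappa) |v| at the face
        forch_c = rho * problem.eps_c * problem.cf_c * np.sqrt(problem.invk_c)
        fo = (gather(forch_c, Lc, inL) + gather(forch_c, Rc, inR)) / cnt
        sp = (gather(speed, Lc, inL) + gather(speed, Rc, inR)) / cnt
        rows.append(uid)
        cols.append(uid)
        vals.append(fo * sp * V)

        # convective term rho/eps^2 (v.grad) u, first-order upwind
        ceps = (gather(problem.eps_c, Lc, inL)
                + gather(problem.eps_c, Rc, inR)) / cnt
        coeff = rho / ceps**2
        for b_ax in range(3):
            eb = np.zeros(3, int)
            eb[b_ax] = 1
            vb = (gather(vc[..., b_ax], Lc, inL)
                  + gather(vc[..., b_ax], Rc, inR)) / cnt
            s_up = np.where(vb > 0, -1, 1)      # upwind neighbor direction
            g = U + s_up[:, None] * eb
            inb = (g[:, b_ax] >= 0) & (g[:, b_ax] <
                                       problem.uidx[a].shape[b_ax])
            gi = np.clip(g, 0, np.array(problem.uidx[a].shape) - 1)
            nuid = problem.uidx[a][gi[:, 0], gi[:, 1], gi[:, 2]]
            w = coeff * np.abs(vb) * V / h
            rows.append(uid)
            cols.append(uid)
            vals.append(np.where(inb, w, 0.0))
            sel = inb & (nuid >= 0)
            rows.append(uid[sel])
            cols.append(nuid[sel])
            vals.append(-w[sel])
    return rows, cols, vals


def solve_flow(problem: FlowProblem, mode: str = "stokes_brinkman_linear",
               tol: float = 1e-8, max_iter: int = 30) -> FlowField:
    """Solve the assembled problem.

    ``stokes_brinkman_linear`` solves the single symmetric saddle-point
    system without convective/Forchheimer terms (exact at the device's
    Re << 1). ``picard_full`` iterates with those terms lagged until the
    relative velocity change drops below ``tol``.
    """
    x, method = _linear_solve(problem.K, problem.b, problem.n_u)
    u, p = _unpack(problem, x)
    log_ = [("linear", method)]
    iterations = 1
    converged = True

    if mode == "picard_full":
        converged = False
        for it in range(max_iter):
            rows, cols, vals = _lagged_terms(problem, u)
            extra = sparse.coo_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=problem.K.shape).tocsr()
            Kp = problem.K + extra
            x_new = spla.spsolve(Kp.tocsc(), problem.b)
            u_new, p_new = _unpack(problem, x_new)
            num = sum(float(np.sum((a - b_) ** 2))
                      for a, b_ in zip(u_new, u))
            den = sum(float(np.sum(a ** 2)) for a in u_new) + 1e-300
            rel = np.sqrt(num / den)
            u, p = u_new, p_new
            iterations += 1
            log_.append(("picard", rel))
            if rel < tol:
                converged = True
                break
        if not converged:
            warnings.warn("Picard iteration did not reach tol; returning "
                          "the best iterate")
    elif mode != "stokes_brinkman_linear":
        raise ValueError(f"unknown mode {mode!r}")

    div_max = _divergence_max(problem, u)
    flow = FlowField(u, p, problem.field, residual=np.nan, div_max=div_max,
                     boundary_flux_imbalance=np.nan, mode=mode,
                     iterations=iterations, converged=converged,
                     iteration_log=log_)
    _, imb = boundary_flux_report(problem, flow)
    flow.boundary_flux_imbalance = imb
    return flow


# --------------------------------------------------------------------------
# Wall shear stress
# --------------------------------------------------------------------------

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def wall_shear_stress(flow: FlowField, field: LabelField,
                      props: MaterialProps) -> WSSField:
    """WSS at lumen cells adjacent to the endothelial wall.

    For each wall-adjacent lumen cell, the wall-normal direction is taken
    from the gradient of the lumen distance transform and the tangential
    velocity is sampled one cell inward along it (where the staggered
    solution is insensitive to the staircase wall). The shear rate is the
    one-sided difference against the no-slip interface value over the
    sampled wall distance, corrected for the cylindrical velocity profile
    with the local vessel radius (distance-transform value at the nearest
    medial-axis voxel):

        wss = mu * |v_t| / d * 2 R_loc / (2 R_loc - d)

    Units Pa (1 Pa = 10 dyn/cm^2). Zero flow yields identically zero WSS.
    """
    labels = field.labels
    lumen = labels == LUMEN
    wall_like = (labels == ENDOTHELIUM) | (labels == EXTERIOR) | \
        (labels == INTERSTITIUM)
    near_wall = lumen & ndimage.binary_dilation(wall_like, _STRUCT_6)
    if not near_wall.any():
        return WSSField(np.full(labels.shape, np.nan),
                        np.empty((0, 3), int), 0.0, 0.0)
    h = field.h
    # distance to the wall: pad lumen with True so block faces do not count
    dist = ndimage.distance_transform_edt(
        np.pad(lumen, 1, constant_values=True))[1:-1, 1:-1, 1:-1] * h
    gx, gy, gz = np.gradient(dist)
    nrm = np.sqrt(gx**2 + gy**2 + gz**2) + 1e-30
    normal = np.stack([gx / nrm, gy / nrm, gz / nrm], axis=-1)

    cells = np.argwhere(near_wall)
    nvec = normal[near_wall]
    # sample one cell inward along the normal when possible
    shape = np.array(labels.shape)
    samp = np.clip(np.round(cells + nvec).astype(int), 0, shape - 1)
    inside = lumen[samp[:, 0], samp[:, 1], samp[:, 2]]
    samp[~inside] = cells[~inside]

    # local vessel radius from the nearest medial-axis voxel
    medial = lumen & (dist >= ndimage.maximum_filter(dist, size=3) - 1e-9)
    mcoords = np.argwhere(medial)
    _, mi = cKDTree(mcoords).query(cells)
    r_loc = dist[mcoords[mi, 0], mcoords[mi, 1], mcoords[mi, 2]]

    d = np.maximum(dist[samp[:, 0], samp[:, 1], samp[:, 2]] - 0.5 * h,
                   0.4 * h)
    r_loc = np.maximum(r_loc, d + 0.5 * h)
    vc = flow.cell_velocity()
    vs = vc[samp[:, 0], samp[:, 1], samp[:, 2]]
    ns = normal[samp[:, 0], samp[:, 1], samp[:, 2]]
    vt = vs - np.sum(vs * ns, axis=1)[:, None] * ns
    vt_mag = np.linalg.norm(vt, axis=1)
    mu = props.regions[LUMEN].mu
    tau = mu * vt_mag / (d * UM) * (2 * r_loc) / (2 * r_loc - d)
    wss = np.full(labels.shape, np.nan)
    wss[cells[:, 0], cells[:, 1], cells[:, 2]] = tau
    mean = float(tau.mean())
    return WSSField(wss, cells, mean, mean * 10.0)


# --------------------------------------------------------------------------
# Per-link statistics
# --------------------------------------------------------------------------

def _link_sample_tree(graph: VesselGraph, h: float):
    pts, lids, tangents = [], [], []
    for lk in graph.links:
        poly = lk.polyline
        seg = np.diff(poly, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        for i in range(len(seg)):
            if seglen[i] == 0:
                continue
            n = max(2, int(np.ceil(seglen[i] / (0.5 * h))))
            t = np.linspace(0, 1, n, endpoint=False)
            pts.append(poly[i] + t[:, None] * seg[i])
            tangents.append(np.tile(seg[i] / seglen[i], (n, 1)))
            lids.append(np.full(n, lk.id))
        pts.append(poly[-1:])
        tangents.append((seg[-1] / seglen[-1])[None]
                        if len(seg) and seglen[-1] > 0 else
                        np.array([[1.0, 0, 0]]))
        lids.append(np.array([lk.id]))
    pts = np.vstack(pts)
    return cKDTree(pts), np.concatenate(lids), np.vstack(tangents)


def link_statistics(flow: FlowField, field: LabelField, graph: VesselGraph,
                    wss: WSSField | None = None) -> list[LinkFlowStats]:
    """Per-link axial velocity, end fluxes, transmural leakage, mean WSS.

    Lumen voxels are assigned to the nearest link centerline; end faces
    are faces between different links or through pressure boundaries, and
    wall faces are lumen faces into the endothelium or interstitium. The
    per-link closure inflow - outflow - leakage is zero to the solver's
    conservation tolerance.
    """
    labels = field.labels
    h = field.h
    lumen = labels == LUMEN
    if not lumen.any():
        raise ValueError("no lumen voxels at this resolution")
    tree, lids, tangents = _link_sample_tree(graph, h)
    centers = (np.argwhere(lumen) + 0.5) * h + field.origin
    _, nearest = tree.query(centers)
    link_of = np.full(labels.shape, -1, np.int64)
    link_of[lumen] = lids[nearest]

    vc = flow.cell_velocity()
    link_ids = sorted({lk.id for lk in graph.links})
    acc = {lid: {"in": 0.0, "out": 0.0, "leak": 0.0, "vax": 0.0,
                 "n": 0, "wss_sum": 0.0, "wss_n": 0} for lid in link_ids}

    # axial velocity per voxel
    tang_vox = tangents[nearest]
    vsel = vc[lumen]
    vax = np.einsum("ij,ij->i", vsel, tang_vox)
    lsel = lids[nearest]
    for lid in link_ids:
        s = lsel == lid
        if s.any():
            acc[lid]["vax"] = float(np.mean(vax[s]))
            acc[lid]["n"] = int(s.sum())
        else:
            missing = [lk for lk in graph.links if lk.id == lid]
            if missing and missing[0].radius < h:
                raise ValueError(
                    f"link {lid} has no lumen voxels at resolution {h} um")

    h2 = flow.h_m**2
    shape = labels.shape
    for a in range(3):
        flux = flow.u[a] * h2
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(0, -1)
        sl_hi[a] = slice(1, None)
        # interior faces: cells c1 (low side) -> c2 (high side)
        l1 = link_of[tuple(sl_lo)].reshape(-1)
        l2 = link_of[tuple(sl_hi)].reshape(-1)
        lab1 = labels[tuple(sl_lo)].reshape(-1)
        lab2 = labels[tuple(sl_hi)].reshape(-1)
        sl_int = [slice(None)] * 3
        sl_int[a] = slice(1, shape[a])
        F = flux[tuple(sl_int)].reshape(-1)
        porous = {ENDOTHELIUM, INTERSTITIUM}
        for lid in link_ids:
            mine1 = l1 == lid
            mine2 = l2 == lid
            # faces leaving through the high side of my voxels
            out1 = mine1 & (l2 != lid)
            if out1.any():
                ff = F[out1]
                to_lumen = (l2[out1] >= 0)
                wallish = np.isin(lab2[out1], list(porous))
                acc[lid]["leak"] += float(ff[wallish].sum())
                endf = ff[to_lumen]
                acc[lid]["out"] += float(endf[endf > 0].sum())
                acc[lid]["in"] += float(-endf[endf < 0].sum())
            out2 = mine2 & (l1 != lid)
            if out2.any():
                ff = -F[out2]            # outward from c2 is -F
                to_lumen = (l1[out2] >= 0)
                wallish = np.isin(lab1[out2], list(porous))
                acc[lid]["leak"] += float(ff[wallish].sum())
                endf = ff[to_lumen]
                acc[lid]["out"] += float(endf[endf > 0].sum())
                acc[lid]["in"] += float(-endf[endf < 0].sum())
        # domain-boundary faces (ghost-pressure ends)
        for side, pos, cellpos in ((0, 0, 0), (1, shape[a], shape[a] - 1)):
            sl_f = [slice(None)] * 3
            sl_f[a] = pos
            sl_c = [slice(None)] * 3
            sl_c[a] = cellpos
            lface = link_of[tuple(sl_c)].reshape(-1)
            Fb = flux[tuple(sl_f)].reshape(-1)
            outward = Fb * (1 if side == 1 else -1)
            for lid in link_ids:
                s = lface == lid
                if s.any():
                    endf = outward[s]
                    acc[lid]["out"] += float(endf[endf > 0].sum())
                    acc[lid]["in"] += float(-endf[endf < 0].sum())

    if wss is not None:
        wvals = wss.wss
        wcells = wss.wall_cells
        wl = link_of[wcells[:, 0], wcells[:, 1], wcells[:, 2]]
        for lid in link_ids:
            s = wl == lid
            if s.any():
                acc[lid]["wss_sum"] = float(
                    np.nansum(wvals[wcells[s, 0], wcells[s, 1], wcells[s, 2]]))
                acc[lid]["wss_n"] = int(s.sum())

    radius = {lk.id: lk.radius for lk in graph.links}
    out = []
    for lid in link_ids:
        a_ = acc[lid]
        mean_wss = a_["wss_sum"] / a_["wss_n"] if a_["wss_n"] else np.nan
        out.append(LinkFlowStats(
            lid, radius[lid], a_["vax"], a_["in"], a_["out"], a_["leak"],
            a_["in"] - a_["out"] - a_["leak"], mean_wss, a_["n"]))
    return out


def link_stats_frame(stats: list[LinkFlowStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


# --------------------------------------------------------------------------
# Streamlines
# --------------------------------------------------------------------------

def velocity_interpolator(flow: FlowField):
    """Trilinear interpolator: position (um) -> velocity (m/s)."""
    from scipy.interpolate import RegularGridInterpolator
    h = flow.labels.h
    org = flow.labels.origin
    interps = []
    for a in range(3):
        fshape = flow.u[a].shape
        axes = []
        for ax in range(3):
            if ax == a:
                axes.append(org[ax] + np.arange(fshape[ax]) * h)
            else:
                axes.append(org[ax] + (np.arange(fshape[ax]) + 0.5) * h)
        interps.append(RegularGridInterpolator(
            tuple(axes), flow.u[a], bounds_error=False, fill_value=0.0))

    def v(points_um):
        pts = np.atleast_2d(points_um)
        out = np.stack([itp(pts) for itp in interps], axis=-1)
        return out if np.asarray(points_um).ndim > 1 else out[0]

    return v


def streamlines(flow: FlowField, seeds, step_um: float | None = None,
                max_len_um: float = 1e5, v_eps: float = 1e-12,
                max_steps: int = 20000) -> list[np.ndarray]:
    """RK4 advection of massless tracers through the interpolated field.

    Integration stops on domain exit, stagnation (|v| < ``v_eps`` m/s), or
    when the path exceeds ``max_len_um``.
    """
    h = flow.labels.h
    org = flow.labels.origin
    extent = np.array(flow.labels.shape) * h
    if step_um is None:
        step_um = 0.5 * h
    vfun = velocity_interpolator(flow)

    def inside(p):
        rel = p - org
        return np.all(rel >= 0) and np.all(rel <= extent)

    out = []
    for seed in np.atleast_2d(np.asarray(seeds, float)):
        if not inside(seed):
            raise ValueError(f"seed {seed} lies outside the domain")
        path = [seed.copy()]
        p = seed.copy()
        length = 0.0
        for _ in range(max_steps):
            v0 = vfun(p)
            s0 = np.linalg.norm(v0)
            if s0 < v_eps:
                break
            dt = step_um / (s0 * 1e6)        # um step -> seconds
            k1 = vfun(p) * 1e6
            k2 = vfun(p + 0.5 * dt * k1) * 1e6
            k3 = vfun(p + 0.5 * dt * k2) * 1e6
            k4 = vfun(p + dt * k3) * 1e6
            newp = p + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            if not inside(newp):
                break
            length += np.linalg.norm(newp - p)
            p = newp
            path.append(p.copy())
            if length >= max_len_um:
                break
        out.append(np.array(path))
    return out


# --------------------------------------------------------------------------
# WSS regression
# --------------------------------------------------------------------------

def wss_regression(stats: list[LinkFlowStats]) -> dict:
    """OLS of per-link mean WSS on axial velocity, wall outflow, radius.

    Returns coefficients, R^2, per-predictor F-test p-values, VIFs, and a
    predicted-vs-actual table.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import (
        variance_inflation_factor)

    df = link_stats_frame(stats).dropna(subset=["mean_wss"])
    if len(df) < 5:
        raise ValueError("need at least 5 links with complete statistics")
    X = df[["mean_axial_velocity", "leakage", "radius_um"]].rename(
        columns={"mean_axial_velocity": "axial_velocity",
                 "leakage": "wall_outflow", "radius_um": "radius"})
    y = df["mean_wss"]
    Xs = X.to_numpy()
    if np.linalg.matrix_rank(Xs - Xs.mean(0)) < X.shape[1]:
        corr = np.corrcoef(Xs, rowvar=False)
        bad = [(X.columns[i], X.columns[j])
               for i in range(3) for j in range(i + 1, 3)
               if abs(corr[i, j]) > 0.999]
        raise ValueError(f"rank-deficient design; collinear predictors: "
                         f"{bad or 'constant column'}")
    Xc = sm.add_constant(X)
    model = sm.OLS(y, Xc).fit()
    vif = {col: float(variance_inflation_factor(Xc.to_numpy(), i))
           for i, col in enumerate(Xc.columns) if col != "const"}
    pred = pd.DataFrame({"actual": y, "predicted": model.fittedvalues})
    return {"coefficients": dict(model.params),
            "r2": float(model.rsquared),
            "p_values": dict(model.pvalues),
            "vif": vif,
            "predicted_vs_actual": pred,
            "model": model}


# --------------------------------------------------------------------------
# Finite-reservoir pressure decay and VTK export
# --------------------------------------------------------------------------

def reservoir_pressure_decay(conductance: float, reservoir_area_m2: float,
                             dp0: float, times_s: np.ndarray,
                             rho: float = RHO_MEDIA, g: float = 9.81):
    """Lumped two-reservoir head decay driving the device.

    The device passes Q = C * dp between two open media reservoirs of area
    A; the head difference then decays as dp(t) = dp0 exp(-t / tau) with
    tau = A / (2 rho g C). This reproduces, as a sequence of steady
    states, the faster pressure equilibration of a leakier (treated)
    device. Returns (dp array, tau).
    """
    if conductance <= 0 or reservoir_area_m2 <= 0:
        raise ValueError("conductance and reservoir area must be positive")
    tau = reservoir_area_m2 / (2.0 * rho * g * conductance)
    return dp0 * np.exp(-np.asarray(times_s, float) / tau), float(tau)


def export_vtk(flow: FlowField, path, wss: WSSField | None = None) -> None:
    """Legacy-ASCII structured-points VTK file with pressure, velocity,
    region labels, and optionally WSS (cell-centered, written as points)."""
    lab = flow.labels
    nx, ny, nz = lab.shape
    h = lab.h
    vc = flow.cell_velocity()
    p = np.nan_to_num(flow.p)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvesselflow solution\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = lab.origin
        f.write(f"ORIGIN {o[0] + h / 2} {o[1] + h / 2} {o[2] + h / 2}\n")
        f.write(f"SPACING {h} {h} {h}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("SCALARS pressure float 1\nLOOKUP_TABLE default\n")
        p.T.ravel().tofile(f, sep="\n", format="%g")
        f.write("\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        lab.labels.T.ravel().tofile(f, sep="\n", format="%d")
        f.write("\nVECTORS velocity float\n")
        flat = vc.transpose(2, 1, 0, 3).reshape(-1, 3)
        np.savetxt(f, flat, fmt="%g")
        if wss is not None:
            f.write("SCALARS wss float 1\nLOOKUP_TABLE default\n")
            np.nan_to_num(wss.wss).T.ravel().tofile(f, sep="\n", format="%g")
            f.write("\n")
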