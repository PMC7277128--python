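"""Area-perimeter elasticity, vertex forces and relaxation dynamics.

Each cell carries the standard vertex-model energy

    U_i = (K_A / 2) (A_i - A_0)^2 + (Gamma_L / 2) (L_i - L_0)^2,

defining a cell pressure ``P_i = dU_i/dA_i = K_A (A_i - A_0)`` and a
cortical tension ``T_i = dU_i/dL_i = Gamma_L (L_i - L_0)``.  The
per-(cell,vertex) force is the energy gradient

    f_ik = dU_i/dr_k = P_i dA_i/dr_k + T_i dL_i/dr_k,

with the gradients taken from :mod:`vertexmech.geometry` (note that
``f_ik`` so defined is the outward-pointing gradient; the restoring force
on the vertex is ``-f_ik``).  Around any closed cell loop
``sum_k C_ik f_ik = 0`` identically, so each cell is automatically in
force (though not torque) balance.

The external boundary stress ``P_ext`` is *tension positive*: a positive
value pulls the periphery outward and the equilibrium minimizes
``U - P_ext A`` where ``A`` is the monolayer area.  With that convention
the conservation law ``sum_i A_i P_eff,i = A P_ext`` holds exactly at any
equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryCache, cross2, primal_geometry
from .topology import IncidenceSet, Monolayer, VERTEX_PERIPHERAL

__all__ = [
    "ConstitutiveParams",
    "ForceState",
    "EdgeCollapseError",
    "energy",
    "pressures_tensions",
    "vertex_forces",
    "peripheral_forces",
    "net_vertex_forces",
    "relax_drag",
    "equilibrate",
    "relax_constrained",
    "orthocentre_constraints",
    "ConstrainedSolveState",
]


@dataclass(frozen=True)
class ConstitutiveParams:
    """Mechanical parameters shared by all cells.

    K_A: area stiffness (energy / length^4).
    A0: reference (preferred) cell area.
    Gamma_L: perimeter stiffness (energy / length^2).
    L0: reference perimeter.
    P_ext: isotropic boundary stress, tension positive.
    eta: vertex drag coefficient for the overdamped dynamics.
    """

    K_A: float = 1.0
    A0: float = 1.0
    Gamma_L: float = 0.1
    L0: float = 0.0
    P_ext: float = 0.0
    eta: float = 1.0

    def __post_init__(self):
        if self.K_A < 0 or self.Gamma_L < 0 or self.eta <= 0:
            raise ValueError("require K_A >= 0, Gamma_L >= 0, eta > 0")


class EdgeCollapseError(RuntimeError):
    """An edge shrank below the degeneracy tolerance: a neighbour exchange
    (T1 transition) would be required, which is outside this model."""


@dataclass
class ForceState:
    """Per-corner forces, external boundary forces and balance residuals."""

    geom: GeometryCache
    params: ConstitutiveParams
    P: np.ndarray            # (N_c,) cell pressures
    T: np.ndarray            # (N_c,) cell tensions
    f: np.ndarray            # (n_corners, 2) f_ik = dU_i/dr_k
    f_ext: np.ndarray        # (n_corners, 2) external forces (peripheral only)
    net_vertex: np.ndarray   # (N_v, 2) sum_i C_ik f_ik - f_ext contributions
    net_cell: np.ndarray     # (N_c, 2) sum_k C_ik f_ik

    @property
    def residual(self) -> float:
        """Largest net-force magnitude over all vertices."""
        return float(np.hypot(*self.net_vertex.T).max())


# ---------------------------------------------------------------------- #
def energy(geom: GeometryCache, params: ConstitutiveParams) -> tuple[float, np.ndarray]:
    """Total and per-cell mechanical energy."""
    Ui = (0.5 * params.K_A * (geom.area - params.A0) ** 2
          + 0.5 * params.Gamma_L * (geom.perimeter - params.L0) ** 2)
    return float(Ui.sum()), Ui


def pressures_tensions(geom: GeometryCache,
                       params: ConstitutiveParams) -> tuple[np.ndarray, np.ndarray]:
    P = params.K_A * (geom.area - params.A0)
    T = params.Gamma_L * (geom.perimeter - params.L0)
    return P, T


def vertex_forces(geom: GeometryCache, params: ConstitutiveParams) -> ForceState:
    """Forces ``f_ik`` plus external boundary forces and balance residuals."""
    inc = geom.inc
    P, T = pressures_tensions(geom, params)
    ii = inc.corner_cell
    f = P[ii, None] * geom.dA + T[ii, None] * geom.dL
    f_ext = peripheral_forces(geom, params)
    net_vertex = np.zeros((inc.n_vertices, 2))
    np.add.at(net_vertex, inc.corner_vertex, f - f_ext)
    net_cell = np.zeros((inc.n_cells, 2))
    np.add.at(net_cell, inc.corner_cell, f)
    return ForceState(geom=geom, params=params, P=P, T=T, f=f, f_ext=f_ext,
                      net_vertex=net_vertex, net_cell=net_cell)


def peripheral_forces(geom: GeometryCache, params: ConstitutiveParams) -> np.ndarray:
    """External force blocks: ``f_ext,ik = P_ext dA_i/dr_k`` at peripheral
    vertices of border cells, zero elsewhere (tension positive)."""
    inc = geom.inc
    f_ext = np.zeros((inc.n_corners, 2))
    if params.P_ext != 0.0:
        mask = inc.vertex_label[inc.corner_vertex] == VERTEX_PERIPHERAL
        f_ext[mask] = params.P_ext * geom.dA[mask]
    return f_ext


def net_vertex_forces(mesh: Monolayer, inc: IncidenceSet,
                      params: ConstitutiveParams) -> tuple[float, np.ndarray]:
    """Enthalpy ``H = U - P_ext A`` and its gradient field over vertices.

    The gradient at vertex k is exactly the net force
    ``sum_i C_ik f_ik - f_ext,k``, so gradient flow of H is the drag
    dynamics."""
    geom = primal_geometry(mesh, inc)
    fs = vertex_forces(geom, params)
    U, _ = energy(geom, params)
    H = U - params.P_ext * float(geom.area.sum())
    return H, fs.net_vertex


# ---------------------------------------------------------------------- #
def _min_edge_length(mesh: Monolayer, inc: IncidenceSet) -> float:
    d = mesh.vertices[inc.edges[:, 1]] - mesh.vertices[inc.edges[:, 0]]
    return float(np.hypot(d[:, 0], d[:, 1]).min())


def relax_drag(mesh: Monolayer, inc: IncidenceSet, params: ConstitutiveParams,
               tol: float = 1e-8, max_steps: int = 200_000,
               dt0: float = 0.05, collapse_tol: float = 1e-6):
    """Overdamped vertex dynamics ``eta dr_k/dt = -(net force)_k``.

    Explicit Euler with backtracking step control: a step is only accepted
    if the enthalpy does not increase.  Returns ``(mesh, log)`` where the
    log records (step, energy, residual, dt) rows; non-convergence returns
    the best state with ``log[-1]['converged'] = False`` rather than
    raising.  Raises :class:`EdgeCollapseError` if an edge shrinks below
    ``collapse_tol`` times the initial minimum edge length.
    """
    r = mesh.vertices.copy()
    dt = dt0 / params.eta
    H, grad = net_vertex_forces(mesh.with_vertices(r), inc, params)
    collapse_len = collapse_tol * _min_edge_length(mesh, inc)
    log = []
    step = 0
    while step < max_steps:
        res = float(np.hypot(grad[:, 0], grad[:, 1]).max())
        log.append({"step": step, "energy": H, "residual": res, "dt": dt})
        if res < tol:
            log[-1]["converged"] = True
            return mesh.with_vertices(r), log
        accepted = False
        for _ in range(60):
            r_new = r - dt * grad / params.eta
            cand = mesh.with_vertices(r_new)
            if _min_edge_length(cand, inc) < collapse_len:
                raise EdgeCollapseError("edge collapsed during relaxation; "
                                        "a T1 transition would be required")
            H_new, grad_new = net_vertex_forces(cand, inc, params)
            if H_new <= H + 1e-12 * max(abs(H), 1.0):
                accepted = True
                break
            dt *= 0.5
        if not accepted:
            break
        r, H, grad = r_new, H_new, grad_new
        dt = min(dt * 1.3, 10.0 * dt0 / params.eta)
        step += 1
    log.append({"step": step, "energy": H,
                "residual": float(np.hypot(grad[:, 0], grad[:, 1]).max()),
                "dt": dt, "converged": False})
    return mesh.with_vertices(r), log


def equilibrate(mesh: Monolayer, inc: IncidenceSet, params: ConstitutiveParams,
                tol: float = 1e-12, max_iter: int = 2000) -> Monolayer:
    """Tight force balance via quasi-Newton descent plus Newton polish.

    Minimizes the enthalpy ``H = U - P_ext A`` with the analytic gradient,
    then applies damped Newton steps with a finite-difference Hessian of
    the gradient field (pseudo-inverse, since rigid-body modes are soft).
    Intended for small monolayers where machine-precision equilibria are
    needed by the stress and Airy diagnostics.
    """
    from scipy.optimize import minimize

    shape = mesh.vertices.shape

    def fun(x):
        H, g = net_vertex_forces(mesh.with_vertices(x.reshape(shape)), inc, params)
        return H, g.ravel()

    res = minimize(fun, mesh.vertices.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-18, "gtol": 1e-14})
    x = res.x
    # Newton polish on the gradient field
    n = x.size
    for _ in range(30):
        _, g = fun(x)
        gmax = np.abs(g).max()
        if gmax < tol:
            break
        Hess = np.empty((n, n))
        h = 1e-6 * max(1.0, np.abs(x).max())
        for a in range(n):
            xp = x.copy(); xp[a] += h
            xm = x.copy(); xm[a] -= h
            Hess[:, a] = (fun(xp)[1] - fun(xm)[1]) / (2 * h)
        Hess = 0.5 * (Hess + Hess.T)
        step, *_ = np.linalg.lstsq(Hess, -g, rcond=1e-10)
        lam = 1.0
        for _ in range(40):
            _, g_new = fun(x + lam * step)
            if np.abs(g_new).max() < gmax:
                x = x + lam * step
                break
            lam *= 0.5
        else:
            break
    return mesh.with_vertices(x.reshape(shape))


# ---------------------------------------------------------------------- #
@dataclass
class ConstrainedSolveState:
    """Outcome of the torque-balance-constrained minimization."""

    mesh: Monolayer
    multipliers: np.ndarray       # lambda_ik per interior corner constraint
    constraint_residual: float    # max |t_j . s_ik|
    force_residual: float         # max net force (unconstrained gradient)
    tangent_residual: float       # gradient projected on the constraint tangent
    converged: bool
    iterations: list = field(default_factory=list)


def orthocentre_constraints(mesh: Monolayer, inc: IncidenceSet):
    """Constraint values ``g_ik = t_j . s_ik`` and gradient rows.

    For every corner (i, k) at an interior vertex, j is the edge radiating
    outward from cell i at k (the edge of the other two cells); g vanishes
    exactly when k sits at the orthocentre of its edge-centroid triangle.
    Returns (g, rows) where each row maps vertex displacements to dg.
    """
    r = mesh.vertices
    g_vals = []
    rows = []  # list of (vertex_index_array, coefficient_vectors (n,2))
    interior = set(inc.interior_vertices.tolist())
    for cid in range(inc.n_corners):
        k = inc.corner_vertex[cid]
        if k not in interior:
            continue
        i = inc.corner_cell[cid]
        loop = inc.mesh.cells[i]
        m = loop.index(k)
        p = loop[(m - 1) % len(loop)]
        nx = loop[(m + 1) % len(loop)]
        j = inc.opposite_edge(i, k)
        t_tail, t_head = inc.edges[j]
        t = r[t_head] - r[t_tail]
        s = 0.5 * (r[p] - r[nx])
        g_vals.append(float(t @ s))
        # dg = s . d(t) + t . d(s)
        idx = np.array([t_head, t_tail, p, nx])
        coef = np.array([s, -s, 0.5 * t, -0.5 * t])
        rows.append((cid, idx, coef))
    return np.array(g_vals), rows


def relax_constrained(mesh: Monolayer, inc: IncidenceSet,
                      params: ConstitutiveParams,
                      tol: float = 1e-10, ctol: float = 1e-10,
                      max_outer: int = 25, rho0: float = 1.0,
                      max_inner: int = 4000) -> ConstrainedSolveState:
    """Augmented-Lagrangian minimization of the enthalpy subject to the
    orthocentre constraints ``t_j . s_ik = 0`` at every interior vertex.

    Outer iterations update multipliers ``lambda <- lambda - rho g`` and
    escalate the penalty when the worst constraint does not contract; inner
    minimizations use L-BFGS with the analytic gradient.  If the converged
    multipliers are negligible (the constrained optimum is also an
    unconstrained equilibrium) a Newton polish tightens the force balance.
    """
    from scipy.optimize import minimize

    shape = mesh.vertices.shape
    g0, rows0 = orthocentre_constraints(mesh, inc)
    n_con = len(g0)
    lam = np.zeros(n_con)
    rho = rho0
    iterations = []

    def augmented(x, lam, rho):
        cand = mesh.with_vertices(x.reshape(shape))
        H, grad = net_vertex_forces(cand, inc, params)
        g, rows = orthocentre_constraints(cand, inc)
        val = H - lam @ g + 0.5 * rho * (g @ g)
        gradL = grad.copy()
        for c, (cid, idx, coef) in enumerate(rows):
            wt = -lam[c] + rho * g[c]
            np.add.at(gradL, idx, wt * coef)
        return val, gradL.ravel(), g

    x = mesh.vertices.ravel().copy()
    g_prev = np.abs(g0).max() if n_con else 0.0
    for outer in range(max_outer):
        res = minimize(lambda xx: augmented(xx, lam, rho)[:2], x, jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": max_inner, "ftol": 1e-18, "gtol": 1e-13})
        x = res.x
        _, _, g = augmented(x, lam, rho)
        g_max = np.abs(g).max() if n_con else 0.0
        iterations.append({"outer": outer, "rho": rho, "g_max": g_max})
        lam = lam - rho * g
        if g_max < ctol:
            break
        if g_max > 0.25 * g_prev:
            rho = min(rho * 10.0, 1e12)
        g_prev = g_max

    cand = mesh.with_vertices(x.reshape(shape))
    _, grad = net_vertex_forces(cand, inc, params)
    # If the constraints are inactive at the optimum (negligible multipliers)
    # the state is also an unconstrained equilibrium: polish the force
    # balance with Newton, keeping the polish only if it preserves g = 0.
    polished = equilibrate(cand, inc, params, tol=min(tol, 1e-12))
    g_pol, _ = orthocentre_constraints(polished, inc)
    if n_con == 0 or np.abs(g_pol).max() <= max(ctol, np.abs(
            orthocentre_constraints(cand, inc)[0]).max()):
        cand = polished
        _, grad = net_vertex_forces(cand, inc, params)
    g, rows = orthocentre_constraints(cand, inc)
    g_max = float(np.abs(g).max()) if n_con else 0.0

    # tangent-space force residual: project the gradient off the constraint rows
    J = np.zeros((n_con, x.size))
    for c, (cid, idx, coef) in enumerate(rows):
        for v, w in zip(idx, coef):
            J[c, 2 * v:2 * v + 2] += w
    gr = grad.ravel()
    if n_con:
        lam_ls, *_ = np.linalg.lstsq(J.T, gr, rcond=None)
        tangent = gr - J.T @ lam_ls
    else:
        tangent = gr
    return ConstrainedSolveState(
        mesh=cand, multipliers=lam,
        constraint_residual=g_max,
        force_residual=float(np.abs(gr).max()),
        tangent_residual=float(np.abs(tangent).max()),
        converged=g_max < ctol,
        iterations=iterations,
    )
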