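"""Cell and tristar stress tensors, by every route the theory provides.

Cell stress (area-weighted first moment of the vertex forces):

    A_i sigma_i = sum_k C_ik q_ik (x) f_ik = sum_k C_ik r_k (x) f_ik
                = sum_j B_ij (t_j (x) h_j) eps_i          (force potential)
                = A_i P_i I + T_i L_i Q_i                 (constitutive)

with the structure tensor ``Q_i = L_i^-1 sum_j Bbar_ij t_j that_j (x)
that_j`` (unit trace).  The effective pressure is ``P_eff,i = tr(sigma_i)/2
= P_i + T_i L_i / (2 A_i)``.  Tristar (intercellular) stress at interior
vertex k:

    E_k sigma_k = sum_i C_ik q_ik (x) f_ik = sum_j A_jk (T_j (x) h_j) eps_k

and, through the map ``M_k`` from the edge-centroid triangle to the force
triangle, ``E_k sigma_k = -(eps E_k + F_k) M_k^T eps``; on torque-balanced
(orthocentric) configurations the two coincide and the stress-geometry
condition ``F_k eps sigma_k = 0`` ties the stress orientation to the
fabric tensor.

The antisymmetric defect of each tensor is the torque-imbalance signal and
is always reported, never silently removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import ConstitutiveParams, ForceState, pressures_tensions
from .force_network import ForcePotential
from .geometry import GeometryCache, cross2
from .topology import EPS, EPS_CELL, EPS_TRI, IncidenceSet, polygon_area

__all__ = [
    "StressField",
    "cell_stress_from_forces",
    "cell_stress_constitutive",
    "cell_stress_from_potential",
    "structure_tensor",
    "tristar_stress",
    "vertex_map",
    "tristar_stress_from_map",
    "global_stress",
    "stress_geometry_check",
    "stress_orientation",
    "effective_pressure",
]


@dataclass
class StressField:
    """A set of 2x2 stress tensors with their antisymmetry diagnostics."""

    sigma: np.ndarray             # (n, 2, 2)
    weight: np.ndarray            # areas A_i or E_k used in the definition
    index: np.ndarray             # cell ids or vertex ids

    @property
    def P_eff(self) -> np.ndarray:
        return 0.5 * np.trace(self.sigma, axis1=1, axis2=2)

    @property
    def asymmetry(self) -> np.ndarray:
        """Per-element torque defect |sigma_xy - sigma_yx|."""
        return np.abs(self.sigma[:, 0, 1] - self.sigma[:, 1, 0])


def _outer_sum(idx, a, b, n):
    out = np.zeros((n, 2, 2))
    np.add.at(out, idx, a[:, :, None] * b[:, None, :])
    return out


# ----------------------------- cell routes ---------------------------- #
def cell_stress_from_forces(fs: ForceState, geom: GeometryCache,
                            centres: np.ndarray | None = None,
                            closure_tol: float = 1e-8) -> StressField:
    """``A_i sigma_i = sum_k C_ik r_k (x) f_ik``.

    Requires per-cell force closure (otherwise the vertex-position form is
    origin dependent and an error is raised); when ``centres`` are given
    the equivalent spoke form ``sum_k C_ik q_ik (x) f_ik`` is used, which
    is identical under closure.
    """
    inc = geom.inc
    scale = max(float(np.abs(fs.f).max()), 1e-300) * geom.mesh.diameter()
    if float(np.abs(fs.net_cell).max()) > closure_tol * scale:
        raise ValueError("per-cell force closure violated: the r_k form of "
                         "the cell stress would be origin dependent")
    if centres is None:
        pos = geom.mesh.vertices[inc.corner_vertex]
    else:
        pos = geom.mesh.vertices[inc.corner_vertex] - np.asarray(centres)[inc.corner_cell]
    S = _outer_sum(inc.corner_cell, pos, fs.f, inc.n_cells)
    S /= geom.area[:, None, None]
    return StressField(sigma=S, weight=geom.area, index=np.arange(inc.n_cells))


def structure_tensor(geom: GeometryCache) -> np.ndarray:
    """``Q_i = L_i^-1 sum_j Bbar_ij t_j that_j (x) that_j`` (unit trace)."""
    inc = geom.inc
    Q = np.zeros((inc.n_cells, 2, 2))
    for i, ed in enumerate(inc.cell_edges):
        for j, _ in ed:
            Q[i] += geom.t_len[j] * np.outer(geom.t_hat[j], geom.t_hat[j])
        Q[i] /= geom.perimeter[i]
    return Q


def cell_stress_constitutive(geom: GeometryCache,
                             params: ConstitutiveParams) -> StressField:
    """``sigma_i = P_i I + (T_i L_i / A_i) Q_i`` (always symmetric)."""
    P, T = pressures_tensions(geom, params)
    Q = structure_tensor(geom)
    S = P[:, None, None] * np.eye(2) + \
        (T * geom.perimeter / geom.area)[:, None, None] * Q
    return StressField(sigma=S, weight=geom.area,
                       index=np.arange(geom.inc.n_cells))


def cell_stress_from_potential(fp: ForcePotential, geom: GeometryCache) -> StressField:
    """``A_i sigma_i = sum_j B_ij (t_j (x) h_j) eps_i`` -- the discrete curl
    of the force potential around the cell boundary.  The antisymmetric
    defect equals the cell torque ``sum_j B_ij h_j . t_j`` mapped through
    the rotation."""
    inc = geom.inc
    S = np.zeros((inc.n_cells, 2, 2))
    for i, ed in enumerate(inc.cell_edges):
        for j, sg in ed:
            S[i] += sg * np.outer(geom.t_vec[j], fp.h[j]) @ EPS_CELL
        S[i] /= geom.area[i]
    return StressField(sigma=S, weight=geom.area, index=np.arange(inc.n_cells))


def effective_pressure_divergence(fp: ForcePotential, geom: GeometryCache) -> np.ndarray:
    """``P_eff,i = -(1/2A_i) sum_j n_ij . h_j`` (discrete divergence form)."""
    inc = geom.inc
    out = np.zeros(inc.n_cells)
    for i, ed in enumerate(inc.cell_edges):
        for j, sg in ed:
            n_ij = -(EPS_CELL @ geom.t_vec[j]) * sg
            out[i] -= 0.5 * float(n_ij @ fp.h[j]) / geom.area[i]
    return out


def effective_pressure(geom: GeometryCache, params: ConstitutiveParams) -> np.ndarray:
    """``P_eff,i = P_i + T_i L_i / (2 A_i)``."""
    P, T = pressures_tensions(geom, params)
    return P + T * geom.perimeter / (2.0 * geom.area)


# ---------------------------- tristar routes -------------------------- #
def tristar_stress(fp: ForcePotential, geom: GeometryCache,
                   T_links: np.ndarray, f: np.ndarray | None = None,
                   closure_tol: float = 1e-8) -> dict:
    """Tristar stress by both printed forms.

    ``spoke``: ``E_k sigma_k = sum_i C_ik q_ik (x) f_ik`` with spokes taken
    from the same centres as ``T_links``; ``link``: ``E_k sigma_k = sum_j
    A_jk (T_j (x) h_j) eps_k``.  The two agree whenever the vertex force
    balance holds (any centres).  Requires ``geom`` kites computed with the
    matching centres.  Raises on vertex-closure violation.
    """
    inc = geom.inc
    f = fp.f if f is None else f
    rot = f @ (-EPS).T
    net = np.zeros((inc.n_vertices, 2))
    np.add.at(net, inc.corner_vertex, rot)
    scale = max(float(np.abs(f).max()), 1e-300) * geom.mesh.diameter()
    ki = inc.interior_vertices
    if len(ki) and np.abs(net[ki]).max() > closure_tol * scale:
        raise ValueError("interior-vertex force closure violated")

    n_v = inc.n_vertices
    spoke = np.zeros((n_v, 2, 2))
    for cid in range(inc.n_corners):
        k = inc.corner_vertex[cid]
        spoke[k] += np.outer(geom.q[cid], f[cid])
    link = np.zeros((n_v, 2, 2))
    for k in ki:
        for j in inc.vertex_edges[k]:
            ajk = int(inc.A[j, k])
            link[k] += ajk * np.outer(T_links[j], fp.h[j]) @ EPS_TRI
    Ek = geom.E
    sig_spoke = np.full((n_v, 2, 2), np.nan)
    sig_link = np.full((n_v, 2, 2), np.nan)
    sig_spoke[ki] = spoke[ki] / Ek[ki, None, None]
    sig_link[ki] = link[ki] / Ek[ki, None, None]
    Peff = np.full(n_v, np.nan)
    for k in ki:  # divergence form -(1/2E_k) sum_j N_jk . h_j
        tot = 0.0
        for j in inc.vertex_edges[k]:
            ajk = int(inc.A[j, k])
            N = -(EPS_TRI @ T_links[j]) * ajk
            tot -= 0.5 * float(N @ fp.h[j])
        Peff[k] = tot / Ek[k]
    return {"spoke": StressField(sigma=sig_spoke[ki], weight=Ek[ki], index=ki),
            "link": StressField(sigma=sig_link[ki], weight=Ek[ki], index=ki),
            "P_eff_divergence": Peff}


def vertex_map(fp: ForcePotential, geom: GeometryCache) -> dict:
    """The linear map ``M_k`` sending the edge-centroid triangle at an
    interior vertex onto the force-network triangle:
    ``M_k s_ik = -eps f_ik`` for all three kites."""
    inc = geom.inc
    M = {}
    for k in inc.interior_vertices:
        order = geom.tri_corners[k]  # anticlockwise corners (i, i', i'')
        js = [inc.corner_jout[c] for c in order]  # c_j of each corner
        h = [fp.h[j] for j in js]
        s = [geom.s[c] for c in order]
        two_a = 2.0 * geom.a_k[k]
        # 2 a_k M_k = sum over the cyclic triple of h_j (x) (eps s_i'k)-type
        # (h (x) s) eps = outer(h, eps^T s); numpy: eps^T @ s == s @ eps
        Mk = (np.outer(h[0], s[1] @ EPS) + np.outer(h[1], s[2] @ EPS)
              + np.outer(h[2], s[0] @ EPS)) / two_a
        M[int(k)] = Mk
    return M


def tristar_stress_from_map(M: dict, geom: GeometryCache) -> StressField:
    """``E_k sigma_k = (eps E_k - F_k) M_k^T eps`` -- the fabric route.

    Derivation: ``E_k sigma_k = sum_i C_ik q_ik (x) f_ik`` with
    ``f_ik = eps M_k s_ik`` gives ``[sum_i C_ik q_ik (x) s_ik] M_k^T
    eps^T``; the kite decomposition supplies the bracket as the transpose
    of ``eps E_k + F_k``.  On orthocentric configurations this equals the
    direct routes and reduces to ``sigma_k = eps M_k^T eps``.
    """
    inc = geom.inc
    ki = inc.interior_vertices
    sig = np.full((len(ki), 2, 2), np.nan)
    for m, k in enumerate(ki):
        Mk = M[int(k)]
        sig[m] = (EPS * geom.E[k] - geom.fabric[k]) @ Mk.T @ EPS / geom.E[k]
    return StressField(sigma=sig, weight=geom.E[ki], index=ki)


def map_stress_relation(M: dict, sigma_k: StressField) -> np.ndarray:
    """Residual of ``sigma_k = eps M_k^T eps`` (holds on the orthocentric
    manifold, where the map itself is symmetric under eps-conjugation)."""
    out = np.empty(len(sigma_k.index))
    for m, k in enumerate(sigma_k.index):
        out[m] = np.abs(sigma_k.sigma[m] - EPS @ M[int(k)].T @ EPS).max()
    return out


# ----------------------------- global laws ---------------------------- #
def global_stress(fs: ForceState, geom: GeometryCache) -> dict:
    """Monolayer stress ``A sigma = sum_i A_i sigma_i`` and the
    conservation-law diagnostics: under an isotropic boundary stress the
    global stress is ``P_ext I`` (tension positive), its deviatoric part
    vanishes, and ``sum_i A_i P_eff,i = A P_ext``."""
    inc = geom.inc
    pos = geom.mesh.vertices[inc.corner_vertex]
    S = (pos[:, :, None] * fs.f[:, None, :]).sum(axis=0)
    A = float(geom.area.sum())
    sigma = S / A
    dev = sigma - 0.5 * np.trace(sigma) * np.eye(2)
    Peff_sum = 0.5 * np.trace(S)
    P_ext = fs.params.P_ext
    return {
        "sigma": sigma,
        "deviatoric_norm": float(np.abs(dev).max()),
        "area": A,
        "sum_A_Peff": Peff_sum,
        "conservation_residual": float(Peff_sum - A * P_ext),
        "relative_conservation_residual":
            float((Peff_sum - A * P_ext) / (abs(A * P_ext) if P_ext else 1.0)),
    }


# --------------------------- stress geometry -------------------------- #
def stress_geometry_check(geom: GeometryCache, sigma_k: StressField) -> np.ndarray:
    """Residual of the stress-geometry condition ``F_k eps sigma_k = 0``
    per interior vertex (near zero on orthocentric equilibria)."""
    out = np.empty(len(sigma_k.index))
    for m, k in enumerate(sigma_k.index):
        out[m] = np.abs(geom.fabric[int(k)] @ EPS @ sigma_k.sigma[m]).max()
    return out


def stress_orientation(geom: GeometryCache, sigma_k: StressField,
                       det_tol: float = 1e-8) -> list[dict]:
    """Principal frames of the fabric tensor and the (symmetrized) tristar
    stress, with their alignment angle.

    Vertices where ``|det F_k| < det_tol E_k^2`` have no well-defined
    fabric orientation (sufficient local symmetry) and are flagged rather
    than raised on.  The antisymmetric defect of sigma is reported
    alongside, never discarded silently.
    """
    out = []
    for m, k in enumerate(sigma_k.index):
        k = int(k)
        F = geom.fabric[k]
        sig = sigma_k.sigma[m]
        sym = 0.5 * (sig + sig.T)
        asym = float(abs(sig[0, 1] - sig[1, 0]))
        rec = {"vertex": k, "asymmetry": asym,
               "detF": float(np.linalg.det(F)),
               "degenerate_fabric": abs(np.linalg.det(F)) < det_tol * geom.E[k] ** 2}
        wF, vF = np.linalg.eigh(F)
        wS, vS = np.linalg.eigh(sym)
        rec["fabric_eigenvalues"] = wF
        rec["stress_eigenvalues"] = wS
        cosang = abs(float(vF[:, 0] @ vS[:, 0]))
        rec["alignment_angle"] = float(np.arccos(np.clip(cosang, 0.0, 1.0)))
        out.append(rec)
    return out


def force_triangle_area(fp: ForcePotential, geom: GeometryCache, k: int) -> float:
    """Signed area of the force-network triangle at interior vertex k
    (equals ``det M_k`` times the edge-centroid triangle area)."""
    order = geom.tri_corners[k]
    pts = fp.h[[geom.inc.corner_jout[c] for c in order]]
    return polygon_area(pts)
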