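"""The discrete Airy stress function psi on kites.

One scalar ``psi_ik`` per kite, defined (up to a global constant) by two
families of jump conditions tied to the force potential ``h_j``:

* across the edge centroid ``c_j`` inside a cell (the two kites of cell i
  sharing edge j):      ``sum_k A_jk psi_ik = h_j . t_j``;
* across edge j inside a tristar (the two kites of vertex k on either
  side of edge j):      ``sum_i B_ij psi_ik = h_j . T_j``.

The first family encodes the cell torque balance, the second the tristar
torque balance.  For ``h_j`` to be a discrete curl of psi over the four
spokes surrounding ``c_j`` the two jump directions must be orthogonal,
``t_j . T_j = 0``; on that (orthocentric) manifold the over-determined
system is consistent, the potential is recovered by

    h_j = (1 / t_j T_j) sum_{i,k} eps_i B_ij A_jk psi_ik q_ik,

and both stress tensors follow from weighted discrete Laplacians of psi.
Off the manifold the least-squares residual of the jump system is a
quantitative torque-imbalance measure and is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import ConstitutiveParams, pressures_tensions
from .force_network import ForcePotential
from .geometry import GeometryCache
from .stress import StressField, structure_tensor
from .topology import EPS, EPS_CELL, EPS_TRI, IncidenceSet

__all__ = [
    "AiryField",
    "solve_airy",
    "reconstruct_potential",
    "laplacian_pressures",
    "stress_from_airy",
    "shape_tensor_D",
    "intracellular_jump_scale",
    "laplacian_operators",
]


@dataclass
class AiryField:
    """Per-kite Airy scalars with averages, differences and residuals."""

    geom: GeometryCache
    psi: np.ndarray           # (n_corners,)
    anchor: int               # corner with psi = 0 (gauge)
    residual_cell: float      # worst defect of the cell-side jump family
    residual_vertex: float    # worst defect of the tristar-side jump family
    residual_norm: float      # least-squares residual norm of the full system
    phi: dict = field(default_factory=dict)    # (i, j) -> mean psi of cell-side pair
    theta: dict = field(default_factory=dict)  # (j, k) -> mean psi of vertex-side pair
    v: dict = field(default_factory=dict)      # (i, j) -> oriented difference v_ij

    def v_cell(self, i: int) -> np.ndarray:
        inc = self.geom.inc
        return np.array([self.v[(i, j)] for j, _ in inc.cell_edges[i]])


def _cell_side_rows(inc: IncidenceSet):
    """(cell i, edge j) pairs with the kite corners at the two endpoints."""
    rows = []
    for i, ed in enumerate(inc.cell_edges):
        for j, _ in ed:
            t, h = inc.edges[j]
            rows.append((i, j, inc.corner_index[(i, h)], inc.corner_index[(i, t)]))
    return rows


def _vertex_side_rows(inc: IncidenceSet):
    """(edge j, vertex k) pairs with the kite corners of the two cells."""
    rows = []
    for j in inc.nonperipheral_edges:
        (i1, s1), (i2, s2) = inc.edge_cells[j]
        ip = i1 if s1 > 0 else i2   # B_ij = +1 cell
        im = i2 if s1 > 0 else i1
        for k in inc.edges[j]:
            if (ip, int(k)) in inc.corner_index and (im, int(k)) in inc.corner_index:
                rows.append((int(j), int(k),
                             inc.corner_index[(ip, int(k))],
                             inc.corner_index[(im, int(k))]))
    return rows


def solve_airy(fp: ForcePotential, geom: GeometryCache,
               T_links: np.ndarray) -> AiryField:
    """Solve both jump families for psi in least squares.

    All equations are assembled simultaneously (rather than integrating
    over a tree) so that any inconsistency appears as a residual instead of
    path dependence.  The gauge is fixed by ``psi = 0`` on the kite of the
    lowest (cell, vertex) index.
    """
    inc = geom.inc
    n = inc.n_corners
    rows_c = _cell_side_rows(inc)
    rows_v = _vertex_side_rows(inc)
    m = len(rows_c) + len(rows_v)
    M = np.zeros((m + 1, n))
    rhs = np.zeros(m + 1)
    for r, (i, j, c_head, c_tail) in enumerate(rows_c):
        M[r, c_head] = 1.0
        M[r, c_tail] = -1.0
        rhs[r] = float(fp.h[j] @ geom.t_vec[j])
    off = len(rows_c)
    for r, (j, k, c_plus, c_minus) in enumerate(rows_v):
        M[off + r, c_plus] = 1.0
        M[off + r, c_minus] = -1.0
        rhs[off + r] = float(fp.h[j] @ T_links[j])
    anchor = inc.corner_index[min(inc.corner_index)]
    M[m, anchor] = 1.0  # gauge row (consistent: rhs 0)
    psi, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    psi = psi - psi[anchor]

    res_c = max((abs(psi[ch] - psi[ct] - rhs[r])
                 for r, (_, _, ch, ct) in enumerate(rows_c)), default=0.0)
    res_v = max((abs(psi[cp] - psi[cm] - rhs[off + r])
                 for r, (_, _, cp, cm) in enumerate(rows_v)), default=0.0)
    af = AiryField(geom=geom, psi=psi, anchor=anchor,
                   residual_cell=float(res_c), residual_vertex=float(res_v),
                   residual_norm=float(np.linalg.norm(M[:m] @ psi - rhs[:m])))
    for i, j, ch, ct in rows_c:
        af.phi[(i, j)] = 0.5 * (psi[ch] + psi[ct])
        sign = dict(inc.edge_cells[j])[i]
        af.v[(i, j)] = sign * (psi[ch] - psi[ct])
    for j, k, cp, cm in rows_v:
        af.theta[(j, k)] = 0.5 * (psi[cp] + psi[cm])
    return af


# ---------------------------------------------------------------------- #
def reconstruct_potential(af: AiryField, T_links: np.ndarray,
                          orth_tol: float = 1e-8) -> dict:
    """Recover ``h_j`` from psi on every non-peripheral edge (curl form and
    the equivalent edge/link projection decomposition).

    Valid only where ``t_j . T_j ~ 0``: the per-edge orthogonality residual
    ``|that . That|`` is returned and edges beyond ``orth_tol`` are flagged
    (the curl construction needs orthogonal jump directions).  Peripheral
    edges, lacking a full four-kite neighbourhood, are excluded.
    """
    geom = af.geom
    inc = geom.inc
    psi = af.psi
    h_curl = np.full((inc.n_edges, 2), np.nan)
    h_proj = np.full((inc.n_edges, 2), np.nan)
    orth = np.full(inc.n_edges, np.nan)
    flagged = []
    for j in inc.nonperipheral_edges:
        t = geom.t_vec[j]
        T = T_links[j]
        tT = geom.t_len[j] * np.hypot(*T)
        orth[j] = abs(float(t @ T)) / tT
        corners = []
        for i, sgB in inc.edge_cells[j]:
            for k in inc.edges[j]:
                key = (i, int(k))
                if key in inc.corner_index:
                    sgA = 1 if int(k) == inc.edges[j][1] else -1
                    corners.append((inc.corner_index[key], sgB, sgA))
        if len(corners) != 4:
            flagged.append(int(j))
            continue
        acc = np.zeros(2)
        for cid, sgB, sgA in corners:
            acc += sgB * sgA * psi[cid] * (EPS_CELL @ geom.q[cid])
        h_curl[j] = acc / tT
        # projection form: (h.t) t/t^2 + (h.T) T/T^2 from the two jump sums
        ht = 0.5 * sum(abs(sgB) * sgA * psi[cid] for cid, sgB, sgA in corners)
        hT = 0.5 * sum(sgB * abs(sgA) * psi[cid] for cid, sgB, sgA in corners)
        h_proj[j] = ht * t / geom.t_len[j] ** 2 + hT * T / np.hypot(*T) ** 2
        if orth[j] > orth_tol:
            flagged.append(int(j))
    return {"h": h_curl, "h_projection": h_proj, "orthogonality": orth,
            "flagged_edges": flagged}


# ---------------------------------------------------------------------- #
def laplacian_pressures(af: AiryField, T_links: np.ndarray) -> dict:
    """Effective pressures as weighted graph Laplacians of psi.

    Cell side (interior cells only, since peripheral edges carry no link):
    ``P_eff,i = (1/2A_i) sum_{i',j} B_ij (t_j/T_j) B_i'j phi_i'j``;
    vertex side (interior vertices):
    ``P_eff,k = (1/2E_k) sum_{j,k'} A_jk (T_j/t_j) A_jk' theta_jk'``.
    """
    geom = af.geom
    inc = geom.inc
    T_len = np.hypot(T_links[:, 0], T_links[:, 1])

    P_cell = np.full(inc.n_cells, np.nan)
    for i in np.flatnonzero(inc.cell_label == 1):
        tot = 0.0
        for j, sg in inc.cell_edges[i]:
            ratio = geom.t_len[j] / T_len[j]
            for i2, sg2 in inc.edge_cells[j]:
                tot += sg * ratio * sg2 * af.phi[(i2, j)]
        P_cell[i] = tot / (2.0 * geom.area[i])

    P_vert = np.full(inc.n_vertices, np.nan)
    for k in inc.interior_vertices:
        tot = 0.0
        for j in inc.vertex_edges[k]:
            ajk = int(inc.A[j, k])
            ratio = T_len[j] / geom.t_len[j]
            for k2 in inc.edges[j]:
                ajk2 = 1 if int(k2) == inc.edges[j][1] else -1
                tot += ajk * ratio * ajk2 * af.theta[(int(j), int(k2))]
        P_vert[k] = tot / (2.0 * geom.E[k])
    return {"cell": P_cell, "vertex": P_vert}


def laplacian_operators(geom: GeometryCache, T_links: np.ndarray) -> dict:
    """The weighted Laplacian factorizations ``G A^T T A`` (vertex side) and
    ``B T^-1 B^T H`` (cell side) with diagonal Hodge-type weights
    ``G = diag(1/E_k)``, ``H = diag(1/A_i)``, ``T = diag(T_j/t_j)``."""
    import scipy.sparse as sp

    inc = geom.inc
    T_len = np.hypot(T_links[:, 0], T_links[:, 1])
    ratio = np.where(np.isfinite(T_len) & (T_len > 0), T_len / geom.t_len, 0.0)
    Tw = sp.diags(ratio)
    G = sp.diags(np.where(geom.E > 0, 1.0 / np.where(geom.E > 0, geom.E, 1.0), 0.0))
    H = sp.diags(1.0 / geom.area)
    A, B = inc.A, inc.B
    return {"vertex_laplacian": (G @ (A.T @ (Tw @ A))).tocsr(),
            "cell_laplacian": (B @ sp.diags(np.where(ratio > 0, 1.0 / np.where(ratio > 0, ratio, 1.0), 0.0)) @ B.T @ H).tocsr(),
            "weights": {"G": G, "H": H, "T": Tw}}


# ---------------------------------------------------------------------- #
def stress_from_airy(af: AiryField, T_links: np.ndarray) -> dict:
    """Full stress tensors from psi.

    Cell side: ``A_i sigma_i = A_i P_eff,i I - sum_{j,k} B_ij
    (t_j (x) T_j)/(t_j T_j) A_jk psi_ik`` (interior cells); vertex side:
    ``E_k sigma_k = E_k P_eff,k I - sum_{i,j} B_ij (T_j (x) t_j)/(T_j t_j)
    A_jk psi_ik`` (interior vertices).  Also verifies ``sum_j v_ij = 0``
    per interior cell.
    """
    geom = af.geom
    inc = geom.inc
    T_len = np.hypot(T_links[:, 0], T_links[:, 1])
    P = laplacian_pressures(af, T_links)

    sig_cell = np.full((inc.n_cells, 2, 2), np.nan)
    v_closure = np.full(inc.n_cells, np.nan)
    for i in np.flatnonzero(inc.cell_label == 1):
        acc = np.zeros((2, 2))
        vsum = 0.0
        for j, sg in inc.cell_edges[i]:
            unit = np.outer(geom.t_vec[j], T_links[j]) / (geom.t_len[j] * T_len[j])
            vij = af.v[(i, j)]
            acc += unit * vij
            vsum += vij
        sig_cell[i] = P["cell"][i] * np.eye(2) - acc / geom.area[i]
        v_closure[i] = vsum

    # vertex side: the tristar curl of the psi-projected potential,
    # h_j(psi) = (sum_k' A_jk' theta_jk') that/t + (sum_i B_ij psi_ik) That/T
    sig_vert = np.full((inc.n_vertices, 2, 2), np.nan)
    for k in inc.interior_vertices:
        acc = np.zeros((2, 2))
        for j in inc.vertex_edges[k]:
            ajk = int(inc.A[j, k])
            ht = sum((1 if int(k2) == inc.edges[j][1] else -1)
                     * af.theta[(int(j), int(k2))] for k2 in inc.edges[j])
            hT = sum(sgB * af.psi[inc.corner_index[(i, int(k))]]
                     for i, sgB in inc.edge_cells[j])
            h_psi = ht * geom.t_vec[j] / geom.t_len[j] ** 2 \
                + hT * T_links[j] / T_len[j] ** 2
            acc += ajk * np.outer(T_links[j], h_psi) @ EPS_TRI
        sig_vert[k] = acc / geom.E[k]
    return {"cell": sig_cell, "vertex": sig_vert, "P_eff": P,
            "v_closure": v_closure}


def shape_tensor_D(af: AiryField, i: int) -> dict:
    """The per-cell tensor ``D_i = sum_j v_ij that_j (x) That_j`` in its
    direct and trigonometric (double-angle) forms; its symmetry is a
    consequence of ``sum_j v_ij = 0``."""
    geom = af.geom
    inc = geom.inc
    direct = np.zeros((2, 2))
    trig = np.zeros((2, 2))
    for j, sg in inc.cell_edges[i]:
        vij = af.v[(i, j)]
        a = geom.alpha[j]
        that = geom.t_hat[j]
        That = -EPS @ that  # anticlockwise normal (the link direction on
        # the orthogonal manifold, where t.T = 0)
        direct += vij * np.outer(that, That)
        trig += 0.5 * vij * np.array([[-np.sin(2 * a), np.cos(2 * a)],
                                      [np.cos(2 * a), np.sin(2 * a)]])
    return {"direct": direct, "trig": trig,
            "asymmetry": float(abs(direct[0, 1] - direct[1, 0]))}


# ---------------------------------------------------------------------- #
def intracellular_jump_scale(af: AiryField, params: ConstitutiveParams) -> dict:
    """Within-cell psi variation compared with T_i L_i.

    For each cell: the range of psi over its kites divided by ``T_i L_i``
    (flagged nan when ``|T_i L_i|`` is negligible), plus (a) the residual
    of the deviatoric matching ``-D_i = T_i L_i (Q_i - I/2)`` and (b) the
    minimum-norm jump set ``v_ij`` solved from that matching alone, which
    scales linearly with the cell tension.
    """
    geom = af.geom
    inc = geom.inc
    P, T = pressures_tensions(geom, params)
    Q = structure_tensor(geom)
    ratio = np.full(inc.n_cells, np.nan)
    match_residual = np.full(inc.n_cells, np.nan)
    v_solved = {}
    for i in range(inc.n_cells):
        cids = inc.corners_of_cell(i)
        spread = float(af.psi[cids].max() - af.psi[cids].min())
        TL = T[i] * geom.perimeter[i]
        if abs(TL) > 1e-14:
            ratio[i] = spread / abs(TL)
        target = TL * (Q[i] - 0.5 * np.eye(2))
        if inc.cell_label[i] == 1:
            D = shape_tensor_D(af, i)["direct"]
            match_residual[i] = float(np.abs(D + target).max())
        # min-norm v from the matching system (2 deviatoric eqs + closure)
        ed = inc.cell_edges[i]
        n = len(ed)
        rowsM = np.zeros((3, n))
        rhsv = np.zeros(3)
        for m, (j, _) in enumerate(ed):
            a = geom.alpha[j]
            rowsM[0, m] = -0.5 * np.sin(2 * a)
            rowsM[1, m] = 0.5 * np.cos(2 * a)
            rowsM[2, m] = 1.0
        rhsv[0] = -target[0, 0]
        rhsv[1] = -target[0, 1]
        sol, *_ = np.linalg.lstsq(rowsM, rhsv, rcond=None)
        v_solved[i] = sol
    return {"ratio": ratio, "match_residual": match_residual,
            "v_solved": v_solved}
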