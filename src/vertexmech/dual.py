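"""Dual networks of cell centres: diagnostics and orthocentric construction.

Cell centres ``R_i`` induce links ``T_j = sum_i B_ij R_i`` dual to the
edges ``t_j`` (defined for border and interior edges; peripheral links are
truncated).  Torque balance demands two geometric conditions:

* orthogonality, ``t_j . T_j = 0`` for every non-peripheral edge;
* orthocentricity, ``t_j . s_ik = 0`` for the edge radiating outward from
  cell i at each interior vertex k -- equivalently each interior vertex
  sits at the orthocentre of the triangle of its neighbouring edge
  centroids.

On an orthocentric mesh the edge-centroid triangle at each vertex and the
triangle of the three cell centres around it are similar (rotated by pi,
scaled by 1/lambda_k), which pins the link lengths to ``T_j = E_k / h_ik``
and lets a consistent set of centres be recovered by least squares, up to
the translation gauge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryCache, cross2, kites, vertex_triangles
from .topology import EPS_TRI, IncidenceSet, Monolayer, polygon_area

__all__ = [
    "DualNetwork",
    "InfeasibleDualError",
    "centroid_centres",
    "links",
    "orthogonality_check",
    "orthocentre_residuals",
    "orthocentre_point",
    "construct_centres",
    "angle_histogram",
    "internal_angles",
]


class InfeasibleDualError(RuntimeError):
    """The mesh is not orthocentric: the target link directions demanded by
    the two endpoints of some edge disagree."""


@dataclass
class DualNetwork:
    """Cell centres, links and the per-vertex scalings of a dual network."""

    centres: np.ndarray          # (N_c, 2) R_i
    T: np.ndarray                # (N_e, 2) links, nan on peripheral edges
    T_len: np.ndarray            # (N_e,)
    U: np.ndarray                # (N_v,) centre-triangle areas (interior k)
    H: np.ndarray                # (n_corners,) centre-triangle altitudes
    lam: np.ndarray              # (N_v,) scale factors lambda_k = E_k / (2 U_k)
    N_jk: dict = field(default_factory=dict)   # (j, k) -> outward tristar normal
    orthogonality: np.ndarray = None   # per-edge t_hat . T_hat (nan peripheral)
    angles: np.ndarray = None          # per-edge intersection angle (nan peripheral)
    eq344_residual: np.ndarray = None  # |E_k - 2 sqrt(a_k U_k)| per interior k


def centroid_centres(mesh: Monolayer, inc: IncidenceSet) -> np.ndarray:
    """Vertex centroids ``Rtilde_i = (1/Z_i) sum_k C_ik r_k``."""
    return np.array([mesh.vertices[loop].mean(axis=0) for loop in mesh.cells])


def links(inc: IncidenceSet, centres: np.ndarray) -> np.ndarray:
    """Links ``T_j = sum_i B_ij R_i``; nan for truncated peripheral links."""
    T = np.full((inc.n_edges, 2), np.nan)
    for j in inc.nonperipheral_edges:
        (i1, s1), (i2, s2) = inc.edge_cells[j]
        T[j] = s1 * centres[i1] + s2 * centres[i2]
    return T


def build_dual(geom: GeometryCache, centres: np.ndarray) -> DualNetwork:
    """Assemble the full dual-network record for given centres."""
    inc = geom.inc
    centres = np.asarray(centres, dtype=float)
    if geom.q is None or geom.centres is None or \
            not np.array_equal(geom.centres, centres):
        kites(geom, centres)
    if geom.a_k is None:
        vertex_triangles(geom)
    T = links(inc, centres)
    T_len = np.hypot(T[:, 0], T[:, 1])

    U = np.zeros(inc.n_vertices)
    H = np.zeros(inc.n_corners)
    lam = np.full(inc.n_vertices, np.nan)
    N_jk = {}
    for k in inc.interior_vertices:
        order = geom.tri_corners[k]
        cells = [inc.corner_cell[c] for c in order]
        pts = centres[cells]
        U[k] = abs(polygon_area(pts))
        if U[k] > 0:
            lam[k] = geom.E[k] / (2.0 * U[k])
        for c in order:
            j = geom.opposite[c]
            base = T_len[j]
            if base > 0:
                H[c] = 2.0 * U[k] / base
        for j in inc.vertex_edges[k]:
            ajk = int(inc.A[j, k])
            N_jk[(int(j), int(k))] = -(EPS_TRI @ T[j]) * ajk

    dot = np.full(inc.n_edges, np.nan)
    ang = np.full(inc.n_edges, np.nan)
    np_e = inc.nonperipheral_edges
    th = geom.t_hat[np_e]
    Th = T[np_e] / T_len[np_e, None]
    dot[np_e] = np.einsum("ja,ja->j", th, Th)
    ang[np_e] = np.arctan2(np.abs(cross2(th, Th)), dot[np_e])

    e344 = np.full(inc.n_vertices, np.nan)
    ki = inc.interior_vertices
    e344[ki] = np.abs(geom.E[ki] - 2.0 * np.sqrt(np.maximum(geom.a_k[ki] * U[ki], 0.0)))
    return DualNetwork(centres=centres, T=T, T_len=T_len, U=U, H=H, lam=lam,
                       N_jk=N_jk, orthogonality=dot, angles=ang,
                       eq344_residual=e344)


def orthogonality_check(geom: GeometryCache, centres: np.ndarray) -> DualNetwork:
    """Per-edge link-edge intersection angles and ``t_j . T_j`` diagnostics."""
    return build_dual(geom, centres)


# ---------------------------------------------------------------------- #
def orthocentre_point(tri: np.ndarray) -> np.ndarray:
    """Orthocentre of a triangle given as a (3, 2) array (classical
    altitude-intersection construction)."""
    a, b, c = tri
    # solve for p with (p - a).(c - b) = 0 and (p - b).(c - a) = 0
    M = np.array([c - b, c - a])
    rhs = np.array([a @ (c - b), b @ (c - a)])
    return np.linalg.solve(M, rhs)


def orthocentre_residuals(geom: GeometryCache) -> dict:
    """Residuals ``g_ik = t_j . s_ik`` per interior corner plus, per interior
    vertex, the distance from the vertex to the orthocentre of its
    edge-centroid triangle (both vanish together)."""
    inc = geom.inc
    if geom.a_k is None:
        vertex_triangles(geom)
    g = np.full(inc.n_corners, np.nan)
    dist = np.full(inc.n_vertices, np.nan)
    for k in inc.interior_vertices:
        for c in geom.tri_corners[k]:
            j = geom.opposite[c]
            g[c] = float(geom.t_vec[j] @ geom.s[c])
        tri = geom.c[geom.tri_vertices[k]]
        dist[k] = float(np.hypot(*(geom.mesh.vertices[k] - orthocentre_point(tri))))
    finite = g[np.isfinite(g)]
    return {"g": g, "distance": dist,
            "max_g": float(np.abs(finite).max()) if finite.size else 0.0,
            "max_distance": float(np.nanmax(dist)) if np.isfinite(dist).any() else 0.0}


def construct_centres(geom: GeometryCache, feas_tol: float = 1e-6,
                      null_tol: float = 1e-7) -> DualNetwork:
    """Recover cell centres from an orthocentric mesh.

    Torque balance makes the triangle of cell centres around each interior
    vertex a copy of the edge-centroid triangle rotated by pi and scaled by
    ``1/lambda_k``: every link ``T_j = sum_i B_ij R_i`` must be parallel to
    the far side ``s_ik`` of the centroid triangle at each of its interior
    endpoints.  These direction conditions are linear and homogeneous in
    the centres, so the centres are found as the non-translational null
    vector of the direction system (SVD); the remaining uniform-scale
    freedom is then fixed by the tristar-consistency relation
    ``E_k = 2 sqrt(a_k U_k)``, which is affine-linear in the scale, and the
    translation by matching mean vertex centroids.

    Raises :class:`InfeasibleDualError` when no consistent direction null
    space exists (the input is not orthocentric) -- the singular-value
    spectrum is attached to the error message.
    """
    inc = geom.inc
    if geom.a_k is None:
        vertex_triangles(geom)
    n_c = inc.n_cells
    ki = inc.interior_vertices
    mu_col = {int(k): 2 * n_c + m for m, k in enumerate(ki)}
    n_unk = 2 * n_c + len(ki)
    scale = geom.mesh.diameter()

    rows = []
    for k in ki:
        for c in geom.tri_corners[k]:
            j = geom.opposite[c]
            ajk = int(inc.A[j, k])
            s = geom.s[c]
            # T_j(R) - mu_k A_jk s_ik = 0 (two homogeneous rows)
            for ax in range(2):
                coef = np.zeros(n_unk)
                for i, sg in inc.edge_cells[j]:
                    coef[2 * i + ax] = sg / scale
                coef[mu_col[int(k)]] = -ajk * s[ax] / scale
                rows.append(coef)
    M = np.array(rows)
    _, sv, Vt = np.linalg.svd(M, full_matrices=True)
    sv_full = np.zeros(n_unk)
    sv_full[:len(sv)] = sv
    null = Vt[sv_full <= null_tol * max(sv.max(), 1.0)]
    # remove the two rigid translations (R constant, mu = 0)
    t1 = np.zeros(n_unk); t1[0:2 * n_c:2] = 1.0 / np.sqrt(n_c)
    t2 = np.zeros(n_unk); t2[1:2 * n_c:2] = 1.0 / np.sqrt(n_c)
    proj = null - np.outer(null @ t1, t1) - np.outer(null @ t2, t2)
    norms = np.linalg.norm(proj, axis=1) if len(proj) else np.zeros(0)
    if not len(norms) or norms.max() < 1e-8:
        raise InfeasibleDualError(
            "no orthogonal dual triangulation exists (mesh is not "
            f"orthocentric); singular values {sv[-min(6, len(sv)):].tolist()}")
    shape = proj[int(np.argmax(norms))]
    shape = shape / np.linalg.norm(shape[:2 * n_c]) * scale
    mu = shape[2 * n_c:]
    if np.abs(mu).min() < 1e-10:
        raise InfeasibleDualError("degenerate per-vertex scalings in the dual")
    if mu.mean() < 0:
        shape = -shape
        mu = -mu
    if mu.min() <= 0:
        raise InfeasibleDualError(
            "inconsistent per-vertex scalings (mixed signs): mesh is not "
            "orthocentric")
    R_star = shape[:2 * n_c].reshape(n_c, 2)

    # residual check of the full similarity system at the solved shape
    resid = float(np.abs(M @ shape).max()) / scale
    if resid > feas_tol:
        raise InfeasibleDualError(
            f"similarity constraints violated by {resid:.3e}: mesh is not "
            "orthocentric")

    # Both the tristar areas E_k (linear in the centres, since the links
    # s_ik close around each interior vertex) and sqrt(a_k U_k) scale
    # linearly with the centre network, so the consistency relation
    # E_k = 2 sqrt(a_k U_k) is scale free: it fixes only the sign of the
    # null vector and serves as the validation residual.  The remaining
    # uniform scale is a genuine gauge; we fix it (with the translation)
    # by least-squares proximity to the vertex centroids.
    E_lin = np.zeros(inc.n_vertices)
    for cid in range(inc.n_corners):
        k = inc.corner_vertex[cid]
        i = inc.corner_cell[cid]
        E_lin[k] -= 0.5 * cross2(geom.s[cid], R_star[i])
    if np.mean(E_lin[ki]) < 0:
        R_star = -R_star
        E_lin = -E_lin
    sqrtU = np.zeros(inc.n_vertices)
    for k in ki:
        cells = [inc.corner_cell[c] for c in geom.tri_corners[k]]
        sqrtU[k] = np.sqrt(abs(polygon_area(R_star[cells])))
    rel = np.abs(E_lin[ki] - 2.0 * np.sqrt(geom.a_k[ki]) * sqrtU[ki]) \
        / np.abs(E_lin[ki]).max()
    if rel.max() > feas_tol:
        raise InfeasibleDualError(
            f"tristar consistency E_k = 2 sqrt(a_k U_k) violated by "
            f"{rel.max():.3e}: mesh is not orthocentric")

    # gauge: m R* + shift closest to the vertex centroids
    cen = centroid_centres(geom.mesh, inc)
    Rc = R_star - R_star.mean(axis=0)
    cc = cen - cen.mean(axis=0)
    m_gauge = float(np.sum(Rc * cc) / np.sum(Rc * Rc))
    if m_gauge <= 0:
        m_gauge = 1.0
    centres = m_gauge * Rc + cen.mean(axis=0)
    return build_dual(geom, centres)


# ---------------------------------------------------------------------- #
def internal_angles(geom: GeometryCache) -> dict:
    """Internal cell angles at interior vertices (orthocentricity implies
    every one of them is at least pi/2)."""
    inc = geom.inc
    out = {}
    for cid in range(inc.n_corners):
        k = inc.corner_vertex[cid]
        if inc.vertex_label[k] != 1:
            continue
        # angle between the two cell edges meeting at k, pointing away from k
        a_in = int(inc.A[inc.corner_jin[cid], k])
        a_out = int(inc.A[inc.corner_jout[cid], k])
        u = -a_in * geom.t_hat[inc.corner_jin[cid]]
        v = -a_out * geom.t_hat[inc.corner_jout[cid]]
        out[cid] = float(np.arccos(np.clip(u @ v, -1.0, 1.0)))
    return out


def angle_histogram(geom_or_angles, centres: np.ndarray | None = None,
                    bins: int = 18) -> dict:
    """Histogram of link-edge intersection angles over (0, pi).

    Accepts a :class:`GeometryCache` plus centres, or a precomputed array
    of angles.  Returns bin edges, counts, the mode bin and the fraction
    within 5 degrees of pi/2; degenerate inputs give an empty histogram
    with a warning flag.
    """
    if isinstance(geom_or_angles, GeometryCache):
        dn = build_dual(geom_or_angles, centres)
        ang = dn.angles[np.isfinite(dn.angles)]
    else:
        ang = np.asarray(geom_or_angles, dtype=float)
        ang = ang[np.isfinite(ang)]
    edges = np.linspace(0.0, np.pi, bins + 1)
    if ang.size == 0:
        return {"bin_edges": edges, "counts": np.zeros(bins, dtype=int),
                "empty": True, "mode_bin": None, "near_orthogonal_fraction": np.nan}
    counts, _ = np.histogram(ang, bins=edges)
    mode = int(np.argmax(counts))
    near = float(np.mean(np.abs(ang - np.pi / 2) <= np.deg2rad(5.0)))
    return {"bin_edges": edges, "counts": counts, "empty": False,
            "mode_bin": mode, "near_orthogonal_fraction": near}
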