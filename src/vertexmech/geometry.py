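"""Primal and intermediate geometry of a monolayer.

Everything derived from vertex positions lives here: edge vectors and
centroids, outward normals, cell areas and perimeters and their exact
gradients, the edge-centroid network of links ``s_ik``, spokes ``q_ik``,
kites, tristars, the triangles of edge centroids around interior vertices,
and the fabric tensor ``F_k`` that measures tristar asymmetry.

Identities maintained (and unit tested):

* ``t_j = sum_k A[j,k] r_k``, ``c_j = 1/2 sum_k Abar[j,k] r_k``;
* oriented area: ``A_i eps_i = sum_j B[i,j] t_j (x) c_j`` whose trace gives
  ``sum_j B[i,j] t_j . c_j = 0`` for every cell;
* link closure: ``sum_i C[i,k] s_ik = 0`` at interior vertices and
  ``sum_k C[i,k] s_ik = 0`` around every cell;
* kite decomposition: ``sum_i C[i,k] s_ik (x) q_ik = eps E_k + F_k`` and
  ``sum_k C[i,k] s_ik (x) q_ik = A_i eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import (EPS, EPS_CELL, IncidenceSet, Monolayer, TopologyError,
                       VERTEX_INTERIOR, polygon_area)

__all__ = [
    "GeometryCache",
    "DegenerateGeometryError",
    "primal_geometry",
    "shape_derivatives",
    "centroid_links",
    "kites",
    "fabric_tensor",
    "vertex_triangles",
    "cross2",
]

DEGENERATE_REL_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Zero-length edge or collinear edge-centroid triangle."""


def cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of stacked 2-vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


@dataclass
class GeometryCache:
    """All derived geometry for one vertex configuration.

    Per-corner arrays are indexed by the corner table of the
    :class:`~vertexmech.topology.IncidenceSet` (one row per cell-vertex
    incidence ``(i, k)``).
    """

    mesh: Monolayer
    inc: IncidenceSet

    # per edge
    t_vec: np.ndarray = None        # (N_e, 2) edge vectors
    t_len: np.ndarray = None        # (N_e,)
    t_hat: np.ndarray = None        # (N_e, 2)
    c: np.ndarray = None            # (N_e, 2) edge centroids
    alpha: np.ndarray = None        # (N_e,) edge orientation angles

    # per cell
    area: np.ndarray = None         # (N_c,)
    perimeter: np.ndarray = None    # (N_c,)
    trace_identity: np.ndarray = None  # sum_j B_ij t_j.c_j per cell

    # per corner (cell-vertex incidence)
    s: np.ndarray = None            # links between adjacent edge centroids
    dA: np.ndarray = None           # dA_i/dr_k
    dL: np.ndarray = None           # dL_i/dr_k

    # kite data (populated by kites(); depend on supplied cell centres)
    centres: np.ndarray = None      # (N_c, 2) the centres the kites refer to
    q: np.ndarray = None            # (n_corners, 2) spokes r_k - R_i
    K: np.ndarray = None            # (n_corners,) kite areas
    E: np.ndarray = None            # (N_v,) tristar areas (interior vertices)
    w: dict = field(default_factory=dict)
    fabric: np.ndarray = None       # (N_v, 2, 2), zero rows at periphery
    kite_selfintersect: np.ndarray = None

    # vertex-triangle data (edge-centroid triangles at interior vertices)
    tri_vertices: dict = field(default_factory=dict)   # k -> (3,) edge ids acw
    tri_corners: dict = field(default_factory=dict)    # k -> (3,) corner ids acw
    a_k: np.ndarray = None          # (N_v,) triangle areas
    altitude: np.ndarray = None     # (n_corners,) h_ik
    opposite: np.ndarray = None     # (n_corners,) opposite edge j for interior k

    def normal(self, i: int, j: int) -> np.ndarray:
        """Outward normal ``n_ij = -eps_i B_ij t_j`` of cell i at edge j."""
        sign = dict(self.inc.edge_cells[j])[i]
        return -(EPS_CELL @ self.t_vec[j]) * sign


# ---------------------------------------------------------------------- #
def primal_geometry(mesh: Monolayer, inc: IncidenceSet) -> GeometryCache:
    """Edges, centroids, areas, perimeters and their exact vertex gradients."""
    g = GeometryCache(mesh=mesh, inc=inc)
    r = mesh.vertices
    tails, heads = inc.edges[:, 0], inc.edges[:, 1]
    g.t_vec = r[heads] - r[tails]
    g.t_len = np.hypot(g.t_vec[:, 0], g.t_vec[:, 1])
    tol = DEGENERATE_REL_TOL * max(mesh.diameter(), 1.0)
    if np.any(g.t_len < tol):
        raise DegenerateGeometryError(
            f"degenerate edges {np.flatnonzero(g.t_len < tol).tolist()}")
    g.t_hat = g.t_vec / g.t_len[:, None]
    g.c = 0.5 * (r[heads] + r[tails])
    g.alpha = np.arctan2(g.t_vec[:, 1], g.t_vec[:, 0])

    n_c = inc.n_cells
    g.area = np.empty(n_c)
    g.perimeter = np.empty(n_c)
    g.trace_identity = np.empty(n_c)
    for i, ed in enumerate(inc.cell_edges):
        js = np.array([j for j, _ in ed])
        sg = np.array([s for _, s in ed])
        g.area[i] = 0.5 * np.sum(sg * cross2(g.c[js], g.t_vec[js]))
        g.perimeter[i] = np.sum(g.t_len[js])
        g.trace_identity[i] = np.sum(sg * np.einsum("ja,ja->j", g.t_vec[js], g.c[js]))

    shape_derivatives(g)
    centroid_links(g)
    return g


def shape_derivatives(g: GeometryCache) -> tuple[np.ndarray, np.ndarray]:
    """Per-corner gradients ``dA_i/dr_k`` and ``dL_i/dr_k``.

    The perimeter gradient is the sum of the two unit edge vectors of cell i
    pointing into vertex k; the area gradient is half the sum of the two
    outward edge normals of cell i at k.
    """
    inc = g.inc
    A = inc.A
    jin, jout, kk, ii = inc.corner_jin, inc.corner_jout, inc.corner_vertex, inc.corner_cell
    a_in = np.asarray(A[jin, kk]).ravel()
    a_out = np.asarray(A[jout, kk]).ravel()
    g.dL = g.t_hat[jin] * a_in[:, None] + g.t_hat[jout] * a_out[:, None]

    b_in = np.array([dict(inc.edge_cells[j])[i] for j, i in zip(jin, ii)])
    b_out = np.array([dict(inc.edge_cells[j])[i] for j, i in zip(jout, ii)])
    n_in = -(g.t_vec[jin] @ EPS_CELL.T) * b_in[:, None]
    n_out = -(g.t_vec[jout] @ EPS_CELL.T) * b_out[:, None]
    g.dA = 0.5 * (n_in + n_out)
    return g.dL, g.dA


def centroid_links(g: GeometryCache) -> np.ndarray:
    """Links ``s_ik`` between the two edge centroids of cell i adjacent to
    vertex k; they run clockwise around cells and anticlockwise as triangles
    around vertices."""
    g.s = g.c[g.inc.corner_jin] - g.c[g.inc.corner_jout]
    return g.s


# ---------------------------------------------------------------------- #
def kites(g: GeometryCache, centres: np.ndarray) -> GeometryCache:
    """Spokes, kite areas, tristar areas and kite self-intersection flags.

    ``centres`` is any candidate set of cell centres R_i (vertex centroids
    by default elsewhere); the kite of corner (i, k) is the quadrilateral
    (r_k, c_out, R_i, c_in) and its area is
    ``K_ik = 1/2 cross(s_ik, q_ik)``.
    """
    inc = g.inc
    centres = np.asarray(centres, dtype=float)
    g.centres = centres
    g.q = g.mesh.vertices[inc.corner_vertex] - centres[inc.corner_cell]
    g.K = 0.5 * cross2(g.s, g.q)
    g.E = np.zeros(inc.n_vertices)
    np.add.at(g.E, inc.corner_vertex, g.K)
    # a centre outside its cell produces self-intersecting (negative) kites
    g.kite_selfintersect = g.K <= 0
    g.w = {}
    for cid in range(inc.n_corners):
        i = inc.corner_cell[cid]
        g.w[cid] = (g.c[inc.corner_jin[cid]] - centres[i],
                    g.c[inc.corner_jout[cid]] - centres[i])
    return g


def kite_polygon(g: GeometryCache, cid: int) -> np.ndarray:
    """Anticlockwise quadrilateral of kite ``cid`` (r_k, c_out, R_i, c_in)."""
    inc = g.inc
    return np.array([
        g.mesh.vertices[inc.corner_vertex[cid]],
        g.c[inc.corner_jout[cid]],
        g.centres[inc.corner_cell[cid]],
        g.c[inc.corner_jin[cid]],
    ])


def fabric_tensor(g: GeometryCache) -> np.ndarray:
    """Fabric tensor ``F_k = 1/2 sum_{i,j} B_ij A_jk w_ij (x) w_ij`` with
    ``w_ij = c_j - R_i``, reported at interior vertices (tristars at the
    periphery are not closed)."""
    if g.q is None:
        raise ValueError("call kites() first")
    inc = g.inc
    F = np.zeros((inc.n_vertices, 2, 2))
    interior = set(inc.interior_vertices.tolist())
    for cid in range(inc.n_corners):
        k = inc.corner_vertex[cid]
        if k not in interior:
            continue
        w_in, w_out = g.w[cid]
        # B_ij A_jk = +1 for the inbound edge of the corner, -1 for the outbound
        F[k] += 0.5 * (np.outer(w_in, w_in) - np.outer(w_out, w_out))
    g.fabric = F
    return F


# ---------------------------------------------------------------------- #
def vertex_triangles(g: GeometryCache) -> GeometryCache:
    """Edge-centroid triangles around interior vertices.

    For each interior vertex k the three corners (i, k) are ordered so that
    the link ``s_ik`` of each corner is followed head-to-tail by the next:
    the triangle of edge centroids runs anticlockwise, its area is ``a_k``
    and ``h_ik`` is the altitude onto side ``s_ik`` (from the opposite
    triangle vertex, the centroid of the edge radiating outward from cell
    i at k)."""
    inc = g.inc
    g.a_k = np.zeros(inc.n_vertices)
    g.altitude = np.zeros(inc.n_corners)
    g.opposite = np.full(inc.n_corners, -1, dtype=int)
    g.tri_vertices = {}
    g.tri_corners = {}
    for k in inc.interior_vertices:
        cids = inc.corners_of_vertex(k)
        if len(cids) != 3:
            raise TopologyError(f"interior vertex {k} is not a trijunction")
        # successor of corner c: the corner whose outbound edge is c's inbound
        by_jout = {inc.corner_jout[c]: c for c in cids}
        c0 = cids[0]
        order = [c0]
        for _ in range(2):
            order.append(by_jout[inc.corner_jin[order[-1]]])
        order = np.array(order)
        # triangle vertices: centroid of jout of each ordered corner
        tri_edges = inc.corner_jout[order]
        pts = g.c[tri_edges]
        area = polygon_area(pts)
        if area <= 0:  # ordering convention makes the loop anticlockwise
            order = order[::-1]
            tri_edges = inc.corner_jout[order]
            pts = g.c[tri_edges]
            area = polygon_area(pts)
        scale = max(g.t_len.max(), 1.0)
        if abs(area) < (DEGENERATE_REL_TOL * scale) ** 2:
            raise DegenerateGeometryError(
                f"collinear edge-centroid triangle at vertex {k}")
        g.a_k[k] = area
        g.tri_vertices[k] = tri_edges
        g.tri_corners[k] = order
        for c in order:
            i = inc.corner_cell[c]
            g.opposite[c] = inc.opposite_edge(i, k)
            base = np.hypot(*g.s[c])
            g.altitude[c] = 2.0 * area / base
    return g


def orientation_apply(mesh: Monolayer, rotation: np.ndarray, shift: np.ndarray) -> Monolayer:
    """Convenience for frame-indifference checks: r -> Y r + Z."""
    return mesh.with_vertices(mesh.vertices @ np.asarray(rotation).T + np.asarray(shift))
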