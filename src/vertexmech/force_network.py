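"""Maxwell-Cremona force network and the vector force potential h_j.

Rotating every balanced force ``f_ik`` anticlockwise by pi/2 (``-eps f``)
produces a reciprocal network with the topology of the edge-centroid
network: rotated forces close into triangles around interior vertices and
polygons around cells.  Its vertices, one per primal edge, define the
vector force potential ``h_j``:

    h_{j_in(i,k)} - h_{j_out(i,k)} = -eps f_ik          (per kite)
    f_ik = -sum_j eps_i B_ij h_j A_jk                   (inverse)

``h`` is integrated over a breadth-first spanning tree of the kite graph
from an anchor peripheral edge (whose ``h`` is pinned at the origin); loop
closure residuals vanish exactly when the vertex force balances hold, and
the per-cell/per-vertex torque scalars ``sum_j B_ij h_j . t_j`` and
``sum_j A_jk h_j . T_j`` vanish exactly when the corresponding stress
tensors are symmetric.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .constitutive import ForceState
from .geometry import GeometryCache
from .topology import EPS, EPS_CELL, IncidenceSet

__all__ = [
    "ForcePotential",
    "NonEquilibriumError",
    "rotate_forces",
    "build_potential",
    "reconstruct_forces",
    "torque_residuals",
    "peripheral_loop",
]


class NonEquilibriumError(RuntimeError):
    """Force loops fail to close: the state is not force balanced and the
    potential h would be path dependent."""


@dataclass
class ForcePotential:
    """Force-network vertices ``h_j`` with provenance and residuals."""

    geom: GeometryCache
    h: np.ndarray                 # (N_e, 2)
    f: np.ndarray                 # (n_corners, 2) forces used to build h
    anchor: int                   # peripheral edge with h = 0
    loop_residual: float          # worst kite-equation defect
    vertex_residuals: np.ndarray  # |sum_i C_ik (-eps f_ik)| interior vertices
    cell_residuals: np.ndarray    # |sum_k C_ik (-eps f_ik)| per cell


def rotate_forces(fs: ForceState) -> np.ndarray:
    """Rotated force vectors ``-eps f_ik`` (anticlockwise by pi/2)."""
    return fs.f @ (-EPS).T


def build_potential(fs_or_f, inc: IncidenceSet, geom: GeometryCache,
                    tol: float | None = None) -> ForcePotential:
    """Integrate ``h_j`` over a spanning tree of the kite graph.

    ``fs_or_f`` is a :class:`ForceState` or a raw per-corner force array.
    Edges are adjacent when they are consecutive in some cell (they then
    share the kite of a corner).  Raises :class:`NonEquilibriumError` when
    any interior vertex is out of balance beyond ``tol`` (default
    ``1e-8 max|f| diameter``), since ``h`` would then be path dependent.
    """
    f = fs_or_f.f if isinstance(fs_or_f, ForceState) else np.asarray(fs_or_f)
    rot = f @ (-EPS).T
    fscale = float(np.abs(f).max()) if f.size else 0.0
    if tol is None:
        tol = 1e-8 * max(fscale, 1e-300) * geom.mesh.diameter()

    net_v = np.zeros((inc.n_vertices, 2))
    np.add.at(net_v, inc.corner_vertex, rot)
    vres = np.hypot(*net_v[inc.interior_vertices].T) if len(inc.interior_vertices) \
        else np.zeros(0)
    net_c = np.zeros((inc.n_cells, 2))
    np.add.at(net_c, inc.corner_cell, rot)
    cres = np.hypot(*net_c.T)
    if fscale > 0 and vres.size and vres.max() > tol:
        k = inc.interior_vertices[int(np.argmax(vres))]
        raise NonEquilibriumError(
            f"force loop around vertex {k} fails to close "
            f"(|residual| = {vres.max():.3e} > tol = {tol:.3e})")

    # kite graph: h[jin] - h[jout] = rot_f for every corner
    adj: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(inc.n_edges)]
    for cid in range(inc.n_corners):
        jin, jout = inc.corner_jin[cid], inc.corner_jout[cid]
        adj[jout].append((jin, rot[cid]))
        adj[jin].append((jout, -rot[cid]))

    anchor = int(inc.peripheral_edges.min()) if len(inc.peripheral_edges) \
        else 0
    h = np.full((inc.n_edges, 2), np.nan)
    h[anchor] = 0.0
    seen = np.zeros(inc.n_edges, dtype=bool)
    seen[anchor] = True
    queue = deque([anchor])
    while queue:
        j = queue.popleft()
        for j2, step in adj[j]:
            if not seen[j2]:
                seen[j2] = True
                h[j2] = h[j] + step
                queue.append(j2)
    if not seen.all():
        raise NonEquilibriumError("kite graph is disconnected")

    worst = 0.0
    for cid in range(inc.n_corners):
        d = h[inc.corner_jin[cid]] - h[inc.corner_jout[cid]] - rot[cid]
        worst = max(worst, float(np.abs(d).max()))
    return ForcePotential(geom=geom, h=h, f=f, anchor=anchor,
                          loop_residual=worst,
                          vertex_residuals=np.asarray(vres),
                          cell_residuals=cres)


def reconstruct_forces(fp: ForcePotential, inc: IncidenceSet) -> np.ndarray:
    """Invert the potential: ``f_ik = -sum_j eps_i B_ij h_j A_jk``."""
    f = np.empty((inc.n_corners, 2))
    for cid in range(inc.n_corners):
        jin, jout = inc.corner_jin[cid], inc.corner_jout[cid]
        # B_ij A_jk = +1 for the inbound edge, -1 for the outbound one
        f[cid] = -(EPS_CELL @ (fp.h[jin] - fp.h[jout]))
    return f


def torque_residuals(fp: ForcePotential, inc: IncidenceSet,
                     T_links: np.ndarray | None = None) -> dict:
    """Torque-imbalance diagnostics.

    Per cell: ``sum_j B_ij h_j . t_j`` (zero iff sigma_i symmetric); per
    interior vertex (requires dual links ``T_links``):
    ``sum_j A_jk h_j . T_j`` (zero iff sigma_k symmetric).
    """
    geom = fp.geom
    cell = np.zeros(inc.n_cells)
    for i, ed in enumerate(inc.cell_edges):
        cell[i] = sum(s * float(fp.h[j] @ geom.t_vec[j]) for j, s in ed)
    out = {"cell": cell}
    if T_links is not None:
        vertex = np.zeros(inc.n_vertices)
        Adata = inc.A
        for k in inc.interior_vertices:
            tot = 0.0
            for j in inc.vertex_edges[k]:
                ajk = int(Adata[j, k])
                tot += ajk * float(fp.h[j] @ T_links[j])
            vertex[k] = tot
        out["vertex"] = vertex
    return out


def peripheral_loop(fp: ForcePotential, inc: IncidenceSet) -> dict:
    """The closed loop of peripheral ``h_j`` (the image of the boundary).

    Returns the loop ordered along the boundary, its signed area (sign
    tracks the sign of P_ext: positive = anticlockwise under boundary
    tension) and, versus the peripheral edge-centroid polygon, the
    segment-length ratios whose constancy expresses shape similarity.
    """
    loop_v = inc.boundary_loop
    if loop_v is None:
        raise ValueError("call topology.partition() first")
    geom = fp.geom
    # peripheral edges ordered along the boundary loop
    edge_of = {}
    for j in inc.peripheral_edges:
        t, h_ = inc.edges[j]
        edge_of[frozenset((int(t), int(h_)))] = int(j)
    ordered = [edge_of[frozenset((int(loop_v[m]), int(loop_v[(m + 1) % len(loop_v)])))]
               for m in range(len(loop_v))]
    hpts = fp.h[ordered]
    cpts = geom.c[ordered]
    x, y = hpts[:, 0], hpts[:, 1]
    signed_area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    dh = np.roll(hpts, -1, axis=0) - hpts
    dc = np.roll(cpts, -1, axis=0) - cpts
    ratios = np.hypot(*dh.T) / np.hypot(*dc.T)
    return {"edges": np.array(ordered), "h": hpts, "signed_area": signed_area,
            "ratios": ratios}
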