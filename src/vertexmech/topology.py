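"""Combinatorial structure of a confluent planar monolayer.

A monolayer is a simply connected patch of polygonal cells tiling part of
the plane.  Cell boundaries form the *primal* network: vertices
``r_k`` (k = 1..N_v), oriented edges ``t_j`` (j = 1..N_e) and oriented cell
faces (i = 1..N_c).  The topology is encoded in two signed incidence
matrices:

* ``A`` (N_e x N_v): ``A[j, k] = +1`` if edge j points into vertex k,
  ``-1`` if it points out of it;
* ``B`` (N_c x N_e): ``B[i, j] = +1`` if edge j is traversed coherently
  with the (anticlockwise) orientation of cell i, ``-1`` if against it.

``B @ A = 0`` expresses that every cell boundary is a closed loop.  The
unsigned variants ``Abar``/``Bbar`` give adjacency without orientation and
``C = Bbar @ Abar / 2`` is the 0/1 cell-vertex adjacency matrix.

Rotation conventions used throughout the package: ``EPS`` is the 2-D
Levi-Civita generator (a *clockwise* rotation by pi/2, ``EPS @ EPS = -I``);
all cells are stored anticlockwise, so the cell orientation tensor is
``EPS_CELL = -EPS`` and the triangles around vertices carry the opposite
orientation ``EPS_TRI = +EPS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "EPS",
    "EPS_CELL",
    "EPS_TRI",
    "Monolayer",
    "IncidenceSet",
    "TopologyError",
    "TrijunctionError",
    "build_incidence",
    "partition",
    "validate",
    "polygon_area",
]

# Clockwise pi/2 rotation generator: EPS @ EPS = -I, EPS.T = -EPS.
EPS = np.array([[0.0, 1.0], [-1.0, 0.0]])
# Orientation tensor of (anticlockwise) cells and of vertex triangles.
EPS_CELL = -EPS
EPS_TRI = EPS

# Edge partition labels.
EDGE_PERIPHERAL, EDGE_BORDER, EDGE_INTERIOR = 0, 1, 2
VERTEX_PERIPHERAL, VERTEX_INTERIOR = 0, 1
CELL_BORDER, CELL_INTERIOR = 0, 1


class TopologyError(ValueError):
    """Raised for non-manifold or non-simply-connected input meshes."""


class TrijunctionError(TopologyError):
    """Raised when an interior vertex is not a three-way junction."""


def polygon_area(points: np.ndarray) -> float:
    """Signed (shoelace) area of a closed polygon given as an (n, 2) array."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Monolayer:
    """A polygonal monolayer: vertex positions plus one vertex loop per cell.

    Cell loops are stored anticlockwise (positive shoelace area); the edge
    list and all incidence signs are derived, never user supplied.
    """

    vertices: np.ndarray  # (N_v, 2) float
    cells: list[list[int]]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N_v, 2) array")
        self.cells = [[int(k) for k in loop] for loop in self.cells]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_polygon(self, i: int) -> np.ndarray:
        return self.vertices[self.cells[i]]

    def cell_areas(self) -> np.ndarray:
        """Shoelace area per cell (positive for anticlockwise loops)."""
        return np.array([polygon_area(self.cell_polygon(i)) for i in range(self.n_cells)])

    def normalized(self) -> "Monolayer":
        """Copy with every cell loop forced anticlockwise."""
        cells = [loop if polygon_area(self.vertices[loop]) > 0 else loop[::-1]
                 for loop in self.cells]
        return Monolayer(self.vertices.copy(), cells)

    def with_vertices(self, vertices: np.ndarray) -> "Monolayer":
        return Monolayer(np.asarray(vertices, dtype=float), [list(c) for c in self.cells])

    def diameter(self) -> float:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(np.hypot(*(hi - lo)))


@dataclass
class IncidenceSet:
    """Incidence matrices, corner tables and boundary partition of a mesh.

    Besides ``A``, ``B``, ``C`` this carries a flat *corner* table indexing
    the cell-vertex incidences ``(i, k)``: every per-kite quantity in the
    package (links ``s_ik``, spokes ``q_ik``, forces ``f_ik``, Airy values
    ``psi_ik``, ...) is stored as an array over corners.
    """

    mesh: Monolayer
    A: sp.csr_matrix  # (N_e, N_v) signed
    B: sp.csr_matrix  # (N_c, N_e) signed
    edges: np.ndarray  # (N_e, 2) [tail, head] with tail < head
    edge_cells: list[list[tuple[int, int]]]  # per edge: [(cell, B sign)]
    cell_edges: list[list[tuple[int, int]]]  # per cell: loop-ordered [(edge, sign)]

    # corner table: one entry per (cell, vertex) incidence, loop ordered
    corner_cell: np.ndarray = field(default=None)
    corner_vertex: np.ndarray = field(default=None)
    corner_jin: np.ndarray = field(default=None)   # edge arriving at the vertex
    corner_jout: np.ndarray = field(default=None)  # edge leaving the vertex
    corner_index: dict = field(default_factory=dict)  # (i, k) -> corner id

    vertex_label: np.ndarray = field(default=None)  # 0 peripheral / 1 interior
    edge_label: np.ndarray = field(default=None)    # 0 peripheral / 1 border / 2 interior
    cell_label: np.ndarray = field(default=None)    # 0 border / 1 interior
    vertex_edges: list = field(default=None)        # incident edges per vertex
    boundary_loop: np.ndarray = field(default=None)  # peripheral vertices in boundary order
    blocks: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    @property
    def n_vertices(self) -> int:
        return self.A.shape[1]

    @property
    def n_edges(self) -> int:
        return self.A.shape[0]

    @property
    def n_cells(self) -> int:
        return self.B.shape[0]

    @property
    def n_corners(self) -> int:
        return len(self.corner_cell)

    @property
    def Abar(self) -> sp.csr_matrix:
        return abs(self.A)

    @property
    def Bbar(self) -> sp.csr_matrix:
        return abs(self.B)

    @property
    def C(self) -> sp.csr_matrix:
        C = (self.Bbar @ self.Abar).tocsr()
        C.data //= 2
        C.eliminate_zeros()
        return C

    @property
    def Z(self) -> np.ndarray:
        """Number of edges (= vertices) of each cell."""
        return np.array([len(loop) for loop in self.mesh.cells])

    # convenience masks ------------------------------------------------- #
    @property
    def interior_vertices(self) -> np.ndarray:
        return np.flatnonzero(self.vertex_label == VERTEX_INTERIOR)

    @property
    def peripheral_vertices(self) -> np.ndarray:
        return np.flatnonzero(self.vertex_label == VERTEX_PERIPHERAL)

    @property
    def interior_edges(self) -> np.ndarray:
        return np.flatnonzero(self.edge_label == EDGE_INTERIOR)

    @property
    def border_edges(self) -> np.ndarray:
        return np.flatnonzero(self.edge_label == EDGE_BORDER)

    @property
    def peripheral_edges(self) -> np.ndarray:
        return np.flatnonzero(self.edge_label == EDGE_PERIPHERAL)

    @property
    def nonperipheral_edges(self) -> np.ndarray:
        return np.flatnonzero(self.edge_label != EDGE_PERIPHERAL)

    @property
    def n_peripheral(self) -> int:
        return int(np.sum(self.vertex_label == VERTEX_PERIPHERAL))

    @property
    def n_border(self) -> int:
        return int(np.sum(self.edge_label == EDGE_BORDER))

    def corners_of_vertex(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.corner_vertex == k)

    def corners_of_cell(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.corner_cell == i)

    def opposite_edge(self, i: int, k: int) -> int:
        """The edge radiating outward from cell i at trijunction k.

        Selected by ``Abar[j, k] (C[i, k] - Bbar[i, j]) = 1``: incident to
        the vertex but not an edge of the cell.
        """
        own = {self.corner_jin[self.corner_index[i, k]],
               self.corner_jout[self.corner_index[i, k]]}
        for j in self.vertex_edges[k]:
            if j not in own:
                return j
        raise TopologyError(f"vertex {k} has no edge opposite cell {i}")


# ---------------------------------------------------------------------- #
def build_incidence(mesh: Monolayer) -> IncidenceSet:
    """Derive edges and the signed incidence matrices from the cell loops.

    Edges are oriented from the lower to the higher vertex index.  Raises
    :class:`TopologyError` for non-manifold edges (shared by more than two
    cells) and :class:`TrijunctionError` for interior vertices whose degree
    is not three.
    """
    mesh = mesh.normalized()
    n_v = mesh.n_vertices
    for i, loop in enumerate(mesh.cells):
        if len(loop) < 3 or len(set(loop)) != len(loop):
            raise TopologyError(f"cell {i} is not a simple loop of >=3 distinct vertices")

    edge_id: dict[tuple[int, int], int] = {}
    edges: list[tuple[int, int]] = []
    edge_cells: list[list[tuple[int, int]]] = []
    cell_edges: list[list[tuple[int, int]]] = []
    for i, loop in enumerate(mesh.cells):
        this = []
        for m, k in enumerate(loop):
            k2 = loop[(m + 1) % len(loop)]
            key = (min(k, k2), max(k, k2))
            j = edge_id.get(key)
            if j is None:
                j = len(edges)
                edge_id[key] = j
                edges.append(key)
                edge_cells.append([])
            sign = 1 if (k, k2) == key else -1
            if len(edge_cells[j]) >= 2:
                raise TopologyError(f"edge {key} shared by more than two cells")
            if any(c == i for c, _ in edge_cells[j]):
                raise TopologyError(f"edge {key} repeated within cell {i}")
            edge_cells[j].append((i, sign))
            this.append((j, sign))
        cell_edges.append(this)

    n_e = len(edges)
    edges_arr = np.array(edges, dtype=int)

    rows = np.repeat(np.arange(n_e), 2)
    cols = edges_arr.ravel()
    vals = np.tile([-1, 1], n_e)  # tail -1, head +1
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_e, n_v), dtype=np.int64)

    bi, bj, bv = [], [], []
    for i, this in enumerate(cell_edges):
        for j, sign in this:
            bi.append(i)
            bj.append(j)
            bv.append(sign)
    B = sp.csr_matrix((bv, (bi, bj)), shape=(mesh.n_cells, n_e), dtype=np.int64)

    inc = IncidenceSet(mesh=mesh, A=A, B=B, edges=edges_arr,
                       edge_cells=edge_cells, cell_edges=cell_edges)
    _build_corners(inc)
    _classify(inc)
    return inc


def _build_corners(inc: IncidenceSet) -> None:
    cc, cv, jin, jout = [], [], [], []
    for i, loop in enumerate(inc.mesh.cells):
        ed = inc.cell_edges[i]
        n = len(loop)
        for m, k in enumerate(loop):
            cc.append(i)
            cv.append(k)
            jin.append(ed[(m - 1) % n][0])
            jout.append(ed[m][0])
    inc.corner_cell = np.array(cc, dtype=int)
    inc.corner_vertex = np.array(cv, dtype=int)
    inc.corner_jin = np.array(jin, dtype=int)
    inc.corner_jout = np.array(jout, dtype=int)
    inc.corner_index = {(i, k): c for c, (i, k) in enumerate(zip(cc, cv))}

    vertex_edges: list[list[int]] = [[] for _ in range(inc.n_vertices)]
    for j, (t, h) in enumerate(inc.edges):
        vertex_edges[t].append(j)
        vertex_edges[h].append(j)
    inc.vertex_edges = vertex_edges


def _classify(inc: IncidenceSet) -> None:
    n_cells_of_edge = np.array([len(ec) for ec in inc.edge_cells])
    boundary_edges = np.flatnonzero(n_cells_of_edge == 1)

    vlabel = np.full(inc.n_vertices, VERTEX_INTERIOR, dtype=int)
    vlabel[inc.edges[boundary_edges].ravel()] = VERTEX_PERIPHERAL
    inc.vertex_label = vlabel

    deg = np.array([len(e) for e in inc.vertex_edges])
    bad = np.flatnonzero((vlabel == VERTEX_INTERIOR) & (deg != 3))
    if bad.size:
        raise TrijunctionError(
            f"interior vertices {bad.tolist()} have degree {deg[bad].tolist()} != 3")

    elabel = np.empty(inc.n_edges, dtype=int)
    both_int = vlabel[inc.edges].sum(axis=1)  # 0, 1 or 2 interior endpoints
    elabel[:] = EDGE_BORDER
    elabel[n_cells_of_edge == 1] = EDGE_PERIPHERAL
    elabel[(n_cells_of_edge == 2) & (both_int == 2)] = EDGE_INTERIOR
    inc.edge_label = elabel

    clabel = np.array([CELL_INTERIOR if all(vlabel[k] == VERTEX_INTERIOR for k in loop)
                       else CELL_BORDER for loop in inc.mesh.cells])
    inc.cell_label = clabel


# ---------------------------------------------------------------------- #
def partition(inc: IncidenceSet) -> IncidenceSet:
    """Trace the boundary loop and expose the block decomposition of A, B, C.

    Vertices are ordered [peripheral, interior], edges [peripheral, border,
    interior] and cells [border, interior]; the permuted matrices and their
    named blocks (``App``, ``Abp``, ``Abi``, ``Aii``, ``Bbp`` ... ``Cii``)
    are stored in ``inc.blocks``.  Raises :class:`TopologyError` if the
    boundary is not a single closed loop (monolayer not simply connected).
    """
    # Walk the boundary: each peripheral vertex joins exactly two
    # peripheral edges of a simply connected monolayer.
    nbr: dict[int, list[int]] = {}
    for j in inc.peripheral_edges:
        t, h = inc.edges[j]
        nbr.setdefault(t, []).append(h)
        nbr.setdefault(h, []).append(t)
    if any(len(v) != 2 for v in nbr.values()):
        raise TopologyError("boundary is not a union of simple closed loops")
    if nbr:
        start = min(nbr)
        loop = [start]
        prev, cur = None, start
        while True:
            a, b = nbr[cur]
            nxt = b if a == prev else a
            if nxt == start:
                break
            loop.append(nxt)
            prev, cur = cur, nxt
        if len(loop) != len(nbr):
            raise TopologyError("boundary has multiple loops: monolayer is "
                                "not simply connected")
        inc.boundary_loop = np.array(loop, dtype=int)
    else:
        inc.boundary_loop = np.array([], dtype=int)

    vorder = np.concatenate([inc.peripheral_vertices, inc.interior_vertices])
    eorder = np.concatenate([inc.peripheral_edges, inc.border_edges, inc.interior_edges])
    corder = np.concatenate([np.flatnonzero(inc.cell_label == CELL_BORDER),
                             np.flatnonzero(inc.cell_label == CELL_INTERIOR)])
    Ap = inc.A[eorder][:, vorder]
    Bp = inc.B[corder][:, eorder]
    Cp = inc.C[corder][:, vorder]
    n_p = inc.n_peripheral
    n_b = inc.n_border
    n_bc = int(np.sum(inc.cell_label == CELL_BORDER))
    ne_p, ne_b = len(inc.peripheral_edges), n_b
    blocks = {
        "vertex_order": vorder, "edge_order": eorder, "cell_order": corder,
        "A": Ap, "B": Bp, "C": Cp,
        "App": Ap[:ne_p, :n_p], "Api_zero": Ap[:ne_p, n_p:],
        "Abp": Ap[ne_p:ne_p + ne_b, :n_p], "Abi": Ap[ne_p:ne_p + ne_b, n_p:],
        "Aip_zero": Ap[ne_p + ne_b:, :n_p], "Aii": Ap[ne_p + ne_b:, n_p:],
        "Bbp": Bp[:n_bc, :ne_p], "Bbb": Bp[:n_bc, ne_p:ne_p + ne_b],
        "Bbi": Bp[:n_bc, ne_p + ne_b:],
        "Bip_zero": Bp[n_bc:, :ne_p], "Bib_zero": Bp[n_bc:, ne_p:ne_p + ne_b],
        "Bii": Bp[n_bc:, ne_p + ne_b:],
        "Cbp": Cp[:n_bc, :n_p], "Cbi": Cp[:n_bc, n_p:],
        "Cip_zero": Cp[n_bc:, :n_p], "Cii": Cp[n_bc:, n_p:],
        "N_p": n_p, "N_b": n_b,
    }
    inc.blocks = blocks
    return inc


# ---------------------------------------------------------------------- #
def validate(inc: IncidenceSet) -> dict:
    """Structured report of every topological invariant, with offenders.

    Report-only: never raises.  Checks loop closure (``BA = 0``), row
    structure of A, the C/Z consistency, the trijunction condition, edge
    manifoldness, the Euler relation and positivity of cell areas.
    """
    checks = {}

    BA = (inc.B @ inc.A).tocoo()
    bad = [(int(i), int(k)) for i, k, v in zip(BA.row, BA.col, BA.data) if v != 0]
    checks["loops_closed_BA"] = {"pass": not bad, "offenders": bad}

    rows_ok = ((inc.A != 0).sum(axis=1).A1 == 2) & (inc.A.sum(axis=1).A1 == 0)
    checks["edge_rows"] = {"pass": bool(rows_ok.all()),
                           "offenders": np.flatnonzero(~rows_ok).tolist()}

    z_ok = inc.C.sum(axis=1).A1 == inc.Z
    checks["cell_valence"] = {"pass": bool(z_ok.all()) and bool((inc.Z >= 3).all()),
                              "offenders": np.flatnonzero(~z_ok).tolist()}

    deg = np.array([len(e) for e in inc.vertex_edges])
    tri_bad = np.flatnonzero((inc.vertex_label == VERTEX_INTERIOR) & (deg != 3))
    checks["trijunctions"] = {"pass": tri_bad.size == 0, "offenders": tri_bad.tolist()}

    ncells = np.array([len(ec) for ec in inc.edge_cells])
    man_bad = np.flatnonzero(ncells > 2)
    # A one-cell edge whose endpoints are both interior is a hole in the tiling.
    hole = [int(j) for j in np.flatnonzero(ncells == 1)
            if inc.vertex_label[inc.edges[j]].sum() == 2]
    checks["manifold"] = {"pass": man_bad.size == 0 and not hole,
                          "offenders": man_bad.tolist() + hole}

    euler = inc.n_cells - inc.n_edges + inc.n_vertices
    checks["euler"] = {"pass": euler == 1, "value": int(euler)}

    areas = inc.mesh.cell_areas()
    checks["positive_areas"] = {"pass": bool((areas > 0).all()),
                                "offenders": np.flatnonzero(areas <= 0).tolist()}

    mixed = [int(j) for j in np.flatnonzero(ncells == 2)
             if inc.vertex_label[inc.edges[j]].sum() == 0]
    checks["border_edges_mixed"] = {
        "pass": not mixed, "offenders": mixed,
        "note": "two-cell edges with both endpoints peripheral break the "
                "block structure of A"}

    checks["pass"] = all(c["pass"] for c in checks.values())
    return checks
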