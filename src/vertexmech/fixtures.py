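"""Deterministic synthetic monolayers for experiments and tests.

Three generator families: regular honeycombs (the symmetric reference
lattice on which every closed-form identity of the theory can be checked),
bounded random Voronoi monolayers (disordered but valid trijunction meshes)
and random perturbations of an existing mesh.  Identical arguments and seed
give bit-identical meshes.
"""

from __future__ import annotations

import numpy as np

from .topology import Monolayer, TopologyError, build_incidence, polygon_area

__all__ = [
    "honeycomb",
    "fig_flower",
    "voronoi_monolayer",
    "perturb",
    "three_cell_orthocentric",
]

_HEX_DIRS = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]


def honeycomb(n_rings: int, side: float = 1.0) -> Monolayer:
    """Central regular hexagon plus ``n_rings`` full rings of hexagons.

    The cell count is the centred hexagonal number ``1 + 3 n (n + 1)``;
    one ring (7 cells) has 30 edges and 24 vertices.
    """
    if n_rings < 0:
        raise ValueError("n_rings must be >= 0")
    centres_ax = [(0, 0)]
    for ring in range(1, n_rings + 1):
        q, r = ring * _HEX_DIRS[4][0], ring * _HEX_DIRS[4][1]
        for d in range(6):
            for _ in range(ring):
                centres_ax.append((q, r))
                q += _HEX_DIRS[d][0]
                r += _HEX_DIRS[d][1]
    # pointy-top axial layout; vertices at angles 30 + 60 m degrees
    verts: dict[tuple[int, int], int] = {}
    coords: list[np.ndarray] = []
    cells = []
    ang = np.deg2rad(30 + 60 * np.arange(6))
    offs = side * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    for q, r in centres_ax:
        cx = side * np.sqrt(3.0) * (q + r / 2.0)
        cy = side * 1.5 * r
        loop = []
        for o in offs:
            key = (round((cx + o[0]) / side * 1e9), round((cy + o[1]) / side * 1e9))
            if key not in verts:
                verts[key] = len(coords)
                coords.append(np.array([cx + o[0], cy + o[1]]))
            loop.append(verts[key])
        cells.append(loop)
    return Monolayer(np.array(coords), cells).normalized()


def fig_flower(side: float = 1.0) -> Monolayer:
    """The seven-cell flower (one interior cell, six border cells)."""
    return honeycomb(1, side)


def voronoi_monolayer(n_cells: int, box: float = 1.0, seed: int = 0,
                      max_tries: int = 20) -> Monolayer:
    """Bounded Voronoi tessellation of uniform random seeds in a square box.

    Seeds are mirrored across all four box edges so every original cell is
    bounded and clipped exactly to the box; the union of cells tiles the
    box (simply connected, confluent).  Near-coincident Voronoi vertices
    (from nearly cocircular seeds) are merged; configurations that still
    violate the interior-trijunction condition are retried with a fresh
    substream of the generator.
    """
    from scipy.spatial import Voronoi

    if n_cells < 3:
        raise TopologyError("need at least 3 cells")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pts = rng.uniform(0.05 * box, 0.95 * box, size=(n_cells, 2))
        mirrored = [pts]
        for axis, at in ((0, 0.0), (0, box), (1, 0.0), (1, box)):
            m = pts.copy()
            m[:, axis] = 2 * at - m[:, axis]
            mirrored.append(m)
        vor = Voronoi(np.vstack(mirrored))
        try:
            mesh = _regions_to_mesh(vor, n_cells, box)
            build_incidence(mesh)  # raises on trijunction violations
            return mesh
        except (TopologyError, ValueError):
            continue
    raise TopologyError(f"no valid Voronoi monolayer after {max_tries} tries")


def _regions_to_mesh(vor, n_cells: int, box: float) -> Monolayer:
    tol = 1e-9 * box
    snapped: dict[tuple[int, int], int] = {}
    coords: list[np.ndarray] = []

    def snap(p: np.ndarray) -> int:
        q = np.clip(p, 0.0, box)
        key = (round(q[0] / tol / 8), round(q[1] / tol / 8))
        if key not in snapped:
            snapped[key] = len(coords)
            coords.append(q)
        return snapped[key]

    cells = []
    for p in range(n_cells):
        region = vor.regions[vor.point_region[p]]
        if -1 in region or len(region) < 3:
            raise TopologyError("unbounded Voronoi region")
        loop = []
        for v in region:
            idx = snap(vor.vertices[v])
            if not loop or (idx != loop[-1] and idx != loop[0]):
                loop.append(idx)
        if len(loop) < 3:
            raise TopologyError("degenerate Voronoi cell")
        cells.append(loop)
    mesh = Monolayer(np.array(coords), cells).normalized()
    if np.any(mesh.cell_areas() <= 0):
        raise TopologyError("degenerate Voronoi cell")
    return mesh


def perturb(mesh: Monolayer, amplitude: float, seed: int = 0,
            freeze_boundary: bool = True, max_tries: int = 20) -> Monolayer:
    """I.i.d. uniform vertex displacements in ``[-amplitude, amplitude]^2``.

    Boundary vertices are frozen by default.  Retries (then raises) if a
    displaced configuration stops being a union of simple positive-area
    polygons.
    """
    if amplitude == 0:
        return mesh.with_vertices(mesh.vertices)
    inc = build_incidence(mesh)
    movable = np.ones(mesh.n_vertices, dtype=bool)
    if freeze_boundary:
        movable[inc.peripheral_vertices] = False
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        disp = rng.uniform(-amplitude, amplitude, size=mesh.vertices.shape)
        disp[~movable] = 0.0
        cand = mesh.with_vertices(mesh.vertices + disp)
        if _all_simple(cand):
            return cand
    raise ValueError("perturbation produced self-intersecting cells")


def _all_simple(mesh: Monolayer) -> bool:
    try:
        from shapely.geometry import Polygon
    except ImportError:  # pragma: no cover
        return bool((mesh.cell_areas() > 0).all())
    return all(Polygon(mesh.cell_polygon(i)).is_valid and
               polygon_area(mesh.cell_polygon(i)) > 0
               for i in range(mesh.n_cells))


def three_cell_orthocentric(inner: float = 1.0, outer: float = 1.6) -> Monolayer:
    """Three congruent rhombi meeting at a central trijunction.

    With exact threefold symmetry every internal vertex (here just the
    centre) lies at the orthocentre of its edge-centroid triangle, so the
    configuration satisfies the torque-balance geometry exactly and admits
    an orthogonal dual network of cell centres.
    """
    a_ang = np.deg2rad([90.0, 210.0, 330.0])
    b_ang = np.deg2rad([150.0, 270.0, 30.0])
    a = inner * np.stack([np.cos(a_ang), np.sin(a_ang)], axis=1)
    b = outer * np.stack([np.cos(b_ang), np.sin(b_ang)], axis=1)
    coords = np.vstack([[0.0, 0.0], a, b])  # 0 centre, 1..3 inner, 4..6 outer
    cells = [[0, 1 + m, 4 + m, 1 + (m + 1) % 3] for m in range(3)]
    return Monolayer(coords, cells).normalized()
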