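"""Readers and writers: the VMJSON mesh dialect, CSV tables and reports.

VMJSON v1 is a minimal JSON mesh format::

    {"vertices": [[x, y], ...], "cells": [[v0, v1, ...], ...]}

with 0-based vertex indices and anticlockwise loops; the writer normalizes
orientation and the reader fixes (with a warning) clockwise input.  The
dual network uses the companion dialect
``{"centres": [[x, y], ...], "links": [[cell_a, cell_b], ...]}``.

Segmented data can be ingested as plain-text polygons (one polygon per
line, whitespace-separated ``x y x y ...`` pairs) that are merged into a
confluent mesh by snapping vertices within a tolerance.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .topology import IncidenceSet, Monolayer, polygon_area

__all__ = [
    "read_vmjson",
    "write_vmjson",
    "write_dual_vmjson",
    "read_polygons",
    "polygons_to_mesh",
    "VMJSONError",
]


class VMJSONError(ValueError):
    """Schema violation in a VMJSON document, with a JSON-pointer-ish path."""


def _check_schema(doc: dict, path: str) -> None:
    if not isinstance(doc, dict):
        raise VMJSONError(f"{path}: expected object, got {type(doc).__name__}")
    for key in ("vertices", "cells"):
        if key not in doc:
            raise VMJSONError(f"{path}/{key}: missing")
        if not isinstance(doc[key], list):
            raise VMJSONError(f"{path}/{key}: expected array")
    for m, v in enumerate(doc["vertices"]):
        if not (isinstance(v, list) and len(v) == 2
                and all(isinstance(x, (int, float)) for x in v)):
            raise VMJSONError(f"{path}/vertices/{m}: expected [x, y]")
    n_v = len(doc["vertices"])
    for i, loop in enumerate(doc["cells"]):
        if not (isinstance(loop, list) and len(loop) >= 3):
            raise VMJSONError(f"{path}/cells/{i}: expected a loop of >= 3 indices")
        for m, k in enumerate(loop):
            if not isinstance(k, int) or not (0 <= k < n_v):
                raise VMJSONError(
                    f"{path}/cells/{i}/{m}: vertex index {k} out of range "
                    f"[0, {n_v})")


def read_vmjson(path) -> Monolayer:
    """Read a VMJSON mesh; clockwise loops are normalized with a warning."""
    doc = json.loads(Path(path).read_text())
    _check_schema(doc, "#")
    mesh = Monolayer(np.array(doc["vertices"], dtype=float),
                     [list(map(int, loop)) for loop in doc["cells"]])
    flipped = [i for i, loop in enumerate(mesh.cells)
               if polygon_area(mesh.vertices[loop]) < 0]
    if flipped:
        warnings.warn(f"cells {flipped} were clockwise; normalized to "
                      "anticlockwise", stacklevel=2)
    return mesh.normalized()


def write_vmjson(mesh: Monolayer, path, metadata: dict | None = None) -> None:
    """Write a mesh (orientation-normalized) as VMJSON v1."""
    mesh = mesh.normalized()
    doc = {"vertices": mesh.vertices.tolist(),
           "cells": [list(map(int, loop)) for loop in mesh.cells]}
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=1))


def write_dual_vmjson(inc: IncidenceSet, centres: np.ndarray, path,
                      metadata: dict | None = None) -> None:
    links = [[int(inc.edge_cells[j][0][0]), int(inc.edge_cells[j][1][0])]
             for j in inc.nonperipheral_edges]
    doc = {"centres": np.asarray(centres).tolist(), "links": links}
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------- #
def read_polygons(path) -> list[np.ndarray]:
    """One polygon per line: ``x0 y0 x1 y1 ...`` (segmentation export)."""
    polys = []
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        vals = [float(x) for x in line.replace(",", " ").split()]
        if not vals:
            continue
        if len(vals) % 2 or len(vals) < 6:
            raise VMJSONError(f"line {ln}: expected >= 3 x,y pairs")
        polys.append(np.array(vals).reshape(-1, 2))
    return polys


def polygons_to_mesh(polygons: list[np.ndarray], merge_tol: float = 1e-6) -> Monolayer:
    """Merge per-cell polygons into a confluent mesh by snapping vertices
    that lie within ``merge_tol`` of each other."""
    coords: list[np.ndarray] = []
    cells = []
    for poly in polygons:
        loop = []
        for p in np.asarray(poly, dtype=float):
            idx = None
            for m, q in enumerate(coords):
                if np.hypot(*(p - q)) <= merge_tol:
                    idx = m
                    break
            if idx is None:
                idx = len(coords)
                coords.append(p)
            if not loop or (idx != loop[-1] and idx != loop[0]):
                loop.append(idx)
        if len(loop) < 3:
            raise VMJSONError("degenerate polygon after merging")
        cells.append(loop)
    return Monolayer(np.array(coords), cells).normalized()
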