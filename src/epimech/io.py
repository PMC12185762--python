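"""Mesh JSON documents and table CSV round-tripping.

The mesh document is plain JSON::

    {
      "vertices": [[x, y], ...],
      "edges":    [[tail, head], ...],
      "cells":    [{"edges": [...], "signs": [...], "age": ..,
                    "preferred_area": .., "stiffness": ..,
                    "is_mcc": .., "can_divide": .., "cycle_time": ..}, ...]
    }

Floats are serialised at full ``repr`` precision, so write -> read is lossless
to the bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import CellState, Mesh

__all__ = ["mesh_to_dict", "mesh_from_dict", "write_mesh", "read_mesh", "SchemaError"]


class SchemaError(ValueError):
    """A mesh document violating the schema, with a path-level message."""


_CELL_FIELDS = ("age", "preferred_area", "stiffness", "is_mcc", "can_divide", "cycle_time")


def mesh_to_dict(mesh: Mesh) -> dict:
    cells = []
    for eids, sgns, st in zip(mesh.cell_edges, mesh.cell_signs, mesh.cells):
        rec = {"edges": eids.tolist(), "signs": sgns.tolist()}
        rec.update({f: getattr(st, f) for f in _CELL_FIELDS})
        cells.append(rec)
    return {
        "vertices": mesh.vertices.tolist(),
        "edges": mesh.edges.tolist(),
        "cells": cells,
    }


def mesh_from_dict(doc: dict) -> Mesh:
    for key in ("vertices", "edges", "cells"):
        if key not in doc:
            raise SchemaError(f"missing top-level key '{key}'")
    vertices = np.asarray(doc["vertices"], dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2:
        raise SchemaError("'vertices' must be an array of [x, y] pairs")
    edges = np.asarray(doc["edges"], dtype=np.intp)
    if edges.size and (edges.ndim != 2 or edges.shape[1] != 2):
        raise SchemaError("'edges' must be an array of [tail, head] pairs")
    nv = len(vertices)
    for k, (t, h) in enumerate(edges):
        if not (0 <= t < nv and 0 <= h < nv):
            raise SchemaError(f"edges[{k}]: vertex index out of range")
        if t == h:
            raise SchemaError(f"edges[{k}]: degenerate edge ({t}, {h})")
    cell_edges, cell_signs, states = [], [], []
    ne = len(edges)
    for ci, rec in enumerate(doc["cells"]):
        try:
            eids = np.asarray(rec["edges"], dtype=np.intp)
            sgns = np.asarray(rec["signs"], dtype=np.intp)
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"cells[{ci}]: missing or malformed 'edges'/'signs'") from exc
        if len(eids) != len(sgns):
            raise SchemaError(f"cells[{ci}]: edges and signs differ in length")
        if np.any((eids < 0) | (eids >= ne)):
            bad = int(eids[(eids < 0) | (eids >= ne)][0])
            raise SchemaError(f"cells[{ci}]: edge index {bad} out of range")
        if np.any(np.abs(sgns) != 1):
            raise SchemaError(f"cells[{ci}]: signs must be +-1")
        cell_edges.append(eids)
        cell_signs.append(sgns)
        kw = {f: rec[f] for f in _CELL_FIELDS if f in rec}
        states.append(CellState(**kw))
    return Mesh(vertices, edges.reshape(-1, 2), cell_edges, cell_signs, states)


def write_mesh(mesh: Mesh, path: str | Path) -> None:
    Path(path).write_text(json.dumps(mesh_to_dict(mesh)))


def read_mesh(path: str | Path) -> Mesh:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    return mesh_from_dict(doc)
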