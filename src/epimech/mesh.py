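"""Planar polygonal mesh of an epithelial monolayer.

The monolayer is a simply connected patch of polygonal cells encoded by two
signed incidence matrices:

* ``A`` (edges x vertices): each row has one ``-1`` (tail) and one ``+1``
  (head), defining the edge vector ``r[head] - r[tail]``.
* ``B`` (cells x edges): ``+1`` where the cell traverses the edge tail->head
  in its counter-clockwise boundary loop, ``-1`` where it traverses it
  head->tail.

Closedness of every cell boundary is equivalent to ``B @ A == 0``: within a
loop each vertex is entered exactly once and left exactly once, so the signed
vertex counts cancel.  All cells are oriented counter-clockwise (positive
shoelace area); the outer boundary, traversed with the tissue on its left, is
then clockwise.

Coordinates are nondimensional; the unit of area is the bulk preferred cell
area (``A0 = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

__all__ = [
    "CellState",
    "Mesh",
    "TopologyReport",
    "build_hex_monolayer",
    "cell_geometry",
    "adjacency_graph",
    "peripheral_cells",
    "validate_topology",
]


@dataclass
class CellState:
    """Per-cell biological state carried alongside the geometry.

    ``stiffness`` is the prefactor sigma multiplying both the pressure and the
    tension force of the cell; multiciliated cells (MCCs) get sigma > 1 and
    are barred from dividing unless the dividing-MCC control is enabled.
    """

    age: float = 0.0
    preferred_area: float = 1.0
    stiffness: float = 1.0
    is_mcc: bool = False
    can_divide: bool = True
    cycle_time: float = 1.0

    def validate(self) -> None:
        if self.age < 0:
            raise ValueError("cell age must be non-negative")
        if self.preferred_area <= 0:
            raise ValueError("preferred area must be positive")
        if self.stiffness <= 0:
            raise ValueError("stiffness prefactor must be positive")

    def copy(self) -> "CellState":
        return replace(self)


class _LoopCache:
    """Flattened cell-boundary loops for vectorised geometry kernels.

    Every cell's counter-clockwise vertex loop is concatenated into flat
    arrays so areas, perimeters and their gradients are computed with
    ``bincount`` scatter/gather instead of per-cell Python loops.
    """

    __slots__ = ("cell_of", "vert", "nxt", "prv", "edge_of", "n_cells", "n_vertices",
                 "_prev_entry")

    def __init__(self, mesh: "Mesh") -> None:
        cell_of: list[int] = []
        vert: list[int] = []
        edge_of: list[int] = []
        for ci in range(mesh.n_cells):
            loop = mesh.cell_vertex_loop(ci)
            cell_of.extend([ci] * len(loop))
            vert.extend(loop)
            edge_of.extend(mesh.cell_edges[ci].tolist())
        self.cell_of = np.asarray(cell_of, dtype=np.intp)
        self.vert = np.asarray(vert, dtype=np.intp)
        self.edge_of = np.asarray(edge_of, dtype=np.intp)
        # next/previous vertex within each loop
        nxt = np.empty_like(self.vert)
        prv = np.empty_like(self.vert)
        start = 0
        for ci in range(mesh.n_cells):
            n = len(mesh.cell_edges[ci])
            idx = np.arange(start, start + n)
            nxt[idx] = self.vert[np.roll(idx, -1)]
            prv[idx] = self.vert[np.roll(idx, 1)]
            start += n
        self.nxt = nxt
        self.prv = prv
        self.n_cells = mesh.n_cells
        self.n_vertices = mesh.n_vertices
        self._prev_entry = None


class Mesh:
    """Polygonal monolayer mesh.

    Parameters
    ----------
    vertices : (V, 2) float array of vertex positions.
    edges : (E, 2) int array of ``(tail, head)`` vertex indices.
    cell_edges : per cell, array of edge indices in boundary order.
    cell_signs : per cell, matching array of +-1 traversal signs.
    cells : per cell :class:`CellState`.
    """

    def __init__(
        self,
        vertices: np.ndarray,
        edges: np.ndarray,
        cell_edges: Sequence[np.ndarray],
        cell_signs: Sequence[np.ndarray],
        cells: Sequence[CellState],
    ) -> None:
        self.vertices = np.asarray(vertices, dtype=float).reshape(-1, 2)
        self.edges = np.asarray(edges, dtype=np.intp).reshape(-1, 2)
        self.cell_edges = [np.asarray(e, dtype=np.intp) for e in cell_edges]
        self.cell_signs = [np.asarray(s, dtype=np.intp) for s in cell_signs]
        self.cells = list(cells)
        if len(self.cell_edges) != len(self.cells):
            raise ValueError("cell_edges and cells must have equal length")
        self._cache: _LoopCache | None = None

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def copy(self) -> "Mesh":
        return Mesh(
            self.vertices.copy(),
            self.edges.copy(),
            [e.copy() for e in self.cell_edges],
            [s.copy() for s in self.cell_signs],
            [c.copy() for c in self.cells],
        )

    def invalidate(self) -> None:
        """Drop cached derived structures after a topology change."""
        self._cache = None

    @property
    def loops(self) -> _LoopCache:
        if self._cache is None or self._cache.n_vertices != self.n_vertices:
            self._cache = _LoopCache(self)
        return self._cache

    # ------------------------------------------------------------- incidence
    def edge_vertex_incidence(self) -> sparse.csr_matrix:
        """Signed incidence matrix A (edges x vertices)."""
        e = np.arange(self.n_edges)
        rows = np.concatenate([e, e])
        cols = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        data = np.concatenate([np.ones(self.n_edges), -np.ones(self.n_edges)])
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_edges, self.n_vertices)
        )

    def cell_edge_incidence(self) -> sparse.csr_matrix:
        """Signed incidence matrix B (cells x edges)."""
        rows, cols, data = [], [], []
        for ci, (eids, sgns) in enumerate(zip(self.cell_edges, self.cell_signs)):
            rows.extend([ci] * len(eids))
            cols.extend(eids.tolist())
            data.extend(sgns.tolist())
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_cells, self.n_edges), dtype=float
        )

    # -------------------------------------------------------------- geometry
    def cell_vertex_loop(self, ci: int) -> list[int]:
        """Ordered (CCW) vertex indices of cell ``ci`` (tail of each directed edge)."""
        out = []
        for eid, sgn in zip(self.cell_edges[ci], self.cell_signs[ci]):
            tail, head = self.edges[eid]
            out.append(int(tail if sgn > 0 else head))
        return out

    def cell_polygon(self, ci: int) -> np.ndarray:
        return self.vertices[self.cell_vertex_loop(ci)]

    def areas(self) -> np.ndarray:
        lp = self.loops
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        cross = x[lp.vert] * y[lp.nxt] - x[lp.nxt] * y[lp.vert]
        return 0.5 * np.bincount(lp.cell_of, weights=cross, minlength=self.n_cells)

    def perimeters(self) -> np.ndarray:
        lp = self.loops
        seg = self.vertices[lp.nxt] - self.vertices[lp.vert]
        ln = np.hypot(seg[:, 0], seg[:, 1])
        return np.bincount(lp.cell_of, weights=ln, minlength=self.n_cells)

    def centroids(self) -> np.ndarray:
        """Area centroids of all cells."""
        lp = self.loops
        v, n = self.vertices[lp.vert], self.vertices[lp.nxt]
        cross = v[:, 0] * n[:, 1] - n[:, 0] * v[:, 1]
        cx = np.bincount(lp.cell_of, weights=(v[:, 0] + n[:, 0]) * cross,
                         minlength=self.n_cells)
        cy = np.bincount(lp.cell_of, weights=(v[:, 1] + n[:, 1]) * cross,
                         minlength=self.n_cells)
        a = self.areas()
        return np.column_stack([cx, cy]) / (6.0 * a[:, None])

    def edge_lengths(self) -> np.ndarray:
        seg = self.vertices[self.edges[:, 1]] - self.vertices[self.edges[:, 0]]
        return np.hypot(seg[:, 0], seg[:, 1])

    # -------------------------------------------------------------- topology
    def edge_cell_count(self) -> np.ndarray:
        """Number of cells bordering each edge (1 = boundary, 2 = interior)."""
        count = np.zeros(self.n_edges, dtype=int)
        for eids in self.cell_edges:
            count[eids] += 1
        return count

    def boundary_edges(self) -> np.ndarray:
        return np.flatnonzero(self.edge_cell_count() == 1)

    def edge_cells(self) -> list[list[int]]:
        """For each edge, the list of bordering cell indices."""
        out: list[list[int]] = [[] for _ in range(self.n_edges)]
        for ci, eids in enumerate(self.cell_edges):
            for e in eids:
                out[e].append(ci)
        return out

    def vertex_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_hex_monolayer(
    rings: int,
    rng: np.random.Generator | None = None,
    cycle_time: float = 1.0,
    cycle_jitter: float = 0.2,
) -> Mesh:
    """Centered hexagonal patch of ``3*rings*(rings+1) + 1`` regular hexagons.

    Side length is chosen so every cell has unit area.  Founder-cell ages are
    drawn uniformly on ``[0, cycle_time)`` so the initial population divides
    asynchronously; pass ``rng=None`` for age 0 everywhere (deterministic
    geometry-only construction).
    """
    if rings < 0:
        raise ValueError("rings must be non-negative")
    s = np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))  # hexagon side for unit area
    # flat-top hexagons; centers on the axial lattice within `rings`
    centers = []
    for q in range(-rings, rings + 1):
        for r in range(max(-rings, -q - rings), min(rings, -q + rings) + 1):
            centers.append((1.5 * s * q, np.sqrt(3.0) * s * (r + q / 2.0)))
    hex_angles = np.deg2rad(np.arange(0, 360, 60))
    offsets = s * np.column_stack([np.cos(hex_angles), np.sin(hex_angles)])

    vert_index: dict[tuple[int, int], int] = {}
    vertices: list[tuple[float, float]] = []
    edge_index: dict[tuple[int, int], int] = {}
    edges: list[tuple[int, int]] = []
    cell_edges: list[np.ndarray] = []
    cell_signs: list[np.ndarray] = []

    def vid(p: np.ndarray) -> int:
        key = (round(p[0] / s * 1e9), round(p[1] / s * 1e9))
        if key not in vert_index:
            vert_index[key] = len(vertices)
            vertices.append((float(p[0]), float(p[1])))
        return vert_index[key]

    for cx, cy in centers:
        loop = [vid(np.array([cx, cy]) + off) for off in offsets]  # CCW
        eids, sgns = [], []
        for a, b in zip(loop, loop[1:] + loop[:1]):
            key = (min(a, b), max(a, b))
            if key not in edge_index:
                edge_index[key] = len(edges)
                edges.append((a, b))
            eid = edge_index[key]
            sgns.append(1 if edges[eid] == (a, b) else -1)
            eids.append(eid)
        cell_edges.append(np.asarray(eids, dtype=np.intp))
        cell_signs.append(np.asarray(sgns, dtype=np.intp))

    states = []
    for _ in centers:
        age = float(rng.uniform(0.0, cycle_time)) if rng is not None else 0.0
        ct = cycle_time
        if rng is not None and cycle_jitter > 0:
            ct = float(cycle_time * rng.uniform(1 - cycle_jitter, 1 + cycle_jitter))
        states.append(CellState(age=age, cycle_time=ct))
    return Mesh(np.asarray(vertices), np.asarray(edges), cell_edges, cell_signs, states)


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def cell_geometry(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (area, perimeter); raises if any polygon is degenerate."""
    areas = mesh.areas()
    if np.any(areas <= 0):
        bad = np.flatnonzero(areas <= 0).tolist()
        raise ValueError(f"non-positive cell area (self-intersecting polygon?): cells {bad}")
    return areas, mesh.perimeters()


def adjacency_graph(mesh: Mesh) -> nx.Graph:
    """Cell-adjacency graph: nodes are cell indices, edges join cells sharing >= 1 mesh edge."""
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_cells))
    for cells in mesh.edge_cells():
        if len(cells) == 2:
            g.add_edge(cells[0], cells[1])
    return g


def peripheral_cells(mesh: Mesh) -> set[int]:
    """Cells owning at least one boundary edge."""
    boundary = set(mesh.boundary_edges().tolist())
    return {
        ci
        for ci, eids in enumerate(mesh.cell_edges)
        if boundary.intersection(eids.tolist())
    }


@dataclass
class TopologyReport:
    ok: bool
    failures: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_topology(mesh: Mesh) -> TopologyReport:
    """Check the mesh's structural invariants; reports failures, never raises.

    Passes iff ``B @ A == 0``, every column pair of ``|A|`` per row sums to 2
    (each edge has exactly one tail and one head), each edge borders 1 or 2
    cells, the Euler relation ``V - E + C = 1`` holds for a disc, and all cell
    polygons have positive signed area.
    """
    failures: list[str] = []
    try:
        a = mesh.edge_vertex_incidence()
        b = mesh.cell_edge_incidence()
        if mesh.n_edges:
            rowsum = np.abs(a).sum(axis=1).A.ravel() if hasattr(np.abs(a).sum(axis=1), "A") \
                else np.asarray(np.abs(a).sum(axis=1)).ravel()
            if not np.all(rowsum == 2):
                failures.append("some edge does not have exactly one tail and one head")
            if np.any(mesh.edges[:, 0] == mesh.edges[:, 1]):
                failures.append("degenerate edge with identical endpoints")
        ba = (b @ a)
        if ba.nnz and np.max(np.abs(ba.data)) > 0:
            failures.append("B @ A != 0: some cell boundary loop is not closed")
        counts = mesh.edge_cell_count()
        if np.any(counts < 1) or np.any(counts > 2):
            bad = np.flatnonzero((counts < 1) | (counts > 2)).tolist()
            failures.append(f"edges bordering !=1,2 cells: {bad}")
        euler = mesh.n_vertices - mesh.n_edges + mesh.n_cells
        if euler != 1:
            failures.append(f"Euler relation V-E+C = {euler} != 1")
        areas = mesh.areas()
        if np.any(areas <= 0):
            failures.append(
                f"non-positive signed area for cells {np.flatnonzero(areas <= 0).tolist()}"
            )
    except Exception as exc:  # structural breakage surfaces as a failure item
        failures.append(f"validation error: {exc!r}")
    return TopologyReport(ok=not failures, failures=failures)


# ---------------------------------------------------------------------------
# loop rebuilding (shared by the surgical operations in `mechanics`)
# ---------------------------------------------------------------------------

def loop_from_edge_set(mesh: Mesh, edge_ids: Iterable[int]) -> tuple[np.ndarray, np.ndarray]:
    """Chain an unordered edge set into a single CCW loop.

    Every vertex must appear in exactly two edges of the set.  Returns
    ``(edge_ids, signs)`` in boundary order with positive signed area.
    """
    edge_ids = list(edge_ids)
    at_vertex: dict[int, list[int]] = {}
    for e in edge_ids:
        for v in mesh.edges[e]:
            at_vertex.setdefault(int(v), []).append(e)
    for v, es in at_vertex.items():
        if len(es) != 2:
            raise ValueError(f"vertex {v} appears in {len(es)} edges of the loop set")
    start = edge_ids[0]
    ordered = [start]
    tail, head = (int(x) for x in mesh.edges[start])
    signs = [1]
    cur_v, first_v = head, tail
    used = {start}
    while cur_v != first_v:
        nxt = [e for e in at_vertex[cur_v] if e not in used]
        if len(nxt) != 1:
            raise ValueError("edge set does not chain into a single loop")
        e = nxt[0]
        t, h = (int(x) for x in mesh.edges[e])
        signs.append(1 if t == cur_v else -1)
        cur_v = h if t == cur_v else t
        ordered.append(e)
        used.add(e)
    if len(used) != len(edge_ids):
        raise ValueError("edge set contains more than one loop")
    # orient CCW
    verts = []
    for e, s in zip(ordered, signs):
        t, h = mesh.edges[e]
        verts.append(int(t if s > 0 else h))
    pts = mesh.vertices[verts]
    area2 = np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1])
    if area2 < 0:
        ordered = ordered[::-1]
        signs = [-s for s in signs[::-1]]
    return np.asarray(ordered, dtype=np.intp), np.asarray(signs, dtype=np.intp)
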