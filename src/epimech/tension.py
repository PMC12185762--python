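"""Geometry-based relative junction-tension inference (CellFIT-style).

At every interior triple (or higher) junction point of a segmented or
simulated tissue, the cortical tensions pulling along the incident junctions
must balance:  ``sum_j t_j * u_j = 0``  with ``u_j`` the unit tangent of
junction j directed away from the node.  Stacking two such rows per interior
node gives a homogeneous least-squares system whose solution — fixed by the
normalisation mean(t) = 1, since tensions are only identifiable up to a
global scale — is the inferred relative tension of every junction.

Only the tension terms of the full CellFIT formulation are used (no curved
interfaces, no Laplace pressures): tangents are estimated from the first
straight segment of each junction at the node.

Junctions are ranked by contiguity distance from a macropinocytotic event:
N1 are the junction(s) of the event itself, N2 share a node with an N1
junction, and so on through N4; anything further is "beyond".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh

__all__ = [
    "JunctionNetwork",
    "TensionSolution",
    "build_junction_network",
    "infer_tensions",
    "ring_labels",
    "before_after_ratio",
    "RING_NAMES",
]

RING_NAMES = ("N1", "N2", "N3", "N4")


@dataclass
class Junction:
    """A junction curve between two nodes, bordered by at most two cells."""

    node_a: int
    node_b: int
    points: np.ndarray          # polyline from node_a to node_b, (k, 2)
    cells: frozenset            # bordering cell ids (1 on the tissue boundary)

    def tangent_at(self, node: int) -> np.ndarray:
        """Unit tangent of the first segment, directed away from ``node``."""
        if node == self.node_a:
            d = self.points[1] - self.points[0]
        elif node == self.node_b:
            d = self.points[-2] - self.points[-1]
        else:
            raise ValueError("junction does not end at this node")
        return d / np.hypot(*d)


@dataclass
class JunctionNetwork:
    node_positions: np.ndarray              # (n_nodes, 2)
    junctions: list[Junction]
    interior: np.ndarray                    # bool per node: off the tissue boundary
    node_junctions: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_junctions:
            self.node_junctions = [[] for _ in range(len(self.node_positions))]
            for j, jn in enumerate(self.junctions):
                self.node_junctions[jn.node_a].append(j)
                self.node_junctions[jn.node_b].append(j)

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


def _network_from_elements(
    vertices: np.ndarray,
    edges: list[tuple[int, int]],
    edge_cells: list[set],
) -> JunctionNetwork:
    """Chain a vertex/edge soup into junction curves between degree-!=2 nodes."""
    nv = len(vertices)
    incident: list[list[int]] = [[] for _ in range(nv)]
    for e, (a, b) in enumerate(edges):
        incident[a].append(e)
        incident[b].append(e)
    degree = np.array([len(x) for x in incident])
    if np.any(degree == 1):
        bad = np.flatnonzero(degree == 1).tolist()
        raise ValueError(f"dangling edges at vertices {bad}")
    is_node = degree >= 3
    if not np.any(is_node):
        raise ValueError("tessellation has no junction points (degree >= 3)")
    node_ids = np.flatnonzero(is_node)
    node_index = {int(v): i for i, v in enumerate(node_ids)}
    boundary_vertex = np.zeros(nv, dtype=bool)
    for e, (a, b) in enumerate(edges):
        if len(edge_cells[e]) < 2:
            boundary_vertex[a] = boundary_vertex[b] = True

    junctions: list[Junction] = []
    used = np.zeros(len(edges), dtype=bool)
    for v0 in node_ids:
        for e0 in incident[v0]:
            if used[e0]:
                continue
            # walk from v0 through degree-2 vertices until the next node
            chain = [int(v0)]
            cells: set = set(edge_cells[e0])
            e, cur = e0, int(v0)
            while True:
                used[e] = True
                a, b = edges[e]
                cur = b if a == cur else a
                chain.append(int(cur))
                cells |= set(edge_cells[e])
                if is_node[cur]:
                    break
                nxt = [ee for ee in incident[cur] if not used[ee]]
                if not nxt:
                    break
                e = nxt[0]
            junctions.append(
                Junction(
                    node_a=node_index[int(v0)],
                    node_b=node_index[int(cur)],
                    points=vertices[chain],
                    cells=frozenset(cells),
                )
            )
    interior = ~boundary_vertex[node_ids]
    return JunctionNetwork(vertices[node_ids].astype(float), junctions, interior)


def build_junction_network(source) -> JunctionNetwork:
    """Build the triple-junction network of a tessellation.

    ``source`` may be a :class:`~epimech.mesh.Mesh` or a list of cell polygons
    ((k, 2) arrays; vertices shared between cells must coincide to ~1e-9 of
    the bounding-box scale).  Two-fold vertices are treated as pass-through
    points of a junction curve; four-fold (rosette) vertices are retained as
    single nodes with four junctions.
    """
    if isinstance(source, Mesh):
        verts = source.vertices
        edges = [tuple(int(v) for v in e) for e in source.edges]
        edge_cells = [set(c) for c in source.edge_cells()]
        return _network_from_elements(verts, edges, edge_cells)
    # polygon soup: dedupe vertices, dedupe undirected edges, count cells
    polys = [np.asarray(p, dtype=float) for p in source]
    scale = max(
        float(np.ptp(np.concatenate(polys)[:, 0])),
        float(np.ptp(np.concatenate(polys)[:, 1])),
        1e-9,
    )
    tol = 1e-9 * scale
    vert_map: dict[tuple[int, int], int] = {}
    verts: list[np.ndarray] = []

    def vid(p: np.ndarray) -> int:
        key = (round(float(p[0]) / tol / 16), round(float(p[1]) / tol / 16))
        if key not in vert_map:
            vert_map[key] = len(verts)
            verts.append(p)
        return vert_map[key]

    edge_map: dict[tuple[int, int], int] = {}
    edges: list[tuple[int, int]] = []
    edge_cells: list[set] = []
    for ci, poly in enumerate(polys):
        ids = [vid(p) for p in poly]
        for a, b in zip(ids, ids[1:] + ids[:1]):
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key not in edge_map:
                edge_map[key] = len(edges)
                edges.append(key)
                edge_cells.append(set())
            edge_cells[edge_map[key]].add(ci)
    return _network_from_elements(np.asarray(verts), edges, edge_cells)


@dataclass
class TensionSolution:
    """Inferred relative junction tensions, normalised to mean 1 over solved junctions."""

    tensions: np.ndarray          # per junction; NaN where unconstrained
    residual_rms: float           # rms force imbalance per interior node
    residual_max: float
    rank_deficient: bool
    n_equations: int
    n_unknowns: int
    condition: float              # ratio of largest to smallest nonzero singular value

    @property
    def solved(self) -> np.ndarray:
        return ~np.isnan(self.tensions)


def infer_tensions(network: JunctionNetwork) -> TensionSolution:
    """Solve the force-balance least-squares system for relative tensions.

    Two balance rows are stacked per interior node; junctions that touch no
    interior node carry no information and are reported as NaN.  The system
    is solved under the constraint mean(t) = 1 via its KKT equations; a
    rank-deficient balance matrix (tensions identifiable only up to more than
    one degree of freedom) is flagged, not raised.
    """
    interior_nodes = np.flatnonzero(network.interior)
    if interior_nodes.size == 0:
        raise ValueError("network has no interior node: tensions are not identifiable")
    covered = sorted(
        {j for node in interior_nodes for j in network.node_junctions[node]}
    )
    col = {j: k for k, j in enumerate(covered)}
    n_un = len(covered)
    rows = []
    for node in interior_nodes:
        rx = np.zeros(n_un)
        ry = np.zeros(n_un)
        for j in network.node_junctions[node]:
            u = network.junctions[j].tangent_at(int(node))
            rx[col[j]] += u[0]
            ry[col[j]] += u[1]
        rows.append(rx)
        rows.append(ry)
    m = np.asarray(rows)
    n_eq = m.shape[0]

    # KKT system for min ||M t||^2 s.t. mean(t) = 1
    ones = np.ones(n_un)
    kkt = np.zeros((n_un + 1, n_un + 1))
    kkt[:n_un, :n_un] = 2.0 * (m.T @ m)
    kkt[:n_un, n_un] = ones
    kkt[n_un, :n_un] = ones
    rhs = np.zeros(n_un + 1)
    rhs[n_un] = float(n_un)
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    t = sol[:n_un]

    sv = np.linalg.svd(m, compute_uv=False)
    tol_sv = max(m.shape) * np.finfo(float).eps * (sv[0] if sv.size else 1.0)
    rank = int(np.sum(sv > tol_sv))
    # tensions are determined up to one global scale; more null dimensions = deficient
    rank_deficient = rank < n_un - 1
    smallest = sv[sv > tol_sv][-1] if rank else np.inf
    res = m @ t
    res2 = np.hypot(res[0::2], res[1::2])

    tensions = np.full(network.n_junctions, np.nan)
    tensions[covered] = t
    return TensionSolution(
        tensions=tensions,
        residual_rms=float(np.sqrt(np.mean(res2**2))),
        residual_max=float(np.max(res2)),
        rank_deficient=rank_deficient,
        n_equations=n_eq,
        n_unknowns=n_un,
        condition=float(sv[0] / smallest) if np.isfinite(smallest) else np.inf,
    )


def ring_labels(
    network: JunctionNetwork,
    event_junctions: list[int] | None = None,
    event_cell: int | None = None,
) -> np.ndarray:
    """Label junctions N1..N4 / beyond by contiguity distance from an event.

    N1 is the event's own junction(s): either an explicit list of junction
    ids, or — when only the host cell is known — every junction bordering
    that cell.  Each subsequent ring contains the junctions sharing a node
    with the previous ring; first-assigned label wins.
    """
    if event_junctions is None:
        if event_cell is None:
            raise ValueError("provide event_junctions or event_cell")
        event_junctions = [
            j for j, jn in enumerate(network.junctions) if event_cell in jn.cells
        ]
        if not event_junctions:
            raise ValueError(f"cell {event_cell} borders no junction in the network")
    for j in event_junctions:
        if not 0 <= j < network.n_junctions:
            raise ValueError(f"event junction {j} not in network")
    labels = np.full(network.n_junctions, "beyond", dtype=object)
    current = set(event_junctions)
    assigned = set(current)
    labels[list(current)] = "N1"
    for name in RING_NAMES[1:]:
        nodes = {
            n
            for j in current
            for n in (network.junctions[j].node_a, network.junctions[j].node_b)
        }
        nxt = {
            j
            for n in nodes
            for j in network.node_junctions[n]
            if j not in assigned
        }
        if not nxt:
            break
        labels[list(nxt)] = name
        assigned |= nxt
        current = nxt
    return labels


def before_after_ratio(
    solutions_before: list[TensionSolution],
    solutions_after: list[TensionSolution],
    labels: np.ndarray,
) -> dict[str, float]:
    """Per-ring tension ratio, after / before.

    For each ring the mean tension over the ring's junctions is averaged over
    the 1-4 frames on each side; the ratio of the after-average to the
    before-average is returned.  Rings with no junction (or no solved
    tension) are reported as NaN.
    """
    for name, sols in (("before", solutions_before), ("after", solutions_after)):
        if not 1 <= len(sols) <= 4:
            raise ValueError(f"need 1-4 frames {name} the event, got {len(sols)}")
    labels = np.asarray(labels, dtype=object)

    def side_mean(sols: list[TensionSolution], ring: str) -> float:
        mask = labels == ring
        if not np.any(mask):
            return np.nan
        frame_means = []
        for s in sols:
            vals = s.tensions[mask]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                frame_means.append(float(np.mean(vals)))
        return float(np.mean(frame_means)) if frame_means else np.nan

    out = {}
    for ring in RING_NAMES:
        b = side_mean(solutions_before, ring)
        a = side_mean(solutions_after, ring)
        out[ring] = a / b if (np.isfinite(a) and np.isfinite(b) and b != 0) else np.nan
    return out
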