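"""Monolayer mechanics: logarithmic constitutive law, forces, relaxation and surgery.

The model's defining contract
-----------------------------
Each cell i with area ``A_i``, perimeter ``L_i``, preferred area ``A0_i``,
stiffness prefactor ``sigma_i`` exerts

* internal pressure   ``p_i = -sigma_i * ln(A_i / A0_i)``
* cortical tension    ``t_i = sigma_i * Gamma * ln(L_i / L0)``

i.e. logarithmic relations between force and strain in both area and
perimeter, with a single prefactor sigma scaling both (sigma = 1 for bulk
cells, sigma = 10 for stiff multiciliated cells in the main condition).
These derive from the potential

``E = sum_i sigma_i [A_i ln(A_i/A0_i) - A_i + A0_i]
     + sum_i sigma_i Gamma [L_i ln(L_i/L0) - L_i + L0]
     + P_ext * (total monolayer area)``

whose bracketed terms are non-negative with minimum 0 at the preferred value,
and ``dE/dA_i = -p_i``, ``dE/dL_i = t_i``.  The uniform external pressure
``P_ext`` acts as an inward traction on boundary edges (equivalently the
``P_ext * area`` energy term, since the cells tile the monolayer).

Vertices move by overdamped gradient descent ``x <- x + (dt/eta) * F`` with
``F = -grad E``, an adaptive step (halved when the energy would rise, grown
1.1x after 10 consecutive accepted steps), and T1 neighbour exchanges whenever
an interior edge becomes shorter than ``t1_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import CellState, Mesh, loop_from_edge_set

__all__ = [
    "MechParams",
    "CellMechanics",
    "RelaxResult",
    "cell_pressure",
    "cell_tension",
    "total_energy",
    "vertex_forces",
    "relax",
    "divide_cell",
    "t1_transition",
    "collapse_boundary_edge",
    "advance",
    "grow_to",
    "cell_mechanics",
]

log = logging.getLogger(__name__)


@dataclass
class MechParams:
    """Mechanical and protocol-step parameters (nondimensional model units).

    Defaults put the tissue in the jammed (solid-like) regime: preferred
    perimeter ``L0 = 0.75`` (a bare length in units where A0 = 1), relative
    cortical stiffness ``Gamma = 0.2``, uniform external pressure 0.5.
    """

    gamma: float = 0.2
    l0: float = 0.75
    p_ext: float = 0.5
    eta: float = 1.0
    dt: float = 0.02
    dt_max: float = 0.5
    force_tol: float = 1e-6
    growth_force_tol: float = 1e-3
    growth_max_steps: int = 400
    t1_threshold: float = 0.05
    cycle_time: float = 1.0
    cycle_jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.l0 <= 0 or self.dt <= 0 or self.force_tol <= 0:
            raise ValueError("gamma, l0, dt and force_tol must be positive")
        if self.p_ext < 0:
            raise ValueError("p_ext must be non-negative")
        if not 0 <= self.cycle_jitter < 1:
            raise ValueError("cycle_jitter must lie in [0, 1)")

    def replace(self, **kw) -> "MechParams":
        return replace(self, **kw)


@dataclass
class CellMechanics:
    """Per-cell mechanical snapshot at one instant."""

    area: np.ndarray
    perimeter: np.ndarray
    pressure: np.ndarray
    tension: np.ndarray


@dataclass
class RelaxResult:
    steps: int
    converged: bool
    max_force: float
    energy: float
    n_t1: int
    dt_final: float
    energy_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# constitutive quantities
# ---------------------------------------------------------------------------

def _sigma(mesh: Mesh) -> np.ndarray:
    return np.array([c.stiffness for c in mesh.cells])


def _a0(mesh: Mesh) -> np.ndarray:
    return np.array([c.preferred_area for c in mesh.cells])


def _cell_params(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """(sigma, A0) arrays, cached on the mesh's loop cache lifetime."""
    cache = getattr(mesh, "_cellparam_cache", None)
    if cache is None or cache[0] is not mesh.loops:
        cache = (mesh.loops, _sigma(mesh), _a0(mesh))
        mesh._cellparam_cache = cache
    return cache[1], cache[2]


def cell_pressure(mesh: Mesh, params: MechParams, areas: np.ndarray | None = None) -> np.ndarray:
    """p_i = -sigma_i * ln(A_i / A0_i).  Positive when the cell is squeezed below A0."""
    a = mesh.areas() if areas is None else areas
    if np.any(a <= 0):
        raise ValueError("non-positive cell area")
    return -_sigma(mesh) * np.log(a / _a0(mesh))


def cell_tension(mesh: Mesh, params: MechParams, perims: np.ndarray | None = None) -> np.ndarray:
    """t_i = sigma_i * Gamma * ln(L_i / L0)."""
    L = mesh.perimeters() if perims is None else perims
    if np.any(L <= 0):
        raise ValueError("non-positive cell perimeter")
    return _sigma(mesh) * params.gamma * np.log(L / params.l0)


def total_energy(mesh: Mesh, params: MechParams) -> float:
    a, L = mesh.areas(), mesh.perimeters()
    if np.any(a <= 0) or np.any(L <= 0):
        raise ValueError("degenerate cell geometry")
    sig, a0 = _sigma(mesh), _a0(mesh)
    e_area = np.sum(sig * (a * np.log(a / a0) - a + a0))
    e_perim = np.sum(sig * params.gamma * (L * np.log(L / params.l0) - L + params.l0))
    return float(e_area + e_perim + params.p_ext * np.sum(a))


try:  # compiled kernel; numpy path below is the reference implementation
    from numba import njit as _njit

    @_njit(cache=True)
    def _force_kernel(pos, vert, nxt, prv, cell_of, sig, a0, gamma, l0, p_ext):
        n_entries = vert.shape[0]
        n_cells = sig.shape[0]
        n_verts = pos.shape[0]
        area = np.zeros(n_cells)
        perim = np.zeros(n_cells)
        seg = np.empty(n_entries)
        bad_edge = -1
        for k in range(n_entries):
            v = vert[k]
            w = nxt[k]
            dx = pos[v, 0] - pos[w, 0]
            dy = pos[v, 1] - pos[w, 1]
            s = np.sqrt(dx * dx + dy * dy)
            seg[k] = s
            if s == 0.0 and bad_edge < 0:
                bad_edge = k
            c = cell_of[k]
            area[c] += 0.5 * (pos[v, 0] * pos[w, 1] - pos[w, 0] * pos[v, 1])
            perim[c] += s
        if bad_edge >= 0:
            return area, perim, np.empty((0, 2)), 0.0, bad_edge
        for c in range(n_cells):
            if area[c] <= 0.0:
                return area, perim, np.empty((0, 2)), 0.0, -2
        energy = 0.0
        pc = np.empty(n_cells)
        tc = np.empty(n_cells)
        for c in range(n_cells):
            la = np.log(area[c] / a0[c])
            ll = np.log(perim[c] / l0)
            pc[c] = -sig[c] * la - p_ext
            tc[c] = sig[c] * gamma * ll
            energy += sig[c] * (area[c] * la - area[c] + a0[c])
            energy += sig[c] * gamma * (perim[c] * ll - perim[c] + l0)
            energy += p_ext * area[c]
        f = np.zeros((n_verts, 2))
        for k in range(n_entries):
            v = vert[k]
            w = nxt[k]
            u = prv[k]
            c = cell_of[k]
            dnx = pos[v, 0] - pos[w, 0]
            dny = pos[v, 1] - pos[w, 1]
            dpx = pos[v, 0] - pos[u, 0]
            dpy = pos[v, 1] - pos[u, 1]
            sp = np.sqrt(dpx * dpx + dpy * dpy)
            sn = seg[k]
            dlx = dpx / sp + dnx / sn
            dly = dpy / sp + dny / sn
            f[v, 0] += pc[c] * 0.5 * (pos[w, 1] - pos[u, 1]) - tc[c] * dlx
            f[v, 1] += pc[c] * 0.5 * (pos[u, 0] - pos[w, 0]) - tc[c] * dly
        return area, perim, f, energy, -3

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba unavailable
    _HAVE_NUMBA = False


def _forces_and_energy(mesh: Mesh, params: MechParams) -> tuple[np.ndarray, float]:
    """Assemble F = -grad E and E in one pass over the flattened cell loops."""
    if _HAVE_NUMBA:
        lp = mesh.loops
        sig, a0 = _cell_params(mesh)
        area, perim, f, energy, status = _force_kernel(
            mesh.vertices, lp.vert, lp.nxt, lp.prv, lp.cell_of,
            sig, a0, params.gamma, params.l0, params.p_ext,
        )
        if status >= 0:
            raise ValueError(f"degenerate zero-length edge {int(lp.edge_of[status])}")
        if status == -2:
            raise ValueError("degenerate cell geometry during force assembly")
        return f, float(energy)
    return _forces_and_energy_numpy(mesh, params)


def _forces_and_energy_numpy(mesh: Mesh, params: MechParams) -> tuple[np.ndarray, float]:
    """Pure-numpy reference implementation of the force/energy assembly."""
    lp = mesh.loops
    pos = mesh.vertices
    v, nx_, pv = lp.vert, lp.nxt, lp.prv
    xv, yv = pos[v, 0], pos[v, 1]
    xn, yn = pos[nx_, 0], pos[nx_, 1]
    xp, yp = pos[pv, 0], pos[pv, 1]

    nc = mesh.n_cells
    a = 0.5 * np.bincount(lp.cell_of, weights=xv * yn - xn * yv, minlength=nc)
    dnx, dny = xv - xn, yv - yn
    seg = np.sqrt(dnx * dnx + dny * dny)
    L = np.bincount(lp.cell_of, weights=seg, minlength=nc)
    if np.any(a <= 0) or np.any(seg == 0):
        if np.any(seg == 0):
            eid = lp.edge_of[np.flatnonzero(seg == 0)[0]]
            raise ValueError(f"degenerate zero-length edge {int(eid)}")
        raise ValueError("degenerate cell geometry during force assembly")

    sig, a0 = _cell_params(mesh)
    log_a = np.log(a / a0)
    log_l = np.log(L / params.l0)
    p = -sig * log_a
    t = sig * params.gamma * log_l
    energy = float(
        np.sum(sig * (a * log_a - a + a0))
        + np.sum(sig * params.gamma * (L * log_l - L + params.l0))
        + params.p_ext * np.sum(a)
    )

    # dA_i/dr_k = 0.5 * (y_next - y_prev, x_prev - x_next) for vertex k of cell i
    # dL_i/dr_k = unit(r_k - r_prev) + unit(r_k - r_next)
    dpx, dpy = xv - xp, yv - yp
    segp = seg[_roll_cache(lp)]  # |r_k - r_prev| = previous entry's segment length
    dlx = dpx / segp + dnx / seg
    dly = dpy / segp + dny / seg

    # F = sum_i (p_i - P_ext) dA_i/dx - sum_i t_i dL_i/dx
    ca = (p - params.p_ext)[lp.cell_of]
    ct = t[lp.cell_of]
    nv = mesh.n_vertices
    fx = np.bincount(v, weights=ca * 0.5 * (yn - yp) - ct * dlx, minlength=nv)
    fy = np.bincount(v, weights=ca * 0.5 * (xp - xn) - ct * dly, minlength=nv)
    return np.column_stack([fx, fy]), energy


def _roll_cache(lp) -> np.ndarray:
    """Index mapping each loop entry to its predecessor entry within the same loop."""
    idx = getattr(lp, "_prev_entry", None)
    if idx is None:
        idx = np.empty(len(lp.vert), dtype=np.intp)
        start = 0
        bounds = np.flatnonzero(np.diff(lp.cell_of)) + 1
        for s, e in zip(np.r_[0, bounds], np.r_[bounds, len(lp.cell_of)]):
            idx[s:e] = np.roll(np.arange(s, e), 1)
        lp._prev_entry = idx
    return idx


def vertex_forces(mesh: Mesh, params: MechParams) -> np.ndarray:
    """Per-vertex force F = -grad E, assembled through the cell boundary loops."""
    return _forces_and_energy(mesh, params)[0]


def cell_mechanics(mesh: Mesh, params: MechParams) -> CellMechanics:
    a, L = mesh.areas(), mesh.perimeters()
    return CellMechanics(
        area=a,
        perimeter=L,
        pressure=cell_pressure(mesh, params, a),
        tension=cell_tension(mesh, params, L),
    )


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------

def collapse_boundary_edge(mesh: Mesh, eid: int) -> bool:
    """Merge the endpoints of a collapsing boundary edge (in place).

    A boundary edge squeezed to near-zero length by the external pressure has
    no T1 partner; its two vertices are fused at the midpoint instead, the
    edge is removed, and the owning cell loses one corner.  Preserves the
    Euler relation (V and E both drop by one).  Returns False (with a log
    entry) for ineligible edges.
    """
    edge_cells = mesh.edge_cells()
    if len(edge_cells[eid]) != 1:
        log.debug("collapse skipped on edge %d: not a boundary edge", eid)
        return False
    owner = edge_cells[eid][0]
    if len(mesh.cell_edges[owner]) <= 3:
        log.debug("collapse skipped on edge %d: owning cell is a triangle", eid)
        return False
    u, w = (int(v) for v in mesh.edges[eid])
    # edges other than eid joining u and w would degenerate into a 2-gon
    for e in range(mesh.n_edges):
        if e != eid and {int(mesh.edges[e, 0]), int(mesh.edges[e, 1])} == {u, w}:
            log.debug("collapse skipped on edge %d: double edge with %d", eid, e)
            return False
    mesh.vertices[u] = 0.5 * (mesh.vertices[u] + mesh.vertices[w])
    # redirect all references of w to u, drop edge eid and vertex w
    edges = mesh.edges.copy()
    edges[edges == w] = u
    keep = np.ones(len(edges), dtype=bool)
    keep[eid] = False
    edges = edges[keep]
    edges[edges > w] -= 1
    old_to_new = np.cumsum(keep) - 1  # edge index remap
    new_cell_edges, new_cell_signs = [], []
    for ci, (eids, sgns) in enumerate(zip(mesh.cell_edges, mesh.cell_signs)):
        m = eids != eid
        new_cell_edges.append(old_to_new[eids[m]].astype(np.intp))
        new_cell_signs.append(sgns[m])
    verts = np.delete(mesh.vertices, w, axis=0)
    mesh.vertices = verts
    mesh.edges = edges.astype(np.intp)
    mesh.cell_edges = new_cell_edges
    mesh.cell_signs = new_cell_signs
    mesh.invalidate()
    return True


def _apply_t1s(mesh: Mesh, params: MechParams) -> int:
    """Resolve all currently short edges: T1 interior edges, collapse boundary ones."""
    n = 0
    for _ in range(16):  # collapsing cascades are rare; bound the sweep
        lengths = mesh.edge_lengths()
        short = np.flatnonzero(lengths < params.t1_threshold)
        if short.size == 0:
            break
        done_any = False
        counts = mesh.edge_cell_count()
        for e in short:
            if counts[e] == 2:
                done = t1_transition(mesh, int(e), params, strict=False)
            else:
                done = collapse_boundary_edge(mesh, int(e))
            if done:
                n += 1
                done_any = True
                break  # edge ids may shift; recompute lengths
        if not done_any:
            break
    return n


def relax(
    mesh: Mesh,
    params: MechParams,
    max_steps: int = 200_000,
    force_tol: float | None = None,
    record_energy: bool = False,
    dt0: float | None = None,
) -> RelaxResult:
    """Overdamped relaxation toward mechanical equilibrium (in place).

    Explicit Euler with adaptive step: a trial step that raises the energy is
    rejected and ``dt`` halved; after 10 consecutive accepted steps ``dt``
    grows 1.1x (capped at ``dt_max``).  Terminates when the largest vertex
    force magnitude drops below ``force_tol`` or after ``max_steps`` (then
    flagged, not raised).  Energy is non-increasing across accepted steps.
    """
    tol = params.force_tol if force_tol is None else force_tol
    dt = params.dt if dt0 is None else dt0
    n_t1 = _apply_t1s(mesh, params)
    f, energy = _forces_and_energy(mesh, params)
    trace = [energy] if record_energy else []
    accepts = 0
    steps = 0
    while steps < max_steps:
        fmax = float(np.max(np.hypot(f[:, 0], f[:, 1]))) if len(f) else 0.0
        if fmax < tol:
            return RelaxResult(steps, True, fmax, energy, n_t1, dt, trace)
        trial = mesh.vertices + (dt / params.eta) * f
        old = mesh.vertices
        mesh.vertices = trial
        try:
            f_new, e_new = _forces_and_energy(mesh, params)
            ok = e_new <= energy + 1e-13 * max(1.0, abs(energy))
        except ValueError:
            ok = False
            f_new, e_new = f, energy
        if ok:
            energy, f = e_new, f_new
            accepts += 1
            if accepts >= 10:
                dt = min(dt * 1.1, params.dt_max)
                accepts = 0
            k = _apply_t1s(mesh, params)
            if k:
                n_t1 += k
                f, energy = _forces_and_energy(mesh, params)
            if record_energy:
                trace.append(energy)
        else:
            mesh.vertices = old
            dt *= 0.5
            accepts = 0
            if dt < 1e-14:
                break
        steps += 1
    fmax = float(np.max(np.hypot(f[:, 0], f[:, 1]))) if len(f) else 0.0
    return RelaxResult(steps, fmax < tol, fmax, energy, n_t1, dt, trace)


# ---------------------------------------------------------------------------
# cell division
# ---------------------------------------------------------------------------

def _long_axis(poly: np.ndarray) -> np.ndarray:
    """Unit vector along the principal (long) axis of the polygon's second area moment."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6 * a)
    cy = np.sum((y + yn) * cross) / (6 * a)
    x, y = x - cx, y - cy
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    ixx = np.sum(cross * (y * y + y * yn + yn * yn)) / 12.0  # integral of y^2
    iyy = np.sum(cross * (x * x + x * xn + xn * xn)) / 12.0  # integral of x^2
    ixy = np.sum(cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / 24.0
    cov = np.array([[iyy, ixy], [ixy, ixx]])  # second moments of area about centroid
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def _chord_crossings(poly: np.ndarray, centroid: np.ndarray, direction: np.ndarray):
    """Intersections of the infinite line (centroid + s*direction) with polygon edges.

    Returns list of (loop_position, edge_parameter, point, s).
    """
    n = len(poly)
    hits = []
    d = direction / np.hypot(*direction)
    nrm = np.array([-d[1], d[0]])
    eps = 1e-9
    for k in range(n):
        a, b = poly[k], poly[(k + 1) % n]
        da = float(np.dot(a - centroid, nrm))
        db = float(np.dot(b - centroid, nrm))
        if (da > 0) == (db > 0):
            continue
        tpar = da / (da - db)
        if tpar <= eps or tpar >= 1 - eps:
            continue
        pt = a + tpar * (b - a)
        hits.append((k, tpar, pt, float(np.dot(pt - centroid, d))))
    return hits


def divide_cell(
    mesh: Mesh,
    ci: int,
    rng: np.random.Generator,
    params: MechParams | None = None,
) -> tuple[int, int]:
    """Split cell ``ci`` by a centroid chord perpendicular to its long axis.

    Two new vertices are created on the crossed edges and joined by a new
    edge; the two daughters inherit sigma and flags, get age 0, preferred
    area 1 and freshly drawn cycle times.  Returns the (parent-slot, appended)
    daughter indices.  Mutates the mesh in place.
    """
    state = mesh.cells[ci]
    if not state.can_divide:
        raise ValueError(f"cell {ci} is not allowed to divide")
    loop = mesh.cell_vertex_loop(ci)
    poly = mesh.vertices[loop]
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * np.sum(cross)
    centroid = np.array(
        [np.sum((x + xn) * cross) / (6 * area), np.sum((y + yn) * cross) / (6 * area)]
    )
    axis = _long_axis(poly)
    chord_dir = np.array([-axis[1], axis[0]])  # perpendicular to the long axis

    hits = None
    for attempt in range(10):
        cand = _chord_crossings(poly, centroid, chord_dir)
        if len(cand) >= 2:
            neg = [h for h in cand if h[3] < 0]
            pos = [h for h in cand if h[3] >= 0]
            if neg and pos:
                # the two crossings bracketing the centroid along the chord
                h1 = max(neg, key=lambda h: h[3])
                h2 = min(pos, key=lambda h: h[3])
                if h1[0] != h2[0]:
                    hits = (h1, h2)
                    break
        ang = rng.uniform(-0.3, 0.3)
        c, s = np.cos(ang), np.sin(ang)
        chord_dir = np.array([c * chord_dir[0] - s * chord_dir[1],
                              s * chord_dir[0] + c * chord_dir[1]])
    if hits is None:
        raise RuntimeError(f"could not find a valid division chord for cell {ci}")

    (k1, t1p, p1, _), (k2, t2p, p2, _) = sorted(hits[:2], key=lambda h: h[0])
    n = len(loop)

    edge_lookup: dict[tuple[int, int], tuple[int, int]] = {}
    for eid in range(mesh.n_edges):
        a, b = (int(v) for v in mesh.edges[eid])
        edge_lookup[(a, b)] = (eid, 1)
        edge_lookup[(b, a)] = (eid, -1)

    edge_cells = mesh.edge_cells()

    def split_edge(kpos: int, point: np.ndarray) -> tuple[int, int, int]:
        """Split the mesh edge under loop position kpos at `point`.

        Returns (new_vertex, first_sub_edge, second_sub_edge) ordered along the
        cell's traversal direction (loop[kpos] -> new -> loop[kpos+1]).
        """
        va, vb = loop[kpos], loop[(kpos + 1) % n]
        eid, sgn = edge_lookup[(va, vb)]
        w = mesh.n_vertices
        mesh.vertices = np.vstack([mesh.vertices, point[None, :]])
        tail, head = (int(v) for v in mesh.edges[eid])
        # reuse eid for (tail, w); append (w, head)
        mesh.edges[eid] = (tail, w)
        new_eid = mesh.n_edges
        mesh.edges = np.vstack([mesh.edges, np.array([[w, head]], dtype=np.intp)])
        # update the other cell bordering eid (if any)
        for oc in edge_cells[eid]:
            if oc == ci:
                continue
            pos_in = int(np.flatnonzero(mesh.cell_edges[oc] == eid)[0])
            sgn_oc = int(mesh.cell_signs[oc][pos_in])
            pair = (eid, new_eid) if sgn_oc > 0 else (new_eid, eid)
            mesh.cell_edges[oc] = np.concatenate(
                [mesh.cell_edges[oc][:pos_in], np.array(pair, dtype=np.intp),
                 mesh.cell_edges[oc][pos_in + 1:]]
            )
            mesh.cell_signs[oc] = np.concatenate(
                [mesh.cell_signs[oc][:pos_in], np.array([sgn_oc, sgn_oc], dtype=np.intp),
                 mesh.cell_signs[oc][pos_in + 1:]]
            )
        first, second = (eid, new_eid) if sgn > 0 else (new_eid, eid)
        return w, first, second

    w1, e1_first, e1_second = split_edge(k1, p1)
    w2, e2_first, e2_second = split_edge(k2, p2)

    chord_eid = mesh.n_edges
    mesh.edges = np.vstack([mesh.edges, np.array([[w1, w2]], dtype=np.intp)])

    # rebuild the two daughter loops by walking the parent loop
    def directed(eid: int, v_from: int) -> tuple[int, int]:
        t, h = (int(v) for v in mesh.edges[eid])
        return (eid, 1) if t == v_from else (eid, -1)

    # daughter 1: w1 -> loop[k1+1] ... loop[k2] -> w2 -> (chord) -> w1
    d1_edges: list[tuple[int, int]] = [directed(e1_second, w1)]
    kk = (k1 + 1) % n
    while kk != k2:
        va, vb = loop[kk], loop[(kk + 1) % n]
        eid, sgn = edge_lookup[(va, vb)]
        d1_edges.append((eid, sgn))
        kk = (kk + 1) % n
    d1_edges.append(directed(e2_first, loop[k2]))
    d1_edges.append((chord_eid, -1))  # w2 -> w1

    # daughter 2: w2 -> loop[k2+1] ... loop[k1] -> w1 -> (chord) -> w2
    d2_edges: list[tuple[int, int]] = [directed(e2_second, w2)]
    kk = (k2 + 1) % n
    while kk != k1:
        va, vb = loop[kk], loop[(kk + 1) % n]
        eid, sgn = edge_lookup[(va, vb)]
        d2_edges.append((eid, sgn))
        kk = (kk + 1) % n
    d2_edges.append(directed(e1_first, loop[k1]))
    d2_edges.append((chord_eid, 1))  # w1 -> w2

    pr = params if params is not None else MechParams()
    jit = pr.cycle_jitter

    def daughter_state() -> CellState:
        ct = pr.cycle_time * float(rng.uniform(1 - jit, 1 + jit)) if jit > 0 else pr.cycle_time
        return CellState(
            age=0.0,
            preferred_area=1.0,
            stiffness=state.stiffness,
            is_mcc=state.is_mcc,
            can_divide=state.can_divide,
            cycle_time=ct,
        )

    mesh.cell_edges[ci] = np.asarray([e for e, _ in d1_edges], dtype=np.intp)
    mesh.cell_signs[ci] = np.asarray([s for _, s in d1_edges], dtype=np.intp)
    mesh.cells[ci] = daughter_state()
    mesh.cell_edges.append(np.asarray([e for e, _ in d2_edges], dtype=np.intp))
    mesh.cell_signs.append(np.asarray([s for _, s in d2_edges], dtype=np.intp))
    mesh.cells.append(daughter_state())
    mesh.invalidate()
    return ci, mesh.n_cells - 1


# ---------------------------------------------------------------------------
# T1 neighbour exchange
# ---------------------------------------------------------------------------

def t1_transition(mesh: Mesh, eid: int, params: MechParams, strict: bool = True) -> bool:
    """Neighbour exchange on interior edge ``eid``.

    The edge is rotated 90 degrees about its midpoint and set to length
    ``1.5 * t1_threshold``; the two cells formerly sharing the edge lose
    adjacency while the two flanking cells gain it.  Vertex/edge/cell counts
    are unchanged.  Returns True on success; ineligible edges are skipped with
    a log entry (or raise when ``strict``).
    """

    def bail(msg: str) -> bool:
        if strict:
            raise ValueError(msg)
        log.debug("T1 skipped on edge %d: %s", eid, msg)
        return False

    edge_cells = mesh.edge_cells()
    if len(edge_cells[eid]) != 2:
        return bail("boundary edge")
    u, w = (int(v) for v in mesh.edges[eid])
    deg = mesh.vertex_degree()
    if deg[u] != 3 or deg[w] != 3:
        return bail("endpoint vertex degree != 3")

    cp, cq = edge_cells[eid]
    # P traverses the edge tail->head (sign +1)
    pos_p = int(np.flatnonzero(mesh.cell_edges[cp] == eid)[0])
    if mesh.cell_signs[cp][pos_p] < 0:
        cp, cq = cq, cp
    if len(mesh.cell_edges[cp]) <= 3 or len(mesh.cell_edges[cq]) <= 3:
        return bail("a bordering cell is a triangle")

    # other edges at u and at w
    at_u = [e for e in range(mesh.n_edges) if u in mesh.edges[e] and e != eid]
    at_w = [e for e in range(mesh.n_edges) if w in mesh.edges[e] and e != eid]
    if len(at_u) != 2 or len(at_w) != 2:
        return bail("inconsistent vertex incidence")

    def cells_of(e: int) -> set[int]:
        return set(edge_cells[e])

    p_set, q_set = {cp}, {cq}
    a_p = next((e for e in at_u if cp in cells_of(e)), None)
    a_q = next((e for e in at_u if cq in cells_of(e)), None)
    b_p = next((e for e in at_w if cp in cells_of(e)), None)
    b_q = next((e for e in at_w if cq in cells_of(e)), None)
    if None in (a_p, a_q, b_p, b_q):
        return bail("could not identify flanking edges")
    r_cells = cells_of(a_p) & cells_of(a_q) - p_set - q_set
    s_cells = cells_of(b_p) & cells_of(b_q) - p_set - q_set
    # R (S) is the third cell at u (w); may be absent if u (w) is on the boundary
    cr = next(iter(r_cells)) if r_cells else None
    cs = next(iter(s_cells)) if s_cells else None
    if cr is None or cs is None:
        return bail("an endpoint touches the tissue boundary")
    if cr == cs:
        return bail("flanking cells coincide")

    # --- geometry: rotate about midpoint; u moves to P's side, w to Q's side
    pu, pw = mesh.vertices[u], mesh.vertices[w]
    mid = 0.5 * (pu + pw)
    d = pw - pu
    dn = d / max(np.hypot(*d), 1e-300)
    n_ccw = np.array([-dn[1], dn[0]])  # points into P (interior on the left of u->w)
    half = 0.75 * params.t1_threshold
    mesh.vertices[u] = mid + half * n_ccw
    mesh.vertices[w] = mid - half * n_ccw

    # --- topology: reattach the flanking edges, move `eid` from P,Q to R,S
    def replace_vertex(e: int, old: int, new: int) -> None:
        t, h = (int(v) for v in mesh.edges[e])
        mesh.edges[e] = (new if t == old else t, new if h == old else h)

    replace_vertex(b_p, w, u)  # P's corner collapses onto u
    replace_vertex(a_q, u, w)  # Q's corner collapses onto w

    def rebuild(cidx: int, edge_set: list[int]) -> None:
        eids, sgns = loop_from_edge_set(mesh, edge_set)
        mesh.cell_edges[cidx] = eids
        mesh.cell_signs[cidx] = sgns

    rebuild(cp, [e for e in mesh.cell_edges[cp] if e != eid])
    rebuild(cq, [e for e in mesh.cell_edges[cq] if e != eid])
    rebuild(cr, list(mesh.cell_edges[cr]) + [eid])
    rebuild(cs, list(mesh.cell_edges[cs]) + [eid])
    mesh.invalidate()
    return True


# ---------------------------------------------------------------------------
# time stepping with division
# ---------------------------------------------------------------------------

def advance(
    mesh: Mesh,
    params: MechParams,
    duration: float,
    rng: np.random.Generator,
    stop_at_cells: int | None = None,
    divide: bool = True,
) -> Mesh:
    """Advance model time: relaxation interleaved with ageing and divisions.

    Divisions are processed one at a time in age order (oldest overdue cell
    first), so any target cell count is hit exactly.  Growth-phase relaxation
    uses the looser ``growth_force_tol`` with a bounded step budget per
    division event; callers wanting a tight equilibrium should call
    :func:`relax` afterwards.
    """
    t = 0.0
    dt_carry: float | None = None
    while True:
        res = relax(mesh, params, max_steps=params.growth_max_steps,
                    force_tol=params.growth_force_tol, dt0=dt_carry)
        dt_carry = res.dt_final
        if stop_at_cells is not None and mesh.n_cells >= stop_at_cells:
            return mesh
        if not divide:
            if duration - t <= 0:
                return mesh
            for c in mesh.cells:
                c.age += duration - t
            return mesh
        waits = [
            (c.cycle_time - c.age, i)
            for i, c in enumerate(mesh.cells)
            if c.can_divide
        ]
        if not waits:
            for c in mesh.cells:
                c.age += duration - t
            return mesh
        wait, ci = min(waits)
        wait = max(wait, 0.0)
        if t + wait >= duration and stop_at_cells is None:
            for c in mesh.cells:
                c.age += duration - t
            return mesh
        for c in mesh.cells:
            c.age += wait
        t += wait
        divide_cell(mesh, ci, rng, params)


def grow_to(mesh: Mesh, params: MechParams, n_cells: int, rng: np.random.Generator) -> Mesh:
    """Grow by division until the cell count reaches exactly ``n_cells``."""
    if mesh.n_cells > n_cells:
        raise ValueError("mesh already larger than requested count")
    return advance(mesh, params, duration=np.inf, rng=rng, stop_at_cells=n_cells)
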