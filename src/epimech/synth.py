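"""Synthetic inputs for the analysis stages.

Three generators stand in for the segmented time-lapse data the analyses were
designed for:

* :func:`gen_tissue` — a Lloyd-relaxed Voronoi tessellation of a disc,
  emulating a segmented epithelial field (areas in um^2, default mean apical
  area 412 um^2 so a 94 um^2 ruffle is ~23% of a cell).
* :func:`gen_known_tension_mesh` — a junction network equilibrated under
  known heterogeneous tensions; the ground truth oracle for the tension
  inference.
* :func:`gen_events` / :func:`gen_compression_wave` — macropinocytosis event
  tables and per-cell area / per-junction length tracks with the measured
  statistical structure: duration 9.3 +- 2.3 min, peak ruffle area 94 +- 36
  um^2 (~22.8 +- 6.6 % of apical area), ~10% apical-area loss per event
  coupled to event size (r^2 ~ 0.4 at n = 43), ~10% shortening of the event
  junction, events never hosted by MCCs, and an adjacency-biased event rate.

Every generator is a deterministic function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

from ._rng import rng_for
from .tension import Junction, JunctionNetwork, build_junction_network

__all__ = [
    "EventGenParams",
    "Tissue",
    "gen_tissue",
    "gen_known_tension_mesh",
    "gen_events",
    "gen_compression_wave",
    "CellTracks",
]


@dataclass
class EventGenParams:
    """Statistical structure of generated macropinocytosis events.

    Defaults are the measured study conditions; ``loss_noise_sd`` is the
    calibrated event-to-event scatter of the fractional area loss that places
    the size/shrinkage correlation near r^2 = 0.4 at n = 43 (see
    docs/methods.md).
    """

    rate_per_cell_hour: float = 0.15
    duration_mean: float = 9.3          # min
    duration_sd: float = 2.3
    peak_area_mean: float = 94.0        # um^2
    peak_area_sd: float = 36.0
    apical_fraction_mean: float = 22.8  # %
    apical_fraction_sd: float = 6.6
    loss_fraction: float = 0.10         # mean fractional apical-area loss per event
    loss_noise_sd: float = 0.046        # calibrated: r^2(peak area, loss) ~ 0.4 at n=43
    junction_shortening: float = 0.10
    junction_noise_sd: float = 0.02
    p_junctional: float = 0.75
    mcc_adjacent_multiplier: float = 2.0
    frame_noise_sd: float = 0.005       # multiplicative per-frame measurement noise

    def __post_init__(self) -> None:
        for name in ("duration_sd", "peak_area_sd", "loss_noise_sd",
                     "junction_noise_sd", "frame_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.p_junctional <= 1:
            raise ValueError("p_junctional must be a probability")
        if self.rate_per_cell_hour < 0:
            raise ValueError("rate must be >= 0")

    def replace(self, **kw) -> "EventGenParams":
        return replace(self, **kw)


@dataclass
class Tissue:
    """Synthetic segmented tissue: polygons (um), centroids, adjacency, labels."""

    polygons: list[np.ndarray]
    centroids: np.ndarray
    adjacency: "object"                 # networkx.Graph over cell ids
    areas: np.ndarray                   # um^2
    is_mcc: np.ndarray                  # bool per cell
    mcc_adjacent: np.ndarray            # bool per cell

    @property
    def n_cells(self) -> int:
        return len(self.polygons)


def _lloyd(points: np.ndarray, radius: float, iters: int) -> np.ndarray:
    """Lloyd relaxation inside a disc via Voronoi clipping."""
    disc = Point(0, 0).buffer(radius, quad_segs=64)
    pts = points.copy()
    for _ in range(iters):
        vor = _bounded_voronoi(pts, radius)
        new = []
        for region in vor:
            c = Polygon(region).centroid
            new.append([c.x, c.y])
        pts = np.asarray(new)
    return pts


def _bounded_voronoi(points: np.ndarray, radius: float) -> list[np.ndarray]:
    """Voronoi cells of `points` clipped to the disc of given radius.

    Far mirror points make all central regions finite before clipping.
    """
    n = len(points)
    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    far = 4.0 * radius * np.column_stack([np.cos(ang), np.sin(ang)])
    vor = Voronoi(np.vstack([points, far]))
    disc = Point(0, 0).buffer(radius, quad_segs=32)
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise RuntimeError("unbounded Voronoi region despite mirror points")
        poly = Polygon(vor.vertices[region])
        clipped = poly.intersection(disc)
        xy = np.asarray(clipped.exterior.coords)[:-1]
        polys.append(xy)
    return polys


def gen_tissue(
    n_cells: int,
    seed: int,
    mean_area_um2: float = 412.0,
    lloyd_iters: int = 3,
    label_mccs: bool = False,
) -> Tissue:
    """Poisson-disc points -> Voronoi -> Lloyd iterations, clipped to a disc.

    The disc is scaled so the mean cell area is ``mean_area_um2`` (the
    measured mean goblet-cell apical area is ~412 um^2: a 94 um^2 ruffle is
    22.8% of it).  With ``label_mccs`` a spaced subset of non-peripheral
    cells is flagged as MCCs using the same exclusion-radius placement as the
    simulation protocol.
    """
    if n_cells < 3:
        raise ValueError("need at least 3 cells")
    rng = rng_for(seed, "tissue")
    radius = np.sqrt(n_cells * mean_area_um2 / np.pi)
    # dart-throwing Poisson disc: min spacing ~0.75 of the mean lattice spacing
    min_d = 0.75 * np.sqrt(mean_area_um2)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_cells and attempts < 200 * n_cells:
        cand = (rng.uniform(-1, 1, 2)) * radius
        attempts += 1
        if np.hypot(*cand) > radius * 0.98:
            continue
        if all(np.hypot(*(cand - p)) >= min_d for p in pts):
            pts.append(cand)
    if len(pts) < n_cells:
        raise RuntimeError("Poisson-disc sampling failed; lower n_cells or spacing")
    points = _lloyd(np.asarray(pts), radius, lloyd_iters)
    polys = _bounded_voronoi(points, radius)

    import networkx as nx
    from shapely.strtree import STRtree

    shp = [Polygon(p) for p in polys]
    tree = STRtree(shp)
    g = nx.Graph()
    g.add_nodes_from(range(n_cells))
    for i, pi in enumerate(shp):
        for j in tree.query(pi):
            j = int(j)
            if j <= i:
                continue
            inter = pi.intersection(shp[j])
            if inter.length > 1e-9 * radius:
                g.add_edge(i, j)
    areas = np.array([p.area for p in shp])
    cents = np.array([[p.centroid.x, p.centroid.y] for p in shp])

    is_mcc = np.zeros(n_cells, dtype=bool)
    if label_mccs:
        peripheral = {
            i for i, p in enumerate(polys)
            if np.any(np.hypot(p[:, 0], p[:, 1]) > 0.999 * radius)
        }
        pool = set(range(n_cells)) - peripheral
        chosen: set[int] = set()
        while pool:
            pick = int(rng.choice(sorted(pool)))
            chosen.add(pick)
            shells, frontier = {pick}, {pick}
            for _ in range(3):
                frontier = {v for f in frontier for v in g.neighbors(f)} - shells
                shells |= frontier
            pool -= shells
            pool.discard(pick)
        is_mcc[list(chosen)] = True
    adj = np.zeros(n_cells, dtype=bool)
    for i in np.flatnonzero(is_mcc):
        for j in g.neighbors(int(i)):
            adj[j] = True
    adj &= ~is_mcc
    return Tissue(polys, cents, g, areas, is_mcc, adj)


# ---------------------------------------------------------------------------
# known-tension geometry (oracle for the inference)
# ---------------------------------------------------------------------------

def _circumcenters(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a, b, c = (points[simplices[:, k]] for k in range(3))
    ax, ay = a[:, 0], a[:, 1]
    bx, by = b[:, 0], b[:, 1]
    cx, cy = c[:, 0], c[:, 1]
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    return np.column_stack([ux, uy])


def gen_known_tension_mesh(
    n_cells: int,
    tension_cv: float,
    seed: int,
) -> tuple[JunctionNetwork, np.ndarray]:
    """Equilibrated junction network with exactly known per-junction tensions.

    Built on the Maxwell reciprocal-diagram property of Voronoi tessellations:
    a Voronoi diagram is in exact force balance at every interior vertex under
    tensions equal to the lengths of the dual Delaunay edges (the three dual
    edges of a triangle sum to zero, and each Voronoi edge is perpendicular to
    its dual).  To control the tension distribution, generator points are
    adjusted by least squares so the Delaunay edge lengths rank-match a
    lognormal sample (mean 1, coefficient of variation ``tension_cv``); the
    *achieved* edge lengths of the final triangulation, normalised to mean 1,
    are returned as the ground truth, so the force balance is exact to machine
    precision (well below the 1e-8 residual contract) regardless of how
    closely the target distribution was met.

    Returns the network (nodes = Voronoi vertices / circumcenters; junction
    "cells" = the two generator cells it separates) and the true tensions.
    """
    if n_cells < 7:
        raise ValueError("need at least 7 cells")
    rng = rng_for(seed, "tension-truth")
    radius = np.sqrt(n_cells / np.pi)
    if tension_cv == 0:
        # uniform tensions: the exact triangular lattice realises them
        # (equilateral Delaunay -> honeycomb Voronoi, all dual lengths equal);
        # a hexagonal patch keeps the hull aligned with the lattice (no ears)
        rings = 1
        while 3 * rings * (rings + 1) + 1 < n_cells:
            rings += 1
        pts = []
        for q in range(-rings, rings + 1):
            for r in range(max(-rings, -q - rings), min(rings, -q + rings) + 1):
                pts.append((q + r / 2.0, np.sqrt(3) / 2.0 * r))
        points = np.asarray(pts)
    else:
        min_d = 0.75
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n_cells and attempts < 400 * n_cells:
            cand = rng.uniform(-1, 1, 2) * radius
            attempts += 1
            if np.hypot(*cand) > radius:
                continue
            if all(np.hypot(*(cand - p)) >= min_d for p in pts):
                pts.append(cand)
        if len(pts) < n_cells:
            raise RuntimeError("Poisson-disc sampling failed")
        points = np.asarray(pts)

    from scipy.optimize import least_squares
    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    edges = sorted({tuple(sorted((s[i], s[j])))
                    for s in tri.simplices for i, j in ((0, 1), (1, 2), (0, 2))})
    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])

    def lengths(p: np.ndarray) -> np.ndarray:
        d = p[ej] - p[ei]
        return np.hypot(d[:, 0], d[:, 1])

    l0 = lengths(points)
    if tension_cv > 0:
        s2 = np.log(1.0 + tension_cv**2)
        sample = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=len(edges))
    else:
        sample = np.ones(len(edges))
    target = np.sort(sample)[np.argsort(np.argsort(l0))] * float(np.mean(l0))

    anchor = 0.05  # weak tie to the initial layout fixes the global pose
    x0 = points.ravel()

    def resid(x: np.ndarray) -> np.ndarray:
        p = x.reshape(-1, 2)
        return np.concatenate([lengths(p) - target, anchor * (x - x0)])

    sol = least_squares(resid, x0, method="trf", max_nfev=200)
    points = sol.x.reshape(-1, 2)

    # re-triangulate: the truth is whatever the final geometry realises
    tri = Delaunay(points)
    simplices = tri.simplices
    z = _circumcenters(points, simplices)
    nb = tri.neighbors
    n_tri = len(simplices)

    junctions = []
    t_list = []
    pair_index: dict[tuple[int, int], int] = {}
    for T in range(n_tri):
        for k in range(3):
            Tn = nb[T][k]
            if Tn < 0 or Tn < T:
                continue
            i, j = [int(v) for m, v in enumerate(simplices[T]) if m != k]
            if np.hypot(*(z[Tn] - z[T])) < 1e-10:
                continue  # cocircular degeneracy: zero-length Voronoi edge
            pair_index[(T, int(Tn))] = len(junctions)
            junctions.append(Junction(
                node_a=T, node_b=int(Tn),
                points=np.vstack([z[T], z[Tn]]),
                cells=frozenset((i, j)),
            ))
            t_list.append(float(np.hypot(*(points[i] - points[j]))))
    t_true = np.asarray(t_list)
    t_true /= np.mean(t_true)

    # interior nodes: all three dual edges present (no hull side, no dropped edge)
    interior = np.zeros(n_tri, dtype=bool)
    for T in range(n_tri):
        ok = True
        for k in range(3):
            Tn = nb[T][k]
            if Tn < 0 or (min(T, Tn), max(T, Tn)) not in pair_index:
                ok = False
                break
        interior[T] = ok

    out = JunctionNetwork(node_positions=z, junctions=junctions, interior=interior)
    resid_max = 0.0
    for node in np.flatnonzero(interior):
        f = np.zeros(2)
        for jid in out.node_junctions[node]:
            f += t_true[jid] * out.junctions[jid].tangent_at(int(node))
        resid_max = max(resid_max, float(np.hypot(*f)))
    out.relax_residual = resid_max
    out.relax_converged = resid_max < 1e-8
    return out, t_true


# ---------------------------------------------------------------------------
# event and track generation
# ---------------------------------------------------------------------------

@dataclass
class CellTracks:
    """Per-cell apical-area and per-junction length time series."""

    areas: pd.DataFrame                  # index: time (min), columns: cell id
    junction_lengths: pd.DataFrame | None
    frame_interval: float                # min
    extrusions: pd.DataFrame | None = None   # columns: cell, time

    @property
    def times(self) -> np.ndarray:
        return self.areas.index.to_numpy()


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size=size)
    scalar = np.isscalar(out)
    out = np.atleast_1d(out)
    for k in range(out.size):
        tries = 0
        while not (lo < out[k] < hi) and tries < 100:
            out[k] = rng.normal(mean, sd)
            tries += 1
        out[k] = np.clip(out[k], lo + 1e-9, hi - 1e-9)
    return float(out[0]) if scalar else out


def gen_events(
    tissue: Tissue,
    params: EventGenParams,
    duration: float,
    seed: int,
    frame_interval: float = 0.5,
) -> tuple[pd.DataFrame, CellTracks]:
    """Poisson macropinocytosis events with the measured per-event structure.

    Events arrive per cell as a homogeneous Poisson process (rate scaled by
    the MCC-adjacency multiplier); MCCs never host events.  Each event draws a
    truncated-normal duration and peak ruffle area, removes a fraction
    ``loss_fraction * (peak / peak_mean) + N(0, loss_noise_sd)`` of the host's
    apical area as a linear ramp over the event, and shortens one host
    junction by ``junction_shortening``.  Tracks carry multiplicative
    per-frame measurement noise.
    """
    if duration < params.duration_mean + 3 * params.duration_sd:
        raise ValueError("recording shorter than a typical event duration")
    rng = rng_for(seed, "events")
    times = np.round(np.arange(0.0, duration + 1e-9, frame_interval), 9)
    nt = len(times)
    n = tissue.n_cells
    hours = duration / 60.0

    events = []
    eid = 0
    margin = 1.0  # min; events must fit inside the recording
    for ci in range(n):
        if tissue.is_mcc[ci]:
            continue
        mult = params.mcc_adjacent_multiplier if tissue.mcc_adjacent[ci] else 1.0
        lam = params.rate_per_cell_hour * mult * hours
        for _ in range(rng.poisson(lam)):
            dur = _truncated_normal(rng, params.duration_mean, params.duration_sd,
                                    1.0, np.inf)
            if dur + 2 * margin > duration:
                continue
            onset = float(rng.uniform(margin, duration - dur - margin))
            peak = _truncated_normal(rng, params.peak_area_mean, params.peak_area_sd,
                                     0.0, tissue.areas[ci])
            junctional = bool(rng.uniform() < params.p_junctional)
            events.append(
                {"event": eid, "cell": ci, "onset": onset, "duration": dur,
                 "peak_area": peak,
                 "location": "junctional" if junctional else "medial",
                 "adjacency": "mcc_adjacent" if tissue.mcc_adjacent[ci]
                              else "non_adjacent"}
            )
            eid += 1
    table = pd.DataFrame(
        events, columns=["event", "cell", "onset", "duration", "peak_area",
                         "location", "adjacency"]
    )

    # --- area tracks: baseline with a permanent ramped loss per event
    areas = np.tile(tissue.areas, (nt, 1)).astype(float)
    loss_fracs = []
    for _, ev in table.iterrows():
        frac = (params.loss_fraction * ev.peak_area / params.peak_area_mean
                + rng.normal(0.0, params.loss_noise_sd))
        frac = float(np.clip(frac, 0.0, 0.9))
        loss_fracs.append(frac)
        ci = int(ev.cell)
        ramp = np.clip((times - ev.onset) / ev.duration, 0.0, 1.0)
        areas[:, ci] *= 1.0 - frac * ramp
    if len(table):
        table = table.assign(loss_fraction=loss_fracs)
    if params.frame_noise_sd > 0:
        areas *= 1.0 + rng.normal(0.0, params.frame_noise_sd, size=areas.shape)
    areas_df = pd.DataFrame(areas, index=times, columns=range(n))

    # --- junction tracks: one junction per tissue adjacency pair
    jl = {}
    jmap = {}
    for k, (a, b) in enumerate(sorted(tissue.adjacency.edges())):
        base = np.sqrt(min(tissue.areas[a], tissue.areas[b]))  # ~edge-length scale
        jl[k] = np.full(nt, base)
        jmap[(a, b)] = k
        jmap[(b, a)] = k
    event_junction = np.full(len(table), -1)
    for i, (_, ev) in enumerate(table.iterrows()):
        if ev.location != "junctional":
            continue
        nbrs = list(tissue.adjacency.neighbors(int(ev.cell)))
        if not nbrs:
            continue
        nb = int(nbrs[int(rng.integers(len(nbrs)))])
        jid = jmap[(int(ev.cell), nb)]
        event_junction[i] = jid
        short = params.junction_shortening + rng.normal(0.0, params.junction_noise_sd)
        short = float(np.clip(short, 0.0, 0.9))
        ramp = np.clip((times - ev.onset) / ev.duration, 0.0, 1.0)
        jl[jid] = jl[jid] * (1.0 - short * ramp)
    if len(table):
        table = table.assign(junction=event_junction)
    jdf = pd.DataFrame(jl, index=times)
    if params.frame_noise_sd > 0:
        jdf *= 1.0 + rng.normal(0.0, params.frame_noise_sd, size=jdf.shape)

    tracks = CellTracks(areas=areas_df, junction_lengths=jdf,
                        frame_interval=frame_interval)
    return table, tracks


def gen_compression_wave(
    tissue: Tissue,
    seed: int,
    duration: float = 40.0,
    pulse_center: float = 15.0,
    pulse_sd: float = 3.0,
    events_per_cell: float = 2.0,
    frame_interval: float = 0.5,
    n_extrusions: int = 3,
    neighbor_suppression: float = 0.3,
    inhibitor: bool = False,
    inhibitor_rate_factor: float = 0.1,
    inhibitor_extrusion_factor: float = 3.0,
    params: EventGenParams | None = None,
) -> tuple[pd.DataFrame, CellTracks, pd.DataFrame]:
    """A compression-induced wave of macropinocytosis, with optional extrusions.

    Event onsets follow a Gaussian pulse in time centred at ``pulse_center``;
    at the default intensity (2 expected events per cell) >= 80% of cells host
    at least one event.  Extruded cells' direct neighbours have their
    post-extrusion event rate suppressed (x ``neighbor_suppression``).  In
    inhibitor mode the event intensity drops x ``inhibitor_rate_factor`` and
    extrusions multiply by ``inhibitor_extrusion_factor``.
    """
    p = params if params is not None else EventGenParams()
    rng = rng_for(seed, "wave")
    times = np.round(np.arange(0.0, duration + 1e-9, frame_interval), 9)
    nt = len(times)
    n = tissue.n_cells
    lam = events_per_cell * (inhibitor_rate_factor if inhibitor else 1.0)

    n_ext = int(round(n_extrusions * (inhibitor_extrusion_factor if inhibitor else 1.0)))
    candidates = np.flatnonzero(~tissue.is_mcc)
    ext_cells = rng.choice(candidates, size=min(n_ext, len(candidates)), replace=False)
    ext_times = rng.uniform(pulse_center - pulse_sd, pulse_center + pulse_sd, len(ext_cells))
    extrusions = pd.DataFrame({"cell": ext_cells.astype(int), "time": ext_times})
    suppressed: dict[int, float] = {}
    for c, t0 in zip(ext_cells, ext_times):
        for nb in tissue.adjacency.neighbors(int(c)):
            suppressed[int(nb)] = min(suppressed.get(int(nb), np.inf), float(t0))

    events = []
    eid = 0
    for ci in range(n):
        if tissue.is_mcc[ci]:
            continue
        for _ in range(rng.poisson(lam)):
            onset = float(rng.normal(pulse_center, pulse_sd))
            dur = _truncated_normal(rng, p.duration_mean, p.duration_sd, 1.0, np.inf)
            if onset < 0.5 or onset + dur > duration - 0.5:
                continue
            if ci in suppressed and onset > suppressed[ci] \
                    and rng.uniform() > neighbor_suppression:
                continue
            peak = _truncated_normal(rng, p.peak_area_mean, p.peak_area_sd,
                                     0.0, tissue.areas[ci])
            events.append({"event": eid, "cell": ci, "onset": onset, "duration": dur,
                           "peak_area": peak, "location": "junctional",
                           "adjacency": "mcc_adjacent" if tissue.mcc_adjacent[ci]
                                        else "non_adjacent"})
            eid += 1
    table = pd.DataFrame(
        events, columns=["event", "cell", "onset", "duration", "peak_area",
                         "location", "adjacency"]
    )

    areas = np.tile(tissue.areas, (nt, 1)).astype(float)
    for _, ev in table.iterrows():
        frac = float(np.clip(
            p.loss_fraction * ev.peak_area / p.peak_area_mean
            + rng.normal(0.0, p.loss_noise_sd), 0.0, 0.9))
        ramp = np.clip((times - ev.onset) / ev.duration, 0.0, 1.0)
        areas[:, int(ev.cell)] *= 1.0 - frac * ramp
    # extruded cells shrink to (near) zero over ~5 min and stay out
    for c, t0 in zip(ext_cells, ext_times):
        ramp = np.clip((times - t0) / 5.0, 0.0, 1.0)
        areas[:, int(c)] *= np.maximum(1.0 - ramp, 0.02)
    if p.frame_noise_sd > 0:
        areas *= 1.0 + rng.normal(0.0, p.frame_noise_sd, size=areas.shape)
    tracks = CellTracks(
        areas=pd.DataFrame(areas, index=times, columns=range(n)),
        junction_lengths=None,
        frame_interval=frame_interval,
        extrusions=extrusions,
    )
    return table, tracks, extrusions
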