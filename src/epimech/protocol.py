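"""The simulated ciliated-epithelium experiment.

A monolayer is grown from a regular 61-cell hexagonal patch by asynchronous
cell division to 400 cells; evenly spaced multiciliated cells (MCCs) are then
chosen from the non-peripheral cells with a topological exclusion radius of
three cell shells, made sigma-times stiffer and barred from dividing; growth
continues to 800 cells; all division stops and the monolayer relaxes to
mechanical equilibrium.  Ten independent replicates are run per parameter set
(sigma in {1, 10}, optionally with dividing MCCs as a control).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .mesh import Mesh, adjacency_graph, build_hex_monolayer, peripheral_cells
from .mechanics import MechParams, RelaxResult, cell_mechanics, grow_to, relax
from ._rng import rng_for

__all__ = ["ProtocolConfig", "SimResult", "select_mccs", "run_protocol", "run_ensemble"]

log = logging.getLogger(__name__)

#: graph-distance shells removed from the candidate pool around each chosen MCC
EXCLUSION_SHELLS = 3


@dataclass
class ProtocolConfig:
    """Configuration of one simulation experiment.

    The default profile is the full 61 -> 400 -> 800 protocol; the ``scaled``
    profile (rings=3, 100 -> 200) is a fast test-sized variant of the same
    experiment.
    """

    rings: int = 4
    n_cells_at_mcc_intro: int = 400
    n_cells_final: int = 800
    sigma_mcc: float = 10.0
    mcc_divide: bool = False
    n_replicates: int = 10
    base_seed: int = 0
    mech: MechParams = field(default_factory=MechParams)

    def __post_init__(self) -> None:
        n0 = 3 * self.rings * (self.rings + 1) + 1
        if not n0 <= self.n_cells_at_mcc_intro <= self.n_cells_final:
            raise ValueError("cell-count thresholds must be ordered: initial <= intro <= final")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigma_mcc <= 0:
            raise ValueError("sigma_mcc must be positive")

    def replace(self, **kw) -> "ProtocolConfig":
        return replace(self, **kw)

    @classmethod
    def scaled(cls, **kw) -> "ProtocolConfig":
        """Fast test profile: 37-cell seed grown 100 -> 200 cells."""
        base = dict(rings=3, n_cells_at_mcc_intro=100, n_cells_final=200,
                    mech=MechParams(force_tol=1e-4))
        base.update(kw)
        return cls(**base)


@dataclass
class SimResult:
    """Output of one protocol run."""

    final_mesh: Mesh
    mesh_at_intro: Mesh
    mesh_at_arrest: Mesh
    mcc_ids: list[int]
    mechanics: "object"  # CellMechanics at equilibrium
    config: ProtocolConfig
    seed: int
    relax_info: RelaxResult | None = None
    converged: bool = True
    error: str | None = None


def select_mccs(mesh: Mesh, rng: np.random.Generator) -> set[int]:
    """Evenly spaced MCC selection with a 3-shell topological exclusion radius.

    Repeatedly pick a cell uniformly at random from the eligible pool
    (non-peripheral, not yet excluded), then remove the chosen cell and its
    first, second and third topological neighbour shells from the pool, until
    the pool is empty.  The result is maximal, and the shortest adjacency path
    between any two chosen cells passes through at least three intermediate
    cells (graph distance >= 4).
    """
    graph = adjacency_graph(mesh)
    periph = peripheral_cells(mesh)
    pool = set(range(mesh.n_cells)) - periph
    if not pool:
        warnings.warn("no non-peripheral cells: MCC selection is empty", stacklevel=2)
        return set()
    chosen: set[int] = set()
    while pool:
        pick = int(rng.choice(sorted(pool)))
        chosen.add(pick)
        shells = {pick}
        frontier = {pick}
        for _ in range(EXCLUSION_SHELLS):
            frontier = {n for f in frontier for n in graph.neighbors(f)} - shells
            shells |= frontier
        pool -= shells
        pool.discard(pick)
    return chosen


def mcc_pair_min_intermediates(mesh: Mesh, mccs: set[int]) -> int | None:
    """Minimum count of intermediate cells on shortest adjacency paths between MCC pairs."""
    if len(mccs) < 2:
        return None
    graph = adjacency_graph(mesh)
    ids = sorted(mccs)
    best = None
    for i, a in enumerate(ids):
        lengths = nx.single_source_shortest_path_length(graph, a)
        for b in ids[i + 1:]:
            d = lengths.get(b)
            if d is not None:
                inter = d - 1
                best = inter if best is None else min(best, inter)
    return best


def run_protocol(config: ProtocolConfig, seed: int) -> SimResult:
    """Run one full growth / MCC-introduction / arrest / relaxation experiment."""
    rng_init = rng_for(seed, "init")
    rng_growth = rng_for(seed, "growth")
    rng_mcc = rng_for(seed, "mcc")
    mech = config.mech

    mesh = build_hex_monolayer(config.rings, rng=rng_init,
                               cycle_time=mech.cycle_time, cycle_jitter=mech.cycle_jitter)
    grow_to(mesh, mech, config.n_cells_at_mcc_intro, rng_growth)
    mesh_at_intro = mesh.copy()

    mccs = select_mccs(mesh, rng_mcc)
    for ci in sorted(mccs):
        st = mesh.cells[ci]
        st.is_mcc = True
        st.stiffness = config.sigma_mcc
        st.can_divide = bool(config.mcc_divide)
    mesh.invalidate()  # per-cell stiffness changed; drop cached sigma/A0 arrays

    grow_to(mesh, mech, config.n_cells_final, rng_growth)
    mesh_at_arrest = mesh.copy()

    for st in mesh.cells:
        st.can_divide = False
    info = relax(mesh, mech)
    if not info.converged:
        log.warning("final relaxation did not reach force_tol=%g (max |F|=%g after %d steps)",
                    mech.force_tol, info.max_force, info.steps)

    spacing = mcc_pair_min_intermediates(mesh, {i for i in mccs if mesh.cells[i].is_mcc})
    if spacing is not None and spacing < EXCLUSION_SHELLS:
        log.info("MCC spacing fell below %d intermediate cells after rearrangements: %d",
                 EXCLUSION_SHELLS, spacing)

    return SimResult(
        final_mesh=mesh,
        mesh_at_intro=mesh_at_intro,
        mesh_at_arrest=mesh_at_arrest,
        mcc_ids=sorted(mccs),
        mechanics=cell_mechanics(mesh, mech),
        config=config,
        seed=seed,
        relax_info=info,
        converged=info.converged,
    )


def run_ensemble(config: ProtocolConfig) -> list[SimResult]:
    """``n_replicates`` independent runs with seeds ``base_seed + k``."""
    results: list[SimResult] = []
    for k in range(config.n_replicates):
        seed = config.base_seed + k
        try:
            results.append(run_protocol(config, seed))
        except Exception as exc:  # collect, do not abort the ensemble
            log.error("replicate %d (seed %d) failed: %r", k, seed, exc)
            results.append(SimResult(
                final_mesh=None, mesh_at_intro=None, mesh_at_arrest=None,
                mcc_ids=[], mechanics=None, config=config, seed=seed,
                converged=False, error=repr(exc),
            ))
    return results
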