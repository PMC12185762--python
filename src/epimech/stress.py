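"""Per-cell stress measures and MCC-neighbourhood decile enrichment statistics.

Cell-level stress tensor (package contract)
-------------------------------------------
For cell i with internal pressure ``p_i``, cortical tension ``t_i``, area
``A_i`` and edge vectors ``l_e``:

``S_i = -(p_i - P_ext) * I + (1/A_i) * sum_e t_i * (l_e (x) l_e) / |l_e|``

The isotropic part ``-(p_i - P_ext)`` is reported as the cell's *effective
pressure*: negative values mean the cell is squeezed below its preferred area
(compression), so the most compressed cells fall in the lowest decile of
effective pressure.  Shear stress is half the principal-stress difference,
``(lambda_max - lambda_min) / 2 >= 0``.

Enrichment statistics
---------------------
Cells are grouped as MCC, MCC-adjacent (sharing an edge with an MCC) or
non-adjacent, with peripheral cells excluded outright.  Within each replicate
the decile cut is the pooled 90th (or 10th) percentile over adjacent and
non-adjacent cells together; the per-group fractions beyond the cut are then
compared across replicates with a two-sided paired t-test (n = replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import Mesh, adjacency_graph, peripheral_cells
from .mechanics import MechParams, cell_pressure, cell_tension

__all__ = [
    "cell_stress_tensor",
    "shear_stress",
    "effective_pressure",
    "classify_cells",
    "decile_fraction",
    "paired_ttest",
    "enrichment_report",
    "neighbor_ring_geometry",
    "stress_table",
]

GROUPS = ("mcc", "mcc_adjacent", "non_adjacent", "peripheral")
#: metric name -> (per-cell quantity, decile tail) as plotted by the enrichment report
METRICS = {
    "effective_pressure": "lowest",   # most compressed
    "tension": "lowest",              # lowest cortical tension
    "shear": "highest",               # most anisotropically loaded
}


def cell_stress_tensor(mesh: Mesh, params: MechParams,
                       check_equilibrium: bool = False) -> np.ndarray:
    """(N, 2, 2) symmetric per-cell stress tensors.

    Meaningful on an equilibrated mesh; pass ``check_equilibrium=True`` to get
    a warning (not an error) when residual forces are large.
    """
    if check_equilibrium:
        from .mechanics import vertex_forces

        f = vertex_forces(mesh, params)
        fmax = float(np.max(np.hypot(f[:, 0], f[:, 1])))
        if fmax > 100 * params.force_tol:
            warnings.warn(
                f"mesh not equilibrated (max |F| = {fmax:.3g}); stress tensors are approximate",
                stacklevel=2,
            )
    areas = mesh.areas()
    p = cell_pressure(mesh, params, areas)
    t = cell_tension(mesh, params)
    out = np.zeros((mesh.n_cells, 2, 2))
    iso = -(p - params.p_ext)
    out[:, 0, 0] = iso
    out[:, 1, 1] = iso
    lp = mesh.loops
    seg = mesh.vertices[lp.nxt] - mesh.vertices[lp.vert]
    ln = np.hypot(seg[:, 0], seg[:, 1])
    w = t[lp.cell_of] / (areas[lp.cell_of] * ln)
    nc = mesh.n_cells
    out[:, 0, 0] += np.bincount(lp.cell_of, weights=w * seg[:, 0] * seg[:, 0], minlength=nc)
    out[:, 1, 1] += np.bincount(lp.cell_of, weights=w * seg[:, 1] * seg[:, 1], minlength=nc)
    xy = np.bincount(lp.cell_of, weights=w * seg[:, 0] * seg[:, 1], minlength=nc)
    out[:, 0, 1] += xy
    out[:, 1, 0] += xy
    return out


def shear_stress(tensor: np.ndarray) -> np.ndarray:
    """Half the principal-stress difference, (lambda_max - lambda_min)/2 >= 0.

    Accepts a single 2x2 symmetric tensor or an (N, 2, 2) stack.
    """
    t = np.asarray(tensor, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    if not np.allclose(t[:, 0, 1], t[:, 1, 0], rtol=0, atol=1e-9 * (1 + np.abs(t).max())):
        raise ValueError("stress tensor must be symmetric")
    # for a symmetric 2x2, (lmax - lmin)/2 = sqrt(((a - d)/2)^2 + b^2)
    s = np.sqrt(0.25 * (t[:, 0, 0] - t[:, 1, 1]) ** 2 + t[:, 0, 1] ** 2)
    return float(s[0]) if single else s


def effective_pressure(mesh: Mesh, params: MechParams) -> np.ndarray:
    """Isotropic pressure part of the cell stress, -(p_i - P_ext); negative = compressed."""
    return -(cell_pressure(mesh, params) - params.p_ext)


def classify_cells(mesh: Mesh) -> np.ndarray:
    """Per-cell group label: peripheral > mcc > mcc_adjacent > non_adjacent.

    Peripheral cells are excluded from all comparisons regardless of their
    adjacency to MCCs.
    """
    labels = np.full(mesh.n_cells, "non_adjacent", dtype=object)
    mcc_ids = {i for i, c in enumerate(mesh.cells) if c.is_mcc}
    if not mcc_ids:
        warnings.warn("mesh has no MCCs: all bulk cells labelled non_adjacent", stacklevel=2)
    graph = adjacency_graph(mesh)
    adjacent = {n for m in mcc_ids for n in graph.neighbors(m)} - mcc_ids
    labels[list(adjacent)] = "mcc_adjacent"
    labels[list(mcc_ids)] = "mcc"
    labels[list(peripheral_cells(mesh))] = "peripheral"
    return labels


def decile_fraction(values: np.ndarray, labels: np.ndarray, tail: str) -> dict[str, float]:
    """Percentage of each comparison group beyond the pooled decile cut.

    Only ``mcc_adjacent`` and ``non_adjacent`` cells enter the pool; the cut
    is the pooled empirical 90th percentile (``tail='highest'``) or 10th
    percentile (``tail='lowest'``), linear interpolation between order
    statistics.  Membership is strict (values equal to the cut are not beyond
    it).  Returns percentages per group.
    """
    if tail not in ("highest", "lowest"):
        raise ValueError("tail must be 'highest' or 'lowest'")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    mask = (labels == "mcc_adjacent") | (labels == "non_adjacent")
    pooled = values[mask]
    if pooled.size < 10:
        raise ValueError(f"need >= 10 included cells to define a decile, got {pooled.size}")
    if tail == "highest":
        cut = float(np.percentile(pooled, 90))
        beyond = values > cut
    else:
        cut = float(np.percentile(pooled, 10))
        beyond = values < cut
    out = {}
    for grp in ("mcc_adjacent", "non_adjacent"):
        g = labels == grp
        out[grp] = 100.0 * float(np.count_nonzero(beyond & g)) / max(1, np.count_nonzero(g))
    return out


@dataclass
class PairedTTest:
    t: float
    p: float
    n: int
    mean_diff: float
    flag: str | None = None


def paired_ttest(pairs: np.ndarray) -> PairedTTest:
    """Classical two-sided paired t-test on (adjacent, non-adjacent) pairs.

    ``pairs`` is (n, 2); the test is on the per-replicate differences
    ``pairs[:, 0] - pairs[:, 1]``.  Degenerate inputs are handled explicitly:
    all-identical pairs give t = 0, p = 1; zero variance with a nonzero mean
    difference is reported as the p -> 0 limit with a flag.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) array of replicate pairs")
    d = pairs[:, 0] - pairs[:, 1]
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTTest(t=0.0, p=1.0, n=n, mean_diff=0.0)
        return PairedTTest(t=np.inf if mean > 0 else -np.inf, p=0.0, n=n,
                           mean_diff=mean, flag="zero variance of differences")
    tstat = mean / (sd / np.sqrt(n))
    from scipy.stats import t as t_dist

    p = 2.0 * float(t_dist.sf(abs(tstat), df=n - 1))
    return PairedTTest(t=float(tstat), p=p, n=n, mean_diff=mean)


def stress_table(result, params: MechParams | None = None) -> pd.DataFrame:
    """Per-cell stress record table for one :class:`~epimech.protocol.SimResult`."""
    mesh = result.final_mesh
    params = params if params is not None else result.config.mech
    tensors = cell_stress_tensor(mesh, params)
    return pd.DataFrame(
        {
            "cell": np.arange(mesh.n_cells),
            "group": classify_cells(mesh),
            "effective_pressure": effective_pressure(mesh, params),
            "tension": cell_tension(mesh, params),
            "shear": shear_stress(tensors),
        }
    )


def enrichment_report(ensemble, params: MechParams | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decile-enrichment fractions per metric/group/replicate, plus paired t-tests.

    Returns ``(fractions, tests)``: ``fractions`` has one row per
    (replicate, metric, group) with the percentage of that group beyond the
    pooled decile cut of its replicate; ``tests`` has one row per metric with
    the across-replicate paired two-sided t-test.
    """
    rows = []
    for res in ensemble:
        if getattr(res, "final_mesh", None) is None:
            continue
        tab = stress_table(res, params)
        for metric, tail in METRICS.items():
            frac = decile_fraction(tab[metric].to_numpy(), tab["group"].to_numpy(), tail)
            for grp, f in frac.items():
                rows.append(
                    {"replicate": res.seed, "metric": metric, "tail": tail,
                     "group": grp, "fraction_pct": f}
                )
    fractions = pd.DataFrame(rows)
    tests = []
    for metric in METRICS:
        sub = fractions[fractions.metric == metric]
        piv = sub.pivot(index="replicate", columns="group", values="fraction_pct")
        tt = paired_ttest(piv[["mcc_adjacent", "non_adjacent"]].to_numpy())
        tests.append(
            {"metric": metric, "tail": METRICS[metric],
             "mean_adjacent": float(piv["mcc_adjacent"].mean()),
             "mean_non_adjacent": float(piv["non_adjacent"].mean()),
             "t": tt.t, "p": tt.p, "n": tt.n}
        )
    return fractions, pd.DataFrame(tests)


def _polygon_long_axis_angle(poly: np.ndarray) -> float:
    """Orientation (radians) of the polygon's long axis via second area moments."""
    from .mechanics import _long_axis

    v = _long_axis(poly)
    return float(np.arctan2(v[1], v[0]))


def neighbor_ring_geometry(mesh: Mesh, mcc_id: int) -> pd.DataFrame:
    """Rosette geometry around one MCC.

    Neighbours are ordered by angle about the MCC centroid.  The elongation
    index of a neighbour is ``cos(2*theta)`` with ``theta`` the angle between
    the neighbour's long axis and the local tangent direction (perpendicular
    to the spoke from the MCC centroid): +1 means tangentially stretched
    (rosette-like), -1 radially stretched, ~0 isotropic.
    """
    if not mesh.cells[mcc_id].is_mcc:
        raise ValueError(f"cell {mcc_id} is not an MCC")
    graph = adjacency_graph(mesh)
    center = mesh.centroids()[mcc_id]
    rows = []
    for nb in graph.neighbors(mcc_id):
        c = mesh.centroids()[nb]
        spoke = c - center
        phi = float(np.arctan2(spoke[1], spoke[0]))
        tangent = phi + np.pi / 2.0
        axis = _polygon_long_axis_angle(mesh.cell_polygon(nb))
        theta = axis - tangent
        rows.append({"neighbor": nb, "angle": phi, "elongation_index": float(np.cos(2 * theta))})
    df = pd.DataFrame(rows).sort_values("angle").reset_index(drop=True)
    return df
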