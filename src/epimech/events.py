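"""Quantification of macropinocytosis events on cell/junction tracks.

All estimators operate on an event table (one row per macropinocytotic
event: host cell, onset, duration, peak ruffle area, location and adjacency
class) and a :class:`~epimech.synth.CellTracks` object (per-cell apical-area
and per-junction length time series at a uniform frame interval).  They are
invariant to time-origin shifts and to consistent unit rescaling.

The event's "end" is onset + duration rounded to the nearest frame; the
area-change window for the per-event loss runs from the onset frame to the
end frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "synchronize_area_traces",
    "area_reduction_and_correlation",
    "junction_length_change",
    "event_rate_by_adjacency",
    "fold_change_log2",
    "remodeling_index",
    "extrusion_neighbor_rate",
    "ruffle_summary",
]

log = logging.getLogger(__name__)


def _frame_index(tracks, t: float) -> int:
    times = tracks.times
    return int(np.clip(round((t - times[0]) / tracks.frame_interval), 0, len(times) - 1))


def synchronize_area_traces(
    tracks,
    events: pd.DataFrame,
    window: tuple[float, float] = (5.0, 15.0),
) -> pd.DataFrame:
    """Event-synchronised, onset-normalised mean apical-area traces.

    Each event cell's trace is divided by its area at event onset and aligned
    at the onset; control cells (cells with no event) are aligned at times
    matched to the event-onset distribution (cycled deterministically).
    Returns one row per time offset with mean/SD/n for both groups.  Cells
    whose track does not cover the window are dropped with a log entry.
    """
    pre, post = window
    dt = tracks.frame_interval
    offsets = np.round(np.arange(-pre, post + 1e-9, dt), 9)
    arr = tracks.areas.to_numpy()
    times = tracks.times

    def collect(cells_and_times) -> np.ndarray:
        rows = []
        for ci, t0 in cells_and_times:
            k0 = _frame_index(tracks, t0)
            lo = k0 - int(round(pre / dt))
            hi = k0 + int(round(post / dt))
            if lo < 0 or hi >= len(times):
                log.info("cell %s dropped: track does not cover the window", ci)
                continue
            ref = arr[k0, ci]
            if ref <= 0:
                continue
            rows.append(arr[lo:hi + 1, ci] / ref)
        return np.asarray(rows)

    ev_pairs = [(int(r.cell), float(r.onset)) for r in events.itertuples()]
    event_cells = {c for c, _ in ev_pairs}
    controls = [c for c in tracks.areas.columns if c not in event_cells]
    onset_times = [t for _, t in ev_pairs] or [times[len(times) // 2]]
    ctrl_pairs = [(int(c), onset_times[i % len(onset_times)])
                  for i, c in enumerate(controls)]

    ev = collect(ev_pairs)
    ct = collect(ctrl_pairs)
    out = {"offset": offsets}
    for name, block in (("event", ev), ("control", ct)):
        if block.size:
            out[f"mean_{name}"] = block.mean(axis=0)
            out[f"sd_{name}"] = block.std(axis=0, ddof=1) if len(block) > 1 else np.zeros(len(offsets))
            out[f"n_{name}"] = len(block)
        else:
            out[f"mean_{name}"] = np.full(len(offsets), np.nan)
            out[f"sd_{name}"] = np.full(len(offsets), np.nan)
            out[f"n_{name}"] = 0
    return pd.DataFrame(out)


@dataclass
class CorrelationResult:
    delta: np.ndarray          # per-event fractional area reduction
    peak_area: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def area_reduction_and_correlation(tracks, events: pd.DataFrame) -> CorrelationResult:
    """Per-event apical-area loss and its correlation with ruffle size.

    ``delta = (area at onset - area at event end) / area at onset`` regressed
    on peak ruffle area by ordinary least squares; ``r_squared`` is the
    squared Pearson correlation.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 events")
    arr = tracks.areas.to_numpy()
    # an event whose window overlaps another event of the same cell cannot be
    # attributed a clean area change; drop it (as single-event tracking would)
    keep = []
    for r in events.itertuples():
        same = events[(events.cell == r.cell) & (events.event != r.event)]
        clean = True
        for o in same.itertuples():
            if r.onset < o.onset + o.duration and o.onset < r.onset + r.duration:
                clean = False
                break
        keep.append(clean)
        if not clean:
            log.info("event %s dropped: overlapping event on cell %s", r.event, r.cell)
    events = events[np.asarray(keep)]
    if len(events) < 3:
        raise ValueError("fewer than 3 non-overlapping events")
    deltas, peaks = [], []
    for r in events.itertuples():
        k0 = _frame_index(tracks, float(r.onset))
        k1 = _frame_index(tracks, float(r.onset) + float(r.duration))
        a0, a1 = arr[k0, int(r.cell)], arr[k1, int(r.cell)]
        deltas.append((a0 - a1) / a0)
        peaks.append(float(r.peak_area))
    deltas = np.asarray(deltas)
    peaks = np.asarray(peaks)
    if np.std(peaks) == 0:
        raise ValueError("zero variance in ruffle peak area")
    fit = stats.linregress(peaks, deltas)
    return CorrelationResult(
        delta=deltas, peak_area=peaks, slope=float(fit.slope),
        intercept=float(fit.intercept), r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue), n=len(deltas),
    )


def junction_length_change(tracks, events: pd.DataFrame) -> dict:
    """Percent junction-length change, event junctions vs matched controls.

    For each junctional event the change is measured from onset to event end
    on the event's junction; control junctions (never hosting an event) are
    measured over the same windows, cycled deterministically.  Groups are
    compared with a two-sided unpaired t-test.
    """
    if tracks.junction_lengths is None:
        raise ValueError("tracks carry no junction lengths")
    jarr = tracks.junction_lengths
    ev = events[(events.get("junction", -1) >= 0)] if "junction" in events else events.iloc[0:0]
    windows = []
    event_pct = []
    event_jids = set()
    for r in ev.itertuples():
        jid = int(r.junction)
        event_jids.add(jid)
        k0 = _frame_index(tracks, float(r.onset))
        k1 = _frame_index(tracks, float(r.onset) + float(r.duration))
        col = jarr[jid].to_numpy()
        if not np.all(np.isfinite(col[[k0, k1]])):
            log.info("junction %d dropped: missing frames", jid)
            continue
        windows.append((k0, k1))
        event_pct.append(100.0 * (col[k1] - col[k0]) / col[k0])
    ctrl_pct = []
    controls = [j for j in jarr.columns if j not in event_jids]
    for i, jid in enumerate(controls):
        if not windows:
            break
        k0, k1 = windows[i % len(windows)]
        col = jarr[jid].to_numpy()
        ctrl_pct.append(100.0 * (col[k1] - col[k0]) / col[k0])
    event_pct = np.asarray(event_pct)
    ctrl_pct = np.asarray(ctrl_pct)
    if event_pct.size and ctrl_pct.size:
        if np.ptp(event_pct) == 0 and np.ptp(ctrl_pct) == 0 \
                and np.mean(event_pct) == np.mean(ctrl_pct):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(event_pct, ctrl_pct)
    else:
        t, p = np.nan, np.nan
    return {
        "event_pct": event_pct,
        "control_pct": ctrl_pct,
        "mean_event_pct": float(np.mean(event_pct)) if event_pct.size else np.nan,
        "mean_control_pct": float(np.mean(ctrl_pct)) if ctrl_pct.size else np.nan,
        "t": float(t),
        "p": float(p),
    }


def event_rate_by_adjacency(
    events: pd.DataFrame,
    census: dict[str, int],
    duration_min: float,
) -> dict[str, float]:
    """Events per cell per hour for MCC-adjacent vs non-adjacent host cells.

    ``census`` maps adjacency class to the number of cells of that class in
    the field; classes with zero cells get NaN.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    hours = duration_min / 60.0
    out = {}
    for cls in ("mcc_adjacent", "non_adjacent"):
        n = census.get(cls, 0)
        count = int(np.sum(events["adjacency"] == cls)) if len(events) else 0
        out[cls] = count / (n * hours) if n > 0 else np.nan
    return out


def fold_change_log2(count_before: float, count_after: float) -> float:
    """log2(after / before).  A zero basal count is an error (no pseudocount)."""
    if count_before <= 0:
        raise ValueError("basal (before) count must be positive; record a basal window")
    if count_after < 0:
        raise ValueError("counts must be non-negative")
    return float(np.log2(count_after / count_before))


def remodeling_index(
    tracks,
    bin_width: float = 2.0,
    events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tissue remodeling over time: mean |area change| / area, per time bin (%).

    Within each bin of width ``bin_width`` (min) the index is the mean over
    cells of the absolute apical-area change across the bin divided by the
    area at the bin start.  Purely area-based, hence insensitive to rigid
    motion.  If ``events`` is given, event counts per bin are reported
    alongside.  Bins with fewer than 2 frames yield NaN.
    """
    times = tracks.times
    arr = tracks.areas.to_numpy()
    edges = np.arange(times[0], times[-1] + bin_width, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = np.flatnonzero((times >= lo) & (times <= hi + 1e-9))
        if in_bin.size < 2:
            idx = np.nan
        else:
            a0, a1 = arr[in_bin[0]], arr[in_bin[-1]]
            ok = a0 > 0
            idx = 100.0 * float(np.mean(np.abs(a1[ok] - a0[ok]) / a0[ok]))
        row = {"bin_start": lo, "bin_end": hi, "remodeling_pct": idx}
        if events is not None:
            # events *active* during the bin (ongoing ramp), not merely onsets
            active = (events.onset < hi) & (events.onset + events.duration > lo)
            row["n_events"] = int(np.sum(active))
        rows.append(row)
    return pd.DataFrame(rows)


def extrusion_neighbor_rate(
    events: pd.DataFrame,
    tissue,
    extrusions: pd.DataFrame,
    window_min: float = 10.0,
    annulus_factor: float = 2.0,
) -> dict:
    """Post-extrusion event rates: direct neighbours vs a control annulus.

    For each extrusion, events with onset within ``window_min`` after the
    extrusion are counted among (a) the extruded cell's direct former
    neighbours and (b) cells whose centroids lie within ``annulus_factor``
    times the mean neighbour-centroid distance, excluding the direct
    neighbours and the extruded cell.  Pooled per-cell rates and their ratio
    are returned; no extrusions give an empty result.
    """
    if extrusions is None or len(extrusions) == 0:
        return {"neighbor_rate": np.nan, "annulus_rate": np.nan,
                "ratio": np.nan, "n_extrusions": 0}
    nb_events = nb_cells = an_events = an_cells = 0
    for r in extrusions.itertuples():
        c, t0 = int(r.cell), float(r.time)
        nbrs = set(int(x) for x in tissue.adjacency.neighbors(c))
        if not nbrs:
            continue
        center = tissue.centroids[c]
        dists = np.hypot(*(tissue.centroids[sorted(nbrs)] - center).T)
        radius = annulus_factor * float(np.mean(dists))
        all_d = np.hypot(*(tissue.centroids - center).T)
        annulus = set(np.flatnonzero(all_d <= radius).tolist()) - nbrs - {c}
        in_window = events[(events.onset > t0) & (events.onset <= t0 + window_min)]
        nb_events += int(in_window.cell.isin(nbrs).sum())
        an_events += int(in_window.cell.isin(annulus).sum())
        nb_cells += len(nbrs)
        an_cells += len(annulus)
    nb_rate = nb_events / nb_cells if nb_cells else np.nan
    an_rate = an_events / an_cells if an_cells else np.nan
    return {
        "neighbor_rate": nb_rate,
        "annulus_rate": an_rate,
        "ratio": nb_rate / an_rate if (an_rate and np.isfinite(an_rate)) else np.nan,
        "n_extrusions": int(len(extrusions)),
    }


def ruffle_summary(events: pd.DataFrame, cell_areas: np.ndarray | dict) -> pd.DataFrame:
    """Distribution summary of ruffle duration, peak area and apical fraction.

    Reports mean +- SD of event duration (min), peak ruffle area (um^2) and
    peak area as % of the host cell's apical area, plus the junctional
    fraction of event locations.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    areas = (np.asarray([cell_areas[c] for c in events.cell])
             if isinstance(cell_areas, dict)
             else np.asarray(cell_areas)[events.cell.to_numpy()])
    pct = 100.0 * events.peak_area.to_numpy() / areas
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    rows = [
        {"quantity": "duration_min", "mean": float(events.duration.mean()),
         "sd": sd(events.duration)},
        {"quantity": "peak_area_um2", "mean": float(events.peak_area.mean()),
         "sd": sd(events.peak_area)},
        {"quantity": "apical_fraction_pct", "mean": float(np.mean(pct)), "sd": sd(pct)},
        {"quantity": "junctional_fraction", "mean":
         float(np.mean(events.location == "junctional")), "sd": np.nan},
    ]
    return pd.DataFrame(rows)
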