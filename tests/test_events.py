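"""Event-table and track estimators: trivial contracts and generator recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epimech.events import (
    area_reduction_and_correlation,
    event_rate_by_adjacency,
    extrusion_neighbor_rate,
    fold_change_log2,
    junction_length_change,
    remodeling_index,
    ruffle_summary,
    synchronize_area_traces,
)
from epimech.synth import CellTracks, EventGenParams, gen_events, gen_tissue


def _flat_tracks(n_cells=6, n_frames=81, dt=0.5, area=400.0):
    times = np.arange(n_frames) * dt
    areas = pd.DataFrame(np.full((n_frames, n_cells), area), index=times,
                         columns=range(n_cells))
    return CellTracks(areas=areas, junction_lengths=None, frame_interval=dt)


def _event_row(cell=0, onset=10.0, duration=8.0, peak=90.0, **kw):
    row = {"event": kw.get("event", 0), "cell": cell, "onset": onset,
           "duration": duration, "peak_area": peak,
           "location": kw.get("location", "junctional"),
           "adjacency": kw.get("adjacency", "non_adjacent")}
    row.update(kw)
    return row


@pytest.fixture(scope="module")
def tissue():
    return gen_tissue(300, seed=0)


@pytest.fixture(scope="module")
def generated(tissue):
    params = EventGenParams()
    table, tracks = gen_events(tissue, params, duration=120.0, seed=0)
    return params, table, tracks


# ------------------------------------------------------------------ synchronised traces
def test_constant_traces_synchronise_to_unity():
    tracks = _flat_tracks()
    events = pd.DataFrame([_event_row(cell=0), _event_row(cell=1, event=1)])
    out = synchronize_area_traces(tracks, events, window=(5.0, 10.0))
    assert np.allclose(out.mean_event, 1.0)
    assert np.allclose(out.sd_event, 0.0)
    assert np.allclose(out.mean_control, 1.0)


def test_post_event_plateau_recovers_ten_percent_loss(generated):
    """Mean normalised area settles near 0.90 after events (10% loss, n=43)."""
    _, table, tracks = generated
    out = synchronize_area_traces(tracks, table.head(43), window=(5.0, 15.0))
    plateau = float(out.mean_event.iloc[-1])
    assert abs(plateau - 0.90) < 0.02
    assert abs(float(out.mean_control.iloc[-1]) - 1.0) < 0.01


def test_short_tracks_are_dropped():
    tracks = _flat_tracks(n_frames=30)
    events = pd.DataFrame([_event_row(onset=1.0)])  # window starts before the track
    out = synchronize_area_traces(tracks, events, window=(5.0, 10.0))
    assert out.n_event.iloc[0] == 0


# ------------------------------------------------------------------ loss/size correlation
def test_perfect_linear_relation_gives_r2_of_one():
    n, dt = 200, 0.5
    times = np.arange(n) * dt
    cells = range(5)
    arr = np.full((n, 5), 400.0)
    rows = []
    for k in range(5):
        peak = 50.0 + 20 * k
        frac = 0.001 * peak
        onset, dur = 20.0, 10.0
        ramp = np.clip((times - onset) / dur, 0, 1)
        arr[:, k] = 400.0 * (1 - frac * ramp)
        rows.append(_event_row(cell=k, event=k, onset=onset, duration=dur, peak=peak))
    tracks = CellTracks(pd.DataFrame(arr, index=times, columns=cells), None, dt)
    res = area_reduction_and_correlation(tracks, pd.DataFrame(rows))
    assert res.r_squared == pytest.approx(1.0, abs=1e-9)
    assert res.slope == pytest.approx(0.001, rel=1e-6)


def test_generator_r2_recovery_at_paper_n(tissue):
    """At n = 43 events the calibrated generator lands near r^2 = 0.4."""
    r2s = []
    for seed in range(5):
        table, tracks = gen_events(tissue, EventGenParams(), 120.0, seed)
        res = area_reduction_and_correlation(tracks, table.head(43))
        r2s.append(res.r_squared)
    assert abs(float(np.mean(r2s)) - 0.4) < 0.12


def test_shuffled_pairing_destroys_correlation(generated):
    _, table, tracks = generated
    shuffled = table.copy()
    rng = np.random.default_rng(1)
    shuffled["peak_area"] = rng.permutation(shuffled["peak_area"].to_numpy())
    res = area_reduction_and_correlation(tracks, shuffled)
    assert res.r_squared < 0.1


def test_zero_variance_peak_area_rejected():
    tracks = _flat_tracks()
    events = pd.DataFrame([_event_row(cell=c, event=c, peak=90.0) for c in range(3)])
    with pytest.raises(ValueError):
        area_reduction_and_correlation(tracks, events)


# ------------------------------------------------------------------ junction shortening
def test_constant_junctions_show_no_change():
    dt = 0.5
    times = np.arange(100) * dt
    areas = pd.DataFrame(np.full((100, 3), 400.0), index=times, columns=range(3))
    jl = pd.DataFrame(np.full((100, 4), 20.0), index=times, columns=range(4))
    tracks = CellTracks(areas, jl, dt)
    events = pd.DataFrame([_event_row(junction=0), _event_row(event=1, junction=1)])
    out = junction_length_change(tracks, events)
    assert out["mean_event_pct"] == 0.0 and out["mean_control_pct"] == 0.0
    assert out["p"] == 1.0


def test_generator_junction_shortening_recovered(generated):
    _, table, tracks = generated
    ev = table[table.junction >= 0].head(40)
    out = junction_length_change(tracks, ev)
    assert abs(-out["mean_event_pct"] - 10.0) < 1.0
    assert out["p"] < 1e-6


def test_unpaired_ttest_matches_closed_form():
    dt = 0.5
    times = np.arange(200) * dt
    areas = pd.DataFrame(np.full((200, 8), 400.0), index=times, columns=range(8))
    data = np.full((200, 8), 20.0)
    # four event junctions shrink by distinct amounts; four controls stay flat
    onset, dur = 20.0, 10.0
    ramp = np.clip((times - onset) / dur, 0, 1)
    drops = [0.08, 0.10, 0.12, 0.09]
    for j, d in enumerate(drops):
        data[:, j] = 20.0 * (1 - d * ramp)
    jl = pd.DataFrame(data, index=times, columns=range(8))
    tracks = CellTracks(areas, jl, dt)
    events = pd.DataFrame([_event_row(event=j, cell=j, onset=onset, duration=dur,
                                      junction=j) for j in range(4)])
    out = junction_length_change(tracks, events)
    a = -100 * np.asarray(drops)
    b = np.zeros(4)
    t_hand, p_hand = sps.ttest_ind(a, b)
    assert out["t"] == pytest.approx(t_hand)
    assert out["p"] == pytest.approx(p_hand)


# ------------------------------------------------------------------ rates & fold change
def test_event_rate_arithmetic():
    events = pd.DataFrame([_event_row(event=k, adjacency="mcc_adjacent") for k in range(10)])
    rates = event_rate_by_adjacency(events, {"mcc_adjacent": 20, "non_adjacent": 0}, 60.0)
    assert rates["mcc_adjacent"] == pytest.approx(0.5)
    assert np.isnan(rates["non_adjacent"])
    half = event_rate_by_adjacency(events, {"mcc_adjacent": 20, "non_adjacent": 0}, 120.0)
    assert half["mcc_adjacent"] == pytest.approx(0.25)


def test_generator_adjacency_bias_recovered():
    """The 2x MCC-adjacent rate multiplier is recovered at n >= 191 events."""
    params = EventGenParams(rate_per_cell_hour=0.3)
    counts = {"mcc_adjacent": 0.0, "non_adjacent": 0.0}
    census = {"mcc_adjacent": 0, "non_adjacent": 0}
    total = 0
    seed = 0
    while total < 191:
        tissue = gen_tissue(250, seed=seed, label_mccs=True)
        table, _ = gen_events(tissue, params, 120.0, seed)
        rates = event_rate_by_adjacency(
            table,
            {"mcc_adjacent": int(tissue.mcc_adjacent.sum()),
             "non_adjacent": int((~tissue.is_mcc & ~tissue.mcc_adjacent).sum())},
            120.0,
        )
        for cls in counts:
            counts[cls] += np.sum(table.adjacency == cls)
            census[cls] += (int(tissue.mcc_adjacent.sum()) if cls == "mcc_adjacent"
                            else int((~tissue.is_mcc & ~tissue.mcc_adjacent).sum()))
        total += len(table)
        seed += 1
    ratio = (counts["mcc_adjacent"] / census["mcc_adjacent"]) / (
        counts["non_adjacent"] / census["non_adjacent"])
    assert abs(ratio - 2.0) < 0.6  # binomial error at ~200 events


@pytest.mark.parametrize("before,after,expected", [(5, 5, 0.0), (3, 12, 2.0)])
def test_fold_change_closed_form(before, after, expected):
    assert fold_change_log2(before, after) == pytest.approx(expected)


def test_fold_change_zero_basal_is_error():
    with pytest.raises(ValueError):
        fold_change_log2(0, 4)


def test_fold_change_unbiased_on_poisson_counts(rng):
    """Mean recovered log2 fold change ~ log2(3) for a true 3x increase."""
    lam = 30.0
    vals = []
    for _ in range(20):
        b = rng.poisson(lam)
        a = rng.poisson(3 * lam)
        if b > 0:
            vals.append(fold_change_log2(b, a))
    assert abs(np.mean(vals) - np.log2(3)) < 0.1


# ------------------------------------------------------------------ remodeling
def test_static_tissue_has_zero_remodeling():
    tracks = _flat_tracks()
    tracks.areas.iloc[:, :] = 400.0
    out = remodeling_index(tracks)
    assert np.allclose(out.remodeling_pct.dropna(), 0.0)


def test_remodeling_is_motion_insensitive():
    # area-based: any per-frame motion that keeps areas fixed contributes nothing
    tracks = _flat_tracks()
    out = remodeling_index(tracks)
    assert np.allclose(out.remodeling_pct.dropna(), 0.0)


# ------------------------------------------------------------------ extrusion rates
def test_uniform_event_field_gives_unit_ratio(tissue):
    rng = np.random.default_rng(0)
    rows = [_event_row(event=k, cell=int(rng.integers(tissue.n_cells)),
                       onset=float(rng.uniform(0, 30))) for k in range(4000)]
    events = pd.DataFrame(rows)
    extr = pd.DataFrame({"cell": [10, 50, 90], "time": [5.0, 6.0, 7.0]})
    out = extrusion_neighbor_rate(events, tissue, extr)
    assert abs(out["ratio"] - 1.0) < 0.25


def test_events_outside_window_never_counted(tissue):
    events = pd.DataFrame([_event_row(event=0, cell=c, onset=30.0)
                           for c in tissue.adjacency.neighbors(10)])
    extr = pd.DataFrame({"cell": [10], "time": [5.0]})
    out = extrusion_neighbor_rate(events, tissue, extr, window_min=10.0)
    assert out["neighbor_rate"] == 0.0


def test_no_extrusions_empty_result(tissue):
    out = extrusion_neighbor_rate(pd.DataFrame(), tissue, pd.DataFrame())
    assert out["n_extrusions"] == 0 and np.isnan(out["ratio"])


# ------------------------------------------------------------------ ruffle summary
def test_ruffle_summary_constructed_row():
    events = pd.DataFrame([_event_row(cell=0, duration=9.3, peak=94.0)])
    out = ruffle_summary(events, {0: 412.0})
    pct = out[out.quantity == "apical_fraction_pct"]["mean"].iloc[0]
    assert pct == pytest.approx(100 * 94 / 412)  # = 22.8%
    assert np.allclose(out[out.quantity != "junctional_fraction"]["sd"].to_numpy(),
                       [0.0, 0.0, 0.0])


def test_generator_ruffle_statistics_at_paper_n(tissue):
    """Duration mean lands within 0.5 min of 9.3 at n = 90 ruffles."""
    params = EventGenParams()
    table, _ = gen_events(tissue, params, 180.0, seed=3)
    sub = table.head(90)
    out = ruffle_summary(sub, tissue.areas)
    dur = out[out.quantity == "duration_min"].iloc[0]
    assert abs(dur["mean"] - 9.3) < 0.5
    area = out[out.quantity == "peak_area_um2"].iloc[0]
    assert abs(area["mean"] - 94.0) < 3 * 36 / np.sqrt(90)
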