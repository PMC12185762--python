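"""Constitutive law, force-energy consistency, relaxation and mesh surgery."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from epimech.mechanics import (
    MechParams,
    advance,
    cell_pressure,
    cell_tension,
    collapse_boundary_edge,
    divide_cell,
    grow_to,
    relax,
    t1_transition,
    total_energy,
    vertex_forces,
)
from epimech.mesh import (
    CellState,
    Mesh,
    adjacency_graph,
    build_hex_monolayer,
    validate_topology,
)


def _scaled_patch(factor, rings=1):
    """Hex patch with all vertices scaled about the origin by sqrt(factor) in area."""
    mesh = build_hex_monolayer(rings)
    mesh.vertices *= np.sqrt(factor)
    return mesh


# ------------------------------------------------------------------ pressure/tension
def test_pressure_zero_at_preferred_area(params):
    mesh = build_hex_monolayer(1)
    assert np.allclose(cell_pressure(mesh, params), 0.0, atol=1e-12)


@pytest.mark.parametrize("sigma,expected", [(1.0, -1.0), (10.0, -10.0)])
def test_pressure_log_law_and_sigma_scaling(params, sigma, expected):
    """A cell at area e*A0 has p = -sigma: the prefactor multiplies the pressure."""
    mesh = _scaled_patch(np.e)
    for c in mesh.cells:
        c.stiffness = sigma
    mesh.invalidate()
    assert np.allclose(cell_pressure(mesh, params), expected, atol=1e-9)


def test_tension_log_law_and_sigma_scaling(params):
    mesh = build_hex_monolayer(1)
    s = np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))
    scale = np.e * params.l0 / (6 * s)  # perimeter becomes e*L0
    mesh.vertices *= scale
    assert np.allclose(cell_tension(mesh, params), params.gamma, atol=1e-12)
    for c in mesh.cells:
        c.stiffness = 10.0
    mesh.invalidate()
    assert np.allclose(cell_tension(mesh, params), 10 * params.gamma, atol=1e-12)


def test_nonpositive_geometry_raises(params):
    mesh = build_hex_monolayer(0)
    mesh.vertices[:] = 0.0
    with pytest.raises(ValueError):
        cell_pressure(mesh, params)


# ------------------------------------------------------------------ energy & forces
def test_energy_zero_at_preferred_state():
    params = MechParams(p_ext=0.0)
    s = np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))
    params = params.replace(l0=6 * s)  # preferred perimeter = actual hexagon perimeter
    mesh = build_hex_monolayer(1)
    assert abs(total_energy(mesh, params)) < 1e-12


def test_energy_terms_nonnegative_without_external_pressure(params, rng):
    p0 = params.replace(p_ext=0.0)
    mesh = build_hex_monolayer(2, rng=rng)
    mesh.vertices += rng.normal(0, 0.05, mesh.vertices.shape)
    assert total_energy(mesh, p0) >= 0.0


def test_energy_invariant_under_rigid_motion(params, hex4):
    e0 = total_energy(hex4, params)
    th = 1.1
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    hex4.vertices = hex4.vertices @ rot.T + 5.0
    assert abs(total_energy(hex4, params) - e0) < 1e-10


def _finite_diff_check(mesh, params, n_vertices=12, h=1e-6, rng=None):
    rng = rng or np.random.default_rng(1)
    f = vertex_forces(mesh, params)
    worst = 0.0
    for v in rng.choice(mesh.n_vertices, min(n_vertices, mesh.n_vertices), replace=False):
        for d in range(2):
            x0 = mesh.vertices[v, d]
            mesh.vertices[v, d] = x0 + h
            ep = total_energy(mesh, params)
            mesh.vertices[v, d] = x0 - h
            em = total_energy(mesh, params)
            mesh.vertices[v, d] = x0
            fd = -(ep - em) / (2 * h)
            worst = max(worst, abs(fd - f[v, d]) / max(1.0, abs(f[v, d])))
    return worst


def test_forces_match_energy_gradient(params, rng):
    """F = -grad E by central finite differences, relative error < 1e-5."""
    mesh = build_hex_monolayer(2, rng=rng)
    mesh.vertices += rng.normal(0, 0.03, mesh.vertices.shape)
    mesh.cells[3].stiffness = 10.0  # heterogeneous sigma exercises both terms
    mesh.invalidate()
    assert _finite_diff_check(mesh, params, rng=rng) < 1e-5


def test_internal_forces_cancel_without_external_load(rng):
    params = MechParams(p_ext=0.0)
    mesh = build_hex_monolayer(2, rng=rng)
    mesh.vertices += rng.normal(0, 0.02, mesh.vertices.shape)
    f = vertex_forces(mesh, params)
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)


def test_sigma_scales_single_cell_force_contribution(params):
    """Multiplying one cell's sigma by k multiplies its force contribution by k."""
    mesh = build_hex_monolayer(0)
    mesh.vertices *= 1.17  # off-equilibrium so forces are nonzero
    p0 = params.replace(p_ext=0.0)
    f1 = vertex_forces(mesh, p0)
    mesh.cells[0].stiffness = 7.0
    mesh.invalidate()
    f7 = vertex_forces(mesh, p0)
    assert np.allclose(f7, 7.0 * f1, rtol=1e-12)


# ------------------------------------------------------------------ relaxation
def test_relax_noop_on_equilibrated_mesh(params):
    mesh = build_hex_monolayer(1)
    relax(mesh, params)
    v0 = mesh.vertices.copy()
    res = relax(mesh, params)
    assert res.steps <= 1 and res.converged
    assert np.allclose(mesh.vertices, v0, atol=1e-12)


def test_single_hexagon_relaxes_to_1d_oracle_minimum():
    """A lone cell relaxes to the regular-hexagon scale minimising the energy."""
    params = MechParams(p_ext=0.3, force_tol=1e-10)
    mesh = build_hex_monolayer(0)
    res = relax(mesh, params)
    assert res.converged
    area = mesh.areas()[0]

    # oracle: 1-D minimisation over the regular-hexagon scale factor
    s0 = np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))
    def energy_of_scale(c):
        a = c**2
        L = 6 * s0 * c
        return (a * np.log(a) - a + 1
                + params.gamma * (L * np.log(L / params.l0) - L + params.l0)
                + params.p_ext * a)
    opt = minimize_scalar(energy_of_scale, bounds=(0.3, 1.5), method="bounded",
                          options={"xatol": 1e-12})
    assert abs(area - opt.x**2) < 1e-6


def test_relax_energy_nonincreasing_and_recovers_after_perturbation(params, rng):
    mesh = build_hex_monolayer(2, rng=rng)
    res0 = relax(mesh, params, force_tol=1e-9)
    e_min = res0.energy
    mesh.vertices *= 1.0 + rng.uniform(-0.01, 0.01, mesh.vertices.shape)
    res = relax(mesh, params, force_tol=1e-9, record_energy=True)
    trace = np.asarray(res.energy_trace)
    assert np.all(np.diff(trace) <= 1e-12 * np.maximum(1.0, np.abs(trace[:-1])))
    assert res.energy <= e_min + 1e-8


def test_relax_flags_nonconvergence(params, hex4):
    res = relax(hex4, params, max_steps=2)
    assert not res.converged  # flagged, not raised


# ------------------------------------------------------------------ division
def test_division_surgery_accounting(params, grown_mesh, rng):
    mesh = grown_mesh.copy()
    nc, ne, nv = mesh.n_cells, mesh.n_edges, mesh.n_vertices
    d1, d2 = divide_cell(mesh, 10, rng, params)
    assert (mesh.n_cells, mesh.n_edges, mesh.n_vertices) == (nc + 1, ne + 3, nv + 2)
    assert validate_topology(mesh).ok
    assert adjacency_graph(mesh).has_edge(d1, d2)
    assert mesh.cells[d1].age == 0.0 and mesh.cells[d2].age == 0.0


def test_division_conserves_area(params, grown_mesh, rng):
    mesh = grown_mesh.copy()
    parent_area = mesh.areas()[7]
    d1, d2 = divide_cell(mesh, 7, rng, params)
    areas = mesh.areas()
    assert abs(areas[d1] + areas[d2] - parent_area) < 1e-9


def test_rectangle_divides_along_short_axis(params, rng):
    """A 2x1 rectangle is bisected vertically into two unit-area daughters."""
    verts = np.array([[0.0, 0], [2, 0], [2, 1], [0, 1]])
    edges = np.array([(0, 1), (1, 2), (2, 3), (3, 0)])
    mesh = Mesh(verts, edges, [np.arange(4)], [np.ones(4, dtype=int)], [CellState()])
    d1, d2 = divide_cell(mesh, 0, rng, MechParams())
    areas = mesh.areas()
    assert np.allclose(sorted(areas), [1.0, 1.0], atol=1e-9)
    # the two new vertices lie on the vertical bisector x = 1
    assert np.allclose(mesh.vertices[-2:, 0], 1.0, atol=1e-9)


def test_mcc_refuses_to_divide(params, hex4, rng):
    hex4.cells[30].is_mcc = True
    hex4.cells[30].can_divide = False
    with pytest.raises(ValueError):
        divide_cell(hex4, 30, rng, params)


def test_repeated_divisions_preserve_topology(params, rng):
    mesh = build_hex_monolayer(2, rng=rng)
    for k in range(60):
        ci = int(rng.integers(mesh.n_cells))
        divide_cell(mesh, ci, rng, params)
        rep = validate_topology(mesh)
        assert rep.ok, (k, rep.failures)
        relax(mesh, params, max_steps=60, force_tol=1e-3)


# ------------------------------------------------------------------ T1
def _shortest_eligible_edge(mesh):
    lengths = mesh.edge_lengths()
    deg = mesh.vertex_degree()
    ec = mesh.edge_cells()
    for e in np.argsort(lengths):
        u, w = mesh.edges[e]
        if len(ec[e]) == 2 and deg[u] == 3 and deg[w] == 3:
            if all(len(mesh.cell_edges[c]) > 3 for c in ec[e]):
                return int(e)
    raise AssertionError("no eligible edge")


def test_t1_swaps_adjacency_and_preserves_counts(params, grown_mesh):
    mesh = grown_mesh.copy()
    e = _shortest_eligible_edge(mesh)
    cp, cq = mesh.edge_cells()[e]
    counts = (mesh.n_cells, mesh.n_edges, mesh.n_vertices)
    assert t1_transition(mesh, e, params)
    assert (mesh.n_cells, mesh.n_edges, mesh.n_vertices) == counts
    assert validate_topology(mesh).ok
    g = adjacency_graph(mesh)
    assert not g.has_edge(cp, cq)  # former sharers lose adjacency
    new_cells = mesh.edge_cells()[e]
    assert set(new_cells).isdisjoint({cp, cq})
    assert g.has_edge(*new_cells)  # flanking cells gain it
    # post-T1 length contract
    assert np.isclose(mesh.edge_lengths()[e], 1.5 * params.t1_threshold, atol=1e-9)


def test_t1_twice_is_adjacency_involution(params, grown_mesh):
    mesh = grown_mesh.copy()
    e = _shortest_eligible_edge(mesh)
    g0 = set(adjacency_graph(mesh).edges)
    t1_transition(mesh, e, params)
    t1_transition(mesh, e, params)
    assert set(adjacency_graph(mesh).edges) == g0


def test_t1_skips_boundary_edge(params, hex4):
    e = int(hex4.boundary_edges()[0])
    assert not t1_transition(hex4, e, params, strict=False)
    with pytest.raises(ValueError):
        t1_transition(hex4, e, params, strict=True)


def test_boundary_edge_collapse_preserves_topology(params, grown_mesh):
    mesh = grown_mesh.copy()
    ec = mesh.edge_cells()
    e = next(int(e) for e in mesh.boundary_edges()
             if len(mesh.cell_edges[ec[e][0]]) > 3)
    nv, ne, nc = mesh.n_vertices, mesh.n_edges, mesh.n_cells
    assert collapse_boundary_edge(mesh, e)
    assert (mesh.n_vertices, mesh.n_edges, mesh.n_cells) == (nv - 1, ne - 1, nc)
    assert validate_topology(mesh).ok


# ------------------------------------------------------------------ advance
def test_advance_zero_duration_is_noop(params, grown_mesh, rng):
    mesh = grown_mesh.copy()
    relax(mesh, params, force_tol=params.growth_force_tol)
    v0 = mesh.vertices.copy()
    nc = mesh.n_cells
    advance(mesh, params, 0.0, rng)
    assert mesh.n_cells == nc
    assert np.allclose(mesh.vertices, v0, atol=1e-9)


def test_advance_without_division_equals_relax(params, rng):
    m1 = build_hex_monolayer(2, rng=np.random.default_rng(3))
    m2 = m1.copy()
    advance(m1, params, 1.0, rng, divide=False)
    relax(m2, params, max_steps=params.growth_max_steps,
          force_tol=params.growth_force_tol)
    assert np.allclose(m1.vertices, m2.vertices, atol=1e-12)


def test_population_doubling_time_tracks_cycle_time():
    """Over 61 -> 244 cells the doubling time matches the mean cycle time within 10%."""
    params = MechParams()
    rng = np.random.default_rng(5)
    mesh = build_hex_monolayer(4, rng=rng)
    ages0 = [c.age for c in mesh.cells]
    t_total = 0.0
    # grow exactly two doublings, measuring elapsed model time via cell ages
    target = 244
    while mesh.n_cells < target:
        waits = [(c.cycle_time - c.age, i) for i, c in enumerate(mesh.cells)
                 if c.can_divide]
        wait, ci = min(waits)
        wait = max(wait, 0.0)
        for c in mesh.cells:
            c.age += wait
        t_total += wait
        from epimech.mechanics import divide_cell

        divide_cell(mesh, ci, rng, params)
    doubling = t_total / 2.0
    assert abs(doubling - params.cycle_time) / params.cycle_time < 0.10
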