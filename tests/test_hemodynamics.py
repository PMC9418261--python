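"""Unit tests for hemorheology, elemental flow laws, the network solver,
hematocrit phase separation, adaptation and pruning."""

import math

import numpy as np
import pytest

from angiopet.config import FlowParams, SimulationConfig
from angiopet.hemodynamics import (NetworkFlowState, adapt_diameters,
                                   adaptation_stimuli, blood_viscosity,
                                   junction_residuals, mu045,
                                   parent_segment_mask, poiseuille_flow,
                                   prune_network, relative_viscosity, shape_C,
                                   solve_network_pressures, split_hematocrit,
                                   starling_flow, tau_e, wall_shear_stress)
from angiopet.network import VesselNetwork


# --------------------------------------------------------------------------
# hemorheology: independent scalar oracles of the empirical formulas
# --------------------------------------------------------------------------

def _mu045_oracle(d):
    return 3.2 + 6 * math.exp(-0.085 * d) - 2.44 * math.exp(-0.06 * d ** 0.645)


def _shape_C_oracle(d):
    g = 1.0 / (1.0 + 1e-11 * d ** 12)
    return (0.8 + math.exp(-0.075 * d)) * (g - 1.0) + g


def _mu_rel_oracle(d, H):
    C = _shape_C_oracle(d)
    w = (d / (d - 1.1)) ** 2
    return (1 + (_mu045_oracle(d) - 1)
            * (((1 - H) ** C - 1) / ((1 - 0.45) ** C - 1)) * w) * w


def test_viscosity_formulas_match_scalar_oracle(rng):
    """mu045, shape C and relative viscosity agree with an independent
    pointwise evaluation to 1e-12 over 100 random (d, H) samples."""
    for _ in range(100):
        d = float(rng.uniform(2.0, 60.0))
        H = float(rng.uniform(0.0, 0.9))
        assert mu045(d) == pytest.approx(_mu045_oracle(d), abs=1e-12)
        assert shape_C(d) == pytest.approx(_shape_C_oracle(d), abs=1e-12)
        assert relative_viscosity(d, H) == pytest.approx(
            _mu_rel_oracle(d, H), abs=1e-12)


def test_viscosity_limits():
    """Asymptotics: mu045 -> 3.2 for wide tubes; C -> 1 (d -> 0) and
    C -> -0.8 (d -> infinity)."""
    assert mu045(1e6) == pytest.approx(3.2, abs=1e-12)
    assert shape_C(1e-6) == pytest.approx(1.0, rel=1e-6)
    assert shape_C(1e3) == pytest.approx(-0.8, abs=1e-9)
    assert mu045(10.0) == pytest.approx(3.892, abs=5e-4)


def test_viscosity_h_zero_and_monotonicity():
    for d in (5.0, 10.0, 20.0, 50.0):
        assert relative_viscosity(d, 0.0) == pytest.approx(
            (d / (d - 1.1)) ** 2, rel=1e-12)
        H = np.linspace(0.01, 0.8, 40)
        mu = relative_viscosity(d, H)
        assert np.all(np.diff(mu) > 0), f"d mu/dH <= 0 at d={d}"


def test_viscosity_domain_errors():
    with pytest.raises(ValueError):
        mu045(1.0)
    with pytest.raises(ValueError):
        relative_viscosity(10.0, 1.0)


def test_blood_viscosity_scales_with_plasma():
    assert blood_viscosity(10.0, 0.45, 2e-3) == pytest.approx(
        2 * blood_viscosity(10.0, 0.45, 1e-3), rel=1e-14)


# --------------------------------------------------------------------------
# elemental laws
# --------------------------------------------------------------------------

def test_poiseuille_closed_form():
    """Q = pi/128 dP d^4/(l mu): hand-checked value and d^4 scaling."""
    q = poiseuille_flow(100.0, 10.0, 100.0, 3e-3)
    assert q == pytest.approx(math.pi / 128 * 100 * (1e-5) ** 4 / (1e-4 * 3e-3),
                              rel=1e-14)
    assert q == pytest.approx(8.18e-14, rel=2e-3)
    assert poiseuille_flow(0.0, 10.0, 100.0, 3e-3) == 0.0
    assert poiseuille_flow(100.0, 20.0, 100.0, 3e-3) == pytest.approx(16 * q, rel=1e-12)


def test_starling_flow_equilibrium_and_area_invariance():
    # transmural equilibrium: hydrostatic difference equals oncotic term
    assert starling_flow(10, 50, 2e-11, 1000.0 + 0.5 * 666, 1000.0,
                         2666.0, 2000.0, 0.5) == pytest.approx(0.0, abs=1e-25)
    # sigma = 0: pure hydrostatic term
    q = starling_flow(10, 50, 2e-11, 10.0, 0.0, 2666.0, 2000.0, 0.0)
    assert q == pytest.approx(math.pi * 1e-5 * 5e-5 * 2e-11 * 10, rel=1e-12)
    # doubling d and halving l leaves the exchange area unchanged
    assert starling_flow(20, 25, 2e-11, 10.0, 0.0, 2666.0, 2000.0, 0.0) == \
        pytest.approx(q, rel=1e-12)


def test_wall_shear_stress():
    assert wall_shear_stress(0.0, 10.0, 3e-3) == 0.0
    t1 = wall_shear_stress(1e-13, 10.0, 3e-3)
    assert t1 == pytest.approx(32 * 3e-3 * 1e-13 / (math.pi * 1e-15), rel=1e-14)
    assert wall_shear_stress(1e-13, 20.0, 3e-3) == pytest.approx(t1 / 8, rel=1e-12)


def test_tau_e_values():
    """Set-point curve: exactly 14 at 10 mmHg (nested log vanishes), -> 100
    at high pressure, and the printed formula at 30 mmHg."""
    assert tau_e(10.0) == pytest.approx(14.0, abs=1e-12)
    assert tau_e(1e6) == pytest.approx(100.0, abs=1e-6)
    inner = math.log10(math.log10(30.0))
    expected = 100 - 86 * math.exp(-5000 * inner ** 5.4)
    assert tau_e(30.0) == pytest.approx(expected, rel=1e-12)
    # continued by the boundary value below 10 mmHg
    assert tau_e(2.0) == pytest.approx(14.0, abs=1e-12)


# --------------------------------------------------------------------------
# hematocrit phase separation
# --------------------------------------------------------------------------

def test_split_hematocrit_cases():
    p = FlowParams()
    # above the critical velocity ratio all red cells take the fast branch
    assert split_hematocrit(0.45, 3.0, 1.0, p) == (0.45, 0.0)
    # symmetric split at lambda = 1
    p1 = FlowParams(lambda_split=1.0)
    h1, h2 = split_hematocrit(0.45, 1.0, 1.0, p1)
    assert h1 == pytest.approx(0.225) and h2 == pytest.approx(0.225)
    # lambda = 2, equal velocities: H1/H2 = 2 with H1 + H2 = H_parent
    h1, h2 = split_hematocrit(0.45, 1.0, 1.0, p)
    assert h1 == pytest.approx(0.30, abs=1e-12)
    assert h2 == pytest.approx(0.15, abs=1e-12)
    # both stagnant: even split
    assert split_hematocrit(0.45, 0.0, 0.0, p) == (0.225, 0.225)
    with pytest.raises(ValueError):
        split_hematocrit(0.45, 1.0, 2.0, p)


def test_split_hematocrit_closure_property(rng):
    """The printed closure conserves the sum H1 + H2 = H_parent whenever
    no branch is clamped."""
    p = FlowParams()
    for _ in range(200):
        hp = rng.uniform(0, 0.9)
        u2 = rng.uniform(0.1, 1.0)
        u1 = u2 * rng.uniform(1.0, p.U_cr * 0.99)
        h1, h2 = split_hematocrit(hp, u1, u2, p)
        assert h1 + h2 == pytest.approx(hp, rel=1e-12)
        assert h1 >= h2 >= 0


# --------------------------------------------------------------------------
# network pressure solve
# --------------------------------------------------------------------------

def _line_network(cfg, n_nodes=2, d=10.0):
    """A parent vessel of n_nodes along the left edge (no capillaries)."""
    net = VesselNetwork(cfg.grid_nodes_per_side, cfg.grid_spacing)
    for i in range(n_nodes - 1):
        net.add_segment(net.flat(i, 0), net.flat(i + 1, 0), d)
    net.parent_nodes = [net.flat(i, 0) for i in range(n_nodes)]
    return net


def test_single_segment_matches_poiseuille(tiny_config):
    cfg = tiny_config
    cfg.flow.inlet_pressure, cfg.flow.outlet_pressure = 2000.0, 1000.0
    cfg.flow.Lp_tumor = cfg.flow.Lp_normal = 1e-30  # negligible leak
    net = _line_network(cfg, n_nodes=2, d=10.0)
    state = solve_network_pressures(net, cfg.flow, cfg)
    mu = blood_viscosity(10.0, cfg.flow.H_inlet, cfg.flow.mu_plasma)
    expected = poiseuille_flow(1000.0, 10.0, net.length_um, mu)
    assert state.Q_b[0] == pytest.approx(expected, rel=1e-10)


def test_symmetric_y_network_splits_evenly(tiny_config):
    """Two identical parallel branches carry identical flows and the
    junction residual is at solver precision."""
    cfg = tiny_config
    net = VesselNetwork(cfg.grid_nodes_per_side, cfg.grid_spacing)
    # parent: (0,0)-(1,0)-(2,0); two symmetric loops around columns 1
    net.add_segment(net.flat(0, 0), net.flat(1, 0), 20.0)
    net.add_segment(net.flat(1, 0), net.flat(2, 0), 20.0)
    net.parent_nodes = [net.flat(i, 0) for i in range(3)]
    # branch A: (0,0)->(0,1)->(1,1)->(1,0); branch B mirrored below
    net.add_segment(net.flat(0, 0), net.flat(0, 1), 10.0)
    net.add_segment(net.flat(0, 1), net.flat(1, 1), 10.0)
    net.add_segment(net.flat(1, 1), net.flat(1, 0), 10.0)
    net.add_segment(net.flat(2, 0), net.flat(2, 1), 10.0)
    net.add_segment(net.flat(2, 1), net.flat(1, 1), 10.0)
    cfg.flow.Lp_tumor = cfg.flow.Lp_normal = 1e-30
    state = solve_network_pressures(net, cfg.flow, cfg)
    res = junction_residuals(net, state)
    qmax = np.abs(state.Q_b).max()
    interior = [k for k, nd in enumerate(state.node_ids)
                if nd not in (net.parent_nodes[0], net.parent_nodes[-1])]
    assert np.abs(res[interior]).max() < 1e-10 * qmax


def _random_loop_network(cfg, rng, n_extra=50):
    """Parent vessel plus random lattice loops hanging off it."""
    n = cfg.grid_nodes_per_side
    net = _line_network(cfg, n_nodes=n, d=30.0)
    occ = {(i, 0) for i in range(n)}
    frontier = [(rng.integers(0, n), 0) for _ in range(3)]
    added = 0
    guard = 0
    while added < n_extra and guard < 50 * n_extra:
        guard += 1
        i, j = frontier[rng.integers(0, len(frontier))]
        di, dj = ((0, 1), (0, -1), (1, 0), (-1, 0))[rng.integers(0, 4)]
        ri, cj = i + di, j + dj
        if not (0 <= ri < n and 0 <= cj < n):
            continue
        if net.add_segment(net.flat(i, j), net.flat(ri, cj),
                           float(rng.uniform(6, 15))):
            added += 1
            frontier.append((ri, cj))
            occ.add((ri, cj))
    return net


def test_random_network_against_dense_oracle(tiny_config, rng):
    """Junction residuals below tolerance and nodal pressures agreeing with
    an independent dense linear-algebra solve at fixed conductances."""
    cfg = tiny_config
    cfg.flow.Lp_tumor = cfg.flow.Lp_normal = 1e-30
    net = _random_loop_network(cfg, rng, n_extra=50)
    state = solve_network_pressures(net, cfg.flow, cfg)
    qmax = np.abs(state.Q_b).max()
    inlet, outlet = net.parent_nodes[0], net.parent_nodes[-1]
    res = junction_residuals(net, state)
    interior = [k for k, nd in enumerate(state.node_ids)
                if nd not in (inlet, outlet)]
    assert np.abs(res[interior]).max() < 1e-10 * qmax

    # dense oracle: rebuild the Kirchhoff system with plain Python loops
    # from the converged viscosities and solve with numpy
    nodes = sorted(net.nodes)
    idx = {nd: k for k, nd in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    rhs = np.zeros(len(nodes))
    a, b, d = net.segment_arrays()
    for k in range(len(a)):
        g = math.pi / 128 * (d[k] * 1e-6) ** 4 / (
            net.length_um * 1e-6 * state.mu_blood[k])
        ka, kb = idx[int(a[k])], idx[int(b[k])]
        A[ka, ka] += g
        A[kb, kb] += g
        A[ka, kb] -= g
        A[kb, ka] -= g
    for nd, val in ((inlet, cfg.flow.inlet_pressure),
                    (outlet, cfg.flow.outlet_pressure)):
        A[idx[nd], :] = 0.0
        A[idx[nd], idx[nd]] = 1.0
        rhs[idx[nd]] = val
    pb_oracle = np.linalg.solve(A, rhs)
    mine = np.array([state.node_pressure(nd) for nd in nodes])
    assert np.allclose(mine, pb_oracle, rtol=1e-8)


def test_pressure_bounds_maximum_principle(tiny_config, rng):
    """Without sources, every nodal pressure lies between the Dirichlet
    inlet and outlet values."""
    cfg = tiny_config
    cfg.flow.Lp_tumor = cfg.flow.Lp_normal = 1e-30
    net = _random_loop_network(cfg, rng, n_extra=30)
    state = solve_network_pressures(net, cfg.flow, cfg)
    assert state.Pb.max() <= cfg.flow.inlet_pressure + 1e-9
    assert state.Pb.min() >= cfg.flow.outlet_pressure - 1e-9


def test_disconnected_component_raises(tiny_config):
    cfg = tiny_config
    net = _line_network(cfg, n_nodes=3)
    net.add_segment(net.flat(5, 5), net.flat(5, 6), 10.0)  # stray island
    with pytest.raises(ValueError, match="disconnected"):
        solve_network_pressures(net, cfg.flow, cfg)


# --------------------------------------------------------------------------
# adaptation
# --------------------------------------------------------------------------

def test_adaptation_stimuli_examples(tiny_config):
    """S_wss = 0 when tau_w + tau_ref = 1; S_m = 1 when Q_ref/(QH) = 9;
    S_p at 10 mmHg equals -log10(14)."""
    cfg = tiny_config
    net = _line_network(cfg, n_nodes=3, d=10.0)
    net.parent_nodes = []  # treat both segments as capillaries
    pa = 10 * 133.322
    # equal flows so Q_ref is exact; the second segment's hematocrit makes
    # Q_ref/(Q H) = 9
    state = NetworkFlowState(
        node_ids=net.node_list(),
        Pb=np.full(3, pa),
        Q_b=np.array([9e-13, 9e-13]),
        Q_t=np.zeros(2), H=np.array([1.0, 1.0 / 9.0]),
        mu_blood=np.full(2, 3e-3),
        tau_w=np.array([1.0 - cfg.flow.tau_ref, 0.5]),
    )
    s_wss, s_p, s_m = adaptation_stimuli(net, state, cfg.flow)
    assert s_wss[0] == pytest.approx(0.0, abs=1e-12)
    assert s_p[0] == pytest.approx(-math.log10(14.0), abs=1e-12)
    # Q_ref = 9e-13, segment 1 has Q*H = 1e-13 -> ratio 9 -> log10(10) = 1
    assert s_m[1] == pytest.approx(1.0, abs=1e-12)


def test_adaptation_growth_and_shrink_direction(tiny_config):
    """A strongly positive net stimulus grows diameters; a strongly
    negative one shrinks them (parent trunk untouched)."""
    cfg = tiny_config
    cfg.flow.adaptation_max_iter = 5
    cfg.flow.adaptation_dt = 0.5
    net = _line_network(cfg, n_nodes=cfg.grid_nodes_per_side, d=30.0)
    n = cfg.grid_nodes_per_side
    # a perfused side loop
    net.add_segment(net.flat(0, 0), net.flat(0, 1), 10.0)
    net.add_segment(net.flat(0, 1), net.flat(1, 1), 10.0)
    net.add_segment(net.flat(1, 1), net.flat(1, 0), 10.0)
    cfg.flow.k_s = -50.0  # huge growth offset
    grown, _ = adapt_diameters(net, cfg.flow, cfg)
    mask = ~parent_segment_mask(net)
    d0 = np.array(net.diameters_um)[mask]
    d1 = np.array(grown.diameters_um)[mask]
    assert np.all(d1 > d0)
    cfg.flow.k_s = 50.0  # huge shrink offset
    shrunk, _ = adapt_diameters(net, cfg.flow, cfg)
    d2 = np.array(shrunk.diameters_um)[mask]
    assert np.all(d2 < d0)
    # parent trunk diameters never remodel
    dp0 = np.array(net.diameters_um)[~mask]
    dp1 = np.array(grown.diameters_um)[~mask]
    assert np.array_equal(dp0, dp1)


def test_adaptation_fixed_point_matches_scalar_oracle(tiny_config):
    """Single capillary loop off the parent: the converged diameter equals
    a brute-force scalar fixed-point iteration built from the elemental
    laws only."""
    cfg = tiny_config
    cfg.flow.adaptation_max_iter = 400
    cfg.flow.adaptation_dt = 0.2
    cfg.flow.Lp_tumor = cfg.flow.Lp_normal = 1e-30
    cfg.flow.k_s = -1.5
    n = cfg.grid_nodes_per_side
    net = _line_network(cfg, n_nodes=n, d=30.0)
    # capillary loop: off at row 3, back at row 7 via column 1
    path = [(3, 0), (3, 1), (4, 1), (5, 1), (6, 1), (7, 1), (7, 0)]
    for (i1, j1), (i2, j2) in zip(path[:-1], path[1:]):
        net.add_segment(net.flat(i1, j1), net.flat(i2, j2), 10.0)
    grown, state = adapt_diameters(net, cfg.flow, cfg)
    cap = ~parent_segment_mask(grown)
    d_solver = np.array(grown.diameters_um)[cap]
    # all loop segments carry the same flow -> identical diameters
    assert np.ptp(d_solver) < 1e-6

    # scalar oracle: the loop sees the parent-vessel pressure difference
    # between its two taps (linear trunk profile, negligible draw); iterate
    # d <- clamp(d + dt * S_total(d)) from the elemental laws only
    p = cfg.flow
    dP_taps = (p.inlet_pressure - p.outlet_pressure) * (7 - 3) / (n - 1)
    H = float(state.H[cap][0])  # phase separation assigns the loop's H
    pb_mid = p.inlet_pressure - (p.inlet_pressure - p.outlet_pressure) * 5 / (n - 1)
    d = 10.0
    for _ in range(400):
        mu = blood_viscosity(d, H, p.mu_plasma)
        q = poiseuille_flow(dP_taps / 6, d, net.length_um, mu)
        tw = wall_shear_stress(q, d, mu)
        qh = max(q * H, 1e-4 * q)  # q is also Q_ref for this single loop
        s = (math.log10(tw + p.tau_ref)
             + p.k_p * (-math.log10(tau_e(pb_mid / 133.322)))
             + p.k_m * math.log10(q / qh + 1.0)
             - p.k_s)
        d = min(max(d + p.adaptation_dt * s, p.d_min_um), p.d_max_um)
    assert d_solver[0] == pytest.approx(d, rel=0.02)


# --------------------------------------------------------------------------
# pruning
# --------------------------------------------------------------------------

def test_prune_removes_blind_ends_keeps_loops(tiny_config):
    cfg = tiny_config
    net = _line_network(cfg, n_nodes=5, d=20.0)
    # perfused loop
    net.add_segment(net.flat(0, 0), net.flat(0, 1), 10.0)
    net.add_segment(net.flat(0, 1), net.flat(1, 1), 10.0)
    net.add_segment(net.flat(1, 1), net.flat(1, 0), 10.0)
    # blind end (no flow)
    net.add_segment(net.flat(2, 0), net.flat(2, 1), 10.0)
    state = solve_network_pressures(net, cfg.flow, cfg)
    pruned, report = prune_network(net, state, 0.01)
    assert report["removed_low_flow"] == 1
    assert not pruned.has_segment(net.flat(2, 0), net.flat(2, 1))
    assert pruned.has_segment(net.flat(0, 1), net.flat(1, 1))


def test_prune_boundary_segment_retained(tiny_config):
    """A segment carrying exactly the threshold flow is kept (strict <)."""
    cfg = tiny_config
    net = _line_network(cfg, n_nodes=3, d=10.0)
    net.parent_nodes = []
    state = NetworkFlowState(
        node_ids=net.node_list(), Pb=np.zeros(3),
        Q_b=np.array([1.0, 0.01]), Q_t=np.zeros(2), H=np.zeros(2),
        mu_blood=np.full(2, 1e-3), tau_w=np.zeros(2))
    pruned, _ = prune_network(net, state, 0.01)
    assert pruned.n_segments == 2  # both kept: 0.01 == 1% of max exactly


def test_prune_everything_raises(tiny_config):
    """Removing a low-flow segment that disconnects the rest empties the
    network entirely, which must raise instead of returning nothing."""
    cfg = tiny_config
    net = VesselNetwork(cfg.grid_nodes_per_side, cfg.grid_spacing)
    net.add_segment(0, 1, 10.0)
    net.add_segment(1, 2, 10.0)
    net.parent_nodes = [0]
    state = NetworkFlowState(
        node_ids=net.node_list(), Pb=np.zeros(3),
        Q_b=np.array([1e-6, 1.0]), Q_t=np.zeros(2), H=np.zeros(2),
        mu_blood=np.full(2, 1e-3), tau_w=np.zeros(2))
    with pytest.raises(RuntimeError):
        prune_network(net, state, 0.01)
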