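"""Hybrid discrete-continuum sprouting angiogenesis.

Tip endothelial cells (tECs) perform a biased lattice walk whose movement
probabilities come from a five-point discretization of the EC conservation
equation

    dn/dt = Dn lap(n) - div[ chi/(1+alpha*c) n grad(c) + phi n grad(f) ]

with saturating chemotaxis up the tumor-angiogenesis-factor (TAF) gradient
and haptotaxis up the fibronectin gradient.  The continuum fields obey

    df/dt = beta*n - gamma*n*f        (production/uptake by ECs)
    dc/dt = -eta*n*c                  (TAF uptake only)

where n is EC occupancy (1 at vessel nodes).  Branching probability grows
with local TAF; a tip stepping onto an occupied node anastomoses (fuses)
and deactivates, creating perfusable loops.  Everything is nondimensional
on the unit square; the lattice is shared with the flow and transport
stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import AngiogenesisParams, SimulationConfig
from .fields import ScalarField
from .network import VesselNetwork

logger = logging.getLogger("angiopet")

__all__ = [
    "TipCell", "MovementProbabilities",
    "init_taf_field", "init_fibronectin_field",
    "update_fibronectin", "update_taf",
    "movement_probabilities", "step_tips", "attempt_branching",
    "grow_network",
]

# move order: stay, right, left, up, down.  Offsets are (di, dj).
_OFFSETS = np.array([[0, 0], [0, 1], [0, -1], [1, 0], [-1, 0]])


@dataclass
class TipCell:
    node: int              # flat lattice index
    sprout_id: int
    age: int = 0           # steps since creation / last branch
    active: bool = True
    prev_node: int | None = None  # immediate reversal is excluded


@dataclass
class MovementProbabilities:
    """P0..P4 = stay, right, left, up, down; sums to 1."""
    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape[-1] != 5:
            raise ValueError("expected five movement probabilities")


# --------------------------------------------------------------------------
# initial fields
# --------------------------------------------------------------------------

def _tumor_distance(config: SimulationConfig) -> np.ndarray:
    """Euclidean distance (in units of L) from the tumor boundary; zero
    inside the tumor disc."""
    n = config.grid_nodes_per_side
    cx, cy = config.tumor_center
    r = 0.5 * config.tumor_size_ratio
    x = np.linspace(0.0, 1.0, n)
    jj, ii = np.meshgrid(x, x)
    return np.maximum(np.hypot(jj - cx, ii - cy) - r, 0.0)


def init_taf_field(config: SimulationConfig) -> ScalarField:
    """TAF concentration: 1 inside the tumor, Gaussian decay with distance
    from the tumor rim, minimum near the parent vessel."""
    dist = _tumor_distance(config)
    dmax = float(dist.max())
    dn = dist / dmax if dmax > 0 else dist
    c = np.exp(-dn ** 2 / config.angiogenesis.eps1)
    return ScalarField(c, config.grid_spacing, units="nondim", name="taf")


def init_fibronectin_field(config: SimulationConfig) -> ScalarField:
    """Fibronectin: maximal at the parent vessel (x = 0), Gaussian decay
    toward the tumor, f = k * exp(-x^2 / eps2); flat (at the lowest rim
    value) inside the tumor mask, where proteases have degraded the
    adhesive matrix, so haptotaxis exerts no bias within the tumor."""
    n = config.grid_nodes_per_side
    p = config.angiogenesis
    x = np.linspace(0.0, 1.0, n)
    vals = np.tile(p.fibronectin_amplitude * np.exp(-x ** 2 / p.eps2), (n, 1))
    tm = config.tumor_mask()
    if tm.any():
        vals[tm] = vals[tm].min()
    return ScalarField(vals, config.grid_spacing,
                       units="nondim", name="fibronectin")


# --------------------------------------------------------------------------
# continuum updates
# --------------------------------------------------------------------------

def update_fibronectin(f: ScalarField, n_occ: np.ndarray,
                       params: AngiogenesisParams, dt: float) -> ScalarField:
    """Explicit pointwise step of df/dt = beta*n - gamma*n*f."""
    if f.values.shape != n_occ.shape:
        raise ValueError("field and occupancy shapes differ")
    if np.any(f.values < 0) or np.any(n_occ < 0):
        raise ValueError("fibronectin and occupancy must be non-negative")
    out = f.values + dt * n_occ * (params.beta - params.gamma * f.values)
    return ScalarField(np.maximum(out, 0.0), f.grid_spacing, f.units, f.name)


def update_taf(c: ScalarField, n_occ: np.ndarray,
               params: AngiogenesisParams, dt: float) -> ScalarField:
    """Explicit pointwise step of dc/dt = -eta*n*c (uptake only)."""
    if c.values.shape != n_occ.shape:
        raise ValueError("field and occupancy shapes differ")
    out = c.values * (1.0 - dt * params.eta * n_occ)
    return ScalarField(np.maximum(out, 0.0), c.grid_spacing, c.units, c.name)


# --------------------------------------------------------------------------
# tip movement
# --------------------------------------------------------------------------

def _probabilities_array(rows: np.ndarray, cols: np.ndarray, c: np.ndarray,
                         f: np.ndarray, params: AngiogenesisParams,
                         dt: float, h: float) -> np.ndarray:
    """Vectorized movement probabilities for tips at (rows, cols).

    Neighbor contributions: Dn*dt/h^2 diffusive part plus chemotactic
    chi/(1+alpha*c_mid)*(c_nb - c_here) and haptotactic phi*(f_nb - f_here)
    terms evaluated at the cell/neighbor midpoint.  Moves that would leave
    the domain get probability zero.  Negative intermediates are clipped
    and the vector renormalized; P0 absorbs the remainder.
    """
    lam = dt / h ** 2
    if 4.0 * params.Dn * lam > 1.0:
        raise ValueError(
            f"dt_nd={dt} too large for h={h}: 4*Dn*dt/h^2 = "
            f"{4 * params.Dn * lam:.3f} > 1; reduce dt_nd")
    n = c.shape[0]
    m = len(rows)
    P = np.zeros((m, 5))
    c_here = c[rows, cols]
    f_here = f[rows, cols]
    for k in range(1, 5):
        di, dj = _OFFSETS[k]
        ri, cj = rows + di, cols + dj
        ok = (ri >= 0) & (ri < n) & (cj >= 0) & (cj < n)
        cn = np.where(ok, c[ri % n, cj % n], 0.0)
        fn = np.where(ok, f[ri % n, cj % n], 0.0)
        chi_mid = params.chi / (1.0 + params.alpha * 0.5 * (cn + c_here))
        contrib = lam * (params.Dn
                         + chi_mid * (cn - c_here)
                         + params.phi_hapto * (fn - f_here))
        P[:, k] = np.where(ok, np.maximum(contrib, 0.0), 0.0)
    s = P[:, 1:].sum(axis=1)
    over = s > 1.0
    if np.any(over):
        P[over, 1:] /= s[over, None]
        s[over] = 1.0
    P[:, 0] = 1.0 - s
    return P


def movement_probabilities(tip: TipCell, c: ScalarField, f: ScalarField,
                           params: AngiogenesisParams, dt: float,
                           h: float) -> MovementProbabilities:
    """Movement probabilities (stay, right, left, up, down) for one tip."""
    n = c.values.shape[0]
    i, j = divmod(tip.node, n)
    P = _probabilities_array(np.array([i]), np.array([j]), c.values, f.values,
                             params, dt, h)[0]
    return MovementProbabilities(P)


class TipArrays:
    """Vectorized tip-cell population (internal fast path).

    ``node``/``prev`` are flat lattice indices (-1 = no predecessor),
    parallel to ``age``, ``active`` and ``sprout``.
    """

    def __init__(self):
        self.node = np.empty(0, dtype=np.int64)
        self.prev = np.empty(0, dtype=np.int64)
        self.age = np.empty(0, dtype=np.int64)
        self.active = np.empty(0, dtype=bool)
        self.sprout = np.empty(0, dtype=np.int64)

    @classmethod
    def from_tips(cls, tips: list[TipCell]) -> "TipArrays":
        ta = cls()
        ta.node = np.array([t.node for t in tips], dtype=np.int64)
        ta.prev = np.array([-1 if t.prev_node is None else t.prev_node
                            for t in tips], dtype=np.int64)
        ta.age = np.array([t.age for t in tips], dtype=np.int64)
        ta.active = np.array([t.active for t in tips], dtype=bool)
        ta.sprout = np.array([t.sprout_id for t in tips], dtype=np.int64)
        return ta

    def write_back(self, tips: list[TipCell]) -> None:
        for k, t in enumerate(tips[:len(self.node)]):
            t.node = int(self.node[k])
            t.prev_node = None if self.prev[k] < 0 else int(self.prev[k])
            t.age = int(self.age[k])
            t.active = bool(self.active[k])
        for k in range(len(tips), len(self.node)):
            tips.append(TipCell(node=int(self.node[k]),
                                sprout_id=int(self.sprout[k]),
                                age=int(self.age[k]),
                                active=bool(self.active[k]),
                                prev_node=None if self.prev[k] < 0
                                else int(self.prev[k])))

    def append(self, node, prev, sprout) -> None:
        self.node = np.append(self.node, node)
        self.prev = np.append(self.prev, prev)
        self.age = np.append(self.age, np.zeros(len(node), dtype=np.int64))
        self.active = np.append(self.active, np.ones(len(node), dtype=bool))
        self.sprout = np.append(self.sprout, sprout)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def _step_tip_arrays(ta: TipArrays, net: VesselNetwork, cvals: np.ndarray,
                     fvals: np.ndarray, params: AngiogenesisParams, dt: float,
                     h: float, rng: np.random.Generator,
                     occ: np.ndarray) -> None:
    """One vectorized movement step; only actual movers enter the Python
    loop (their total over a run is bounded by the segment count)."""
    n = net.n_side
    act = np.nonzero(ta.active)[0]
    if len(act) == 0:
        return
    rows, cols = np.divmod(ta.node[act], n)
    P = _probabilities_array(rows, cols, cvals, fvals, params, dt, h)
    # forbid immediate reversal: zero the move pointing back at prev
    has_prev = ta.prev[act] >= 0
    if np.any(has_prev):
        pi, pj = np.divmod(np.where(has_prev, ta.prev[act], 0), n)
        di = pi - rows
        dj = pj - cols
        for k in range(1, 5):
            back = has_prev & (di == _OFFSETS[k][0]) & (dj == _OFFSETS[k][1])
            P[back, 0] += P[back, k]
            P[back, k] = 0.0
    u = rng.random(len(act))
    moves = (u[:, None] >= np.cumsum(P, axis=1)).sum(axis=1)
    ta.age[act] += 1
    movers = np.nonzero(moves > 0)[0]
    for idx in movers:
        t = act[idx]
        di, dj = _OFFSETS[moves[idx]]
        ri, cj = rows[idx] + di, cols[idx] + dj
        if not (0 <= ri < n and 0 <= cj < n):
            ta.active[t] = False
            continue
        target = int(ri) * n + int(cj)
        node = int(ta.node[t])
        fused = bool(occ[ri, cj]) and target != node
        net.add_segment(node, target, params.d0_um)
        occ[ri, cj] = True
        if fused:
            ta.active[t] = False  # anastomosis
        else:
            ta.prev[t] = node
            ta.node[t] = target


def _branch_tip_arrays(ta: TipArrays, cvals: np.ndarray,
                       params: AngiogenesisParams, rng: np.random.Generator,
                       occ: np.ndarray) -> None:
    """Vectorized branching: eligible tips spawn a co-located tip with
    probability given by the local-TAF table.

    A branch requires room: an unoccupied 4-neighbor, and fewer than two
    tips already on the node (one mother, one daughter) — sprout tips are
    physical cells and cannot stack, and without the cap the population
    at a saturated-TAF colonization front grows without bound.
    """
    n = cvals.shape[0]
    elig = np.nonzero(ta.active & (ta.age >= params.branch_age_min))[0]
    if len(elig) == 0:
        return
    # tips per node, over all active tips
    counts = np.zeros(n * n, dtype=np.int64)
    np.add.at(counts, ta.node[ta.active], 1)
    rows, cols = np.divmod(ta.node[elig], n)
    thresholds = np.asarray(params.branch_taf_thresholds)
    probs = np.asarray(params.branch_probabilities)
    p = probs[np.searchsorted(thresholds, cvals[rows, cols], side="right")]
    hit = rng.random(len(elig)) < p
    # room check: at least one unoccupied 4-neighbor
    free = np.zeros(len(elig), dtype=bool)
    for di, dj in _OFFSETS[1:]:
        ri, cj = rows + di, cols + dj
        ok = (ri >= 0) & (ri < n) & (cj >= 0) & (cj < n)
        free |= ok & ~occ[ri % n, cj % n]
    sel = elig[hit & free & (counts[ta.node[elig]] < 2)]
    if len(sel) == 0:
        return
    ta.age[sel] = 0
    next_id = int(ta.sprout.max()) + 1 if len(ta.sprout) else 0
    ta.append(ta.node[sel].copy(), ta.prev[sel].copy(),
              np.arange(next_id, next_id + len(sel), dtype=np.int64))


def step_tips(tips: list[TipCell], net: VesselNetwork, c: ScalarField,
              f: ScalarField, params: AngiogenesisParams, dt: float,
              h: float, rng: np.random.Generator,
              occupancy: np.ndarray | None = None) -> None:
    """Advance every active tip one step (in place).

    Each tip samples one of five moves by cumulative-sum inversion in the
    fixed order stay/right/left/up/down.  A move lays a new segment of
    diameter d0; stepping onto an occupied node records the segment and
    deactivates the tip (anastomosis).  Immediate reversal onto the node
    the tip just came from is excluded.
    """
    if occupancy is None:
        occupancy = np.zeros((net.n_side, net.n_side), dtype=bool)
        for nd in net.nodes:
            occupancy[nd // net.n_side, nd % net.n_side] = True
    ta = TipArrays.from_tips(tips)
    _step_tip_arrays(ta, net, c.values, f.values, params, dt, h, rng,
                     occupancy)
    ta.write_back(tips)


def branch_probability(c_local: float, params: AngiogenesisParams) -> float:
    """Piecewise-constant branching probability, non-decreasing in TAF."""
    k = int(np.searchsorted(np.asarray(params.branch_taf_thresholds), c_local,
                            side="right"))
    return params.branch_probabilities[k]


def attempt_branching(tips: list[TipCell], c: ScalarField,
                      params: AngiogenesisParams, rng: np.random.Generator,
                      occupancy: np.ndarray | None = None) -> list[TipCell]:
    """Tips older than branch_age_min may spawn a second tip at their node
    with probability increasing with local TAF; both ages reset.  A branch
    requires at least one unoccupied 4-neighbor (no room, no branch)."""
    if occupancy is None:
        n_side = c.values.shape[0]
        occupancy = np.zeros((n_side, n_side), dtype=bool)
        for t in tips:
            occupancy[t.node // n_side, t.node % n_side] = True
    ta = TipArrays.from_tips(tips)
    _branch_tip_arrays(ta, c.values, params, rng, occupancy)
    ta.write_back(tips)
    return tips


# --------------------------------------------------------------------------
# full growth loop
# --------------------------------------------------------------------------

def _parent_vessel(config: SimulationConfig) -> VesselNetwork:
    n = config.grid_nodes_per_side
    net = VesselNetwork(n, config.grid_spacing)
    d = config.angiogenesis.parent_diameter_um
    for i in range(n - 1):
        net.add_segment(net.flat(i, 0), net.flat(i + 1, 0), d)
    net.parent_nodes = [net.flat(i, 0) for i in range(n)]
    return net


def sprout_rows(config: SimulationConfig) -> list[int]:
    """Initial sprout positions, equally spaced along the parent vessel."""
    n = config.grid_nodes_per_side
    k = config.n_initial_sprouts
    return [int(round((s + 1) / (k + 1) * (n - 1))) for s in range(k)]


def grow_network(config: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 snapshot_callback=None) -> tuple[VesselNetwork, ScalarField, ScalarField]:
    """Run the full angiogenesis loop and return (network, TAF, fibronectin).

    Each step: tip movement -> branching -> continuum field updates.  Each
    sprout starts with one segment extending perpendicular from the parent
    vessel (the biological sprout bud), which also guarantees the required
    number of sprout lineages.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.grid_nodes_per_side
    h = 1.0 / (n - 1)
    p = config.angiogenesis
    net = _parent_vessel(config)
    c = init_taf_field(config)
    f = init_fibronectin_field(config)
    occ = np.zeros((n, n), dtype=bool)
    occ[:, 0] = True
    ta = TipArrays()
    rows = sprout_rows(config)
    for sid, row in enumerate(rows):
        a, b = net.flat(row, 0), net.flat(row, 1)
        net.add_segment(a, b, p.d0_um)
        occ[row, 1] = True
    ta.append(np.array([net.flat(r, 1) for r in rows], dtype=np.int64),
              np.array([net.flat(r, 0) for r in rows], dtype=np.int64),
              np.arange(len(rows), dtype=np.int64))

    n_steps = config.n_steps
    had_anastomosis = False
    for step in range(n_steps):
        before = ta.n_active
        _step_tip_arrays(ta, net, c.values, f.values, p, p.dt_nd, h, rng, occ)
        if ta.n_active < before:
            had_anastomosis = True
        _branch_tip_arrays(ta, c.values, p, rng, occ)
        n_occ = occ.astype(float)
        f = update_fibronectin(f, n_occ, p, p.dt_nd)
        c = update_taf(c, n_occ, p, p.dt_nd)
        if snapshot_callback is not None and config.steps_per_day > 0 \
                and (step + 1) % config.steps_per_day == 0:
            tips: list[TipCell] = []
            ta.write_back(tips)
            snapshot_callback((step + 1) // config.steps_per_day, net, c, f, tips)
        if ta.n_active == 0:
            if not had_anastomosis:
                logger.warning(
                    "all tips deactivated at step %d before any anastomosis; "
                    "returning partial network", step + 1)
            break
    return net, c, f
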