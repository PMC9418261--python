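"""Spatiotemporal tracer kinetics (FDG by default).

Three coupled concentration fields on the lattice: extracellular Ci
(transported by interstitial diffusion and convection), intracellular free
Ce, and intracellular phosphorylated Cm (trapped):

    dCi/dt = D_eff lap(Ci) - v_i . grad(Ci) + L1 Cp - (L2 + L3) Ci + L4 Ce
    dCe/dt = L3 Ci - (L4 + L5) Ce
    dCm/dt = L5 Ce

The exchange rates L1, L2 are built per cell from the hemodynamic and
interstitial solutions (Starling filtration plus transvascular diffusion
moderated by the wall Peclet number); L3..L5 are cellular rates.  The
scheme is operator splitting: explicit first-order upwind advection,
backward-Euler sparse diffusion (factorized once), and an exact implicit
solve of the local linear reaction system.  The well-mixed limit
(D_eff = 0, v = 0, uniform rates) reduces to the classic 4-compartment
5-rate-constant (5K) ODE model, which doubles as the correctness anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import InterstitialParams, SDMParams, SimulationConfig
from .fields import ScalarField, VectorField
from .interstitial import IFPSolution, TissueDomain, phi_b, phi_L

logger = logging.getLogger("angiopet")

__all__ = [
    "InputFunction", "KineticConstants", "ConcentrationState",
    "TimeActivityCurve", "aif_parametric", "peclet", "peclet_factor",
    "compute_L1", "compute_L2", "rate_fields", "step_sdm",
    "ode_5k_reference", "simulate_uptake",
]


# --------------------------------------------------------------------------
# arterial input function
# --------------------------------------------------------------------------

def aif_parametric(t, params: SDMParams):
    """Parametric plasma input: bolus rise A1*t*exp(-t/tau1) plus washout
    A2*(exp(-t/tau2) - exp(-t/tau1)); Cp(0) = 0, a single early peak, then
    monotone decay.  kBq/ml."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("aif_parametric requires t >= 0")
    return (params.aif_A1 * t * np.exp(-t / params.aif_tau1)
            + params.aif_A2 * (np.exp(-t / params.aif_tau2)
                               - np.exp(-t / params.aif_tau1)))


@dataclass
class InputFunction:
    """Plasma concentration Cp(t): parametric, or a sampled table that
    overrides it (linear interpolation between knots)."""

    params: SDMParams
    times_s: np.ndarray | None = None
    cp_kbq_ml: np.ndarray | None = None

    @classmethod
    def from_csv(cls, path, params: SDMParams) -> "InputFunction":
        df = pd.read_csv(path)
        t = np.asarray(df["time_s"], dtype=float)
        v = np.asarray(df["cp_kbq_per_ml"], dtype=float)
        if np.any(v < 0):
            raise ValueError("tabulated Cp must be non-negative")
        return cls(params, t, v)

    def __call__(self, t):
        if self.times_s is not None:
            return np.interp(t, self.times_s, self.cp_kbq_ml)
        return aif_parametric(t, self.params)


# --------------------------------------------------------------------------
# compartment constants and states
# --------------------------------------------------------------------------

@dataclass
class KineticConstants:
    """5K model rates: K1/K2 plasma<->extracellular, K3/K4 in/out of the
    cell, K5 phosphorylation.  1/s."""

    K1: float
    K2: float
    K3: float
    K4: float
    K5: float

    def __post_init__(self):
        for name in ("K1", "K2", "K3", "K4", "K5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ConcentrationState:
    """Ci, Ce, Cm fields (kBq/ml) at time t; Ctot is their sum."""

    t: float
    Ci: ScalarField
    Ce: ScalarField
    Cm: ScalarField

    @property
    def Ctot(self) -> ScalarField:
        return ScalarField(self.Ci.values + self.Ce.values + self.Cm.values,
                           self.Ci.grid_spacing, "kBq/ml", "c_tot")


@dataclass
class TimeActivityCurve:
    """Regional mean concentration curves (tumor / normal)."""

    frame: pd.DataFrame  # columns time_s, tumor_ci, ..., normal_ctot

    def tumor(self, component: str) -> np.ndarray:
        return self.frame[f"tumor_{component}"].to_numpy()


# --------------------------------------------------------------------------
# exchange-rate fields
# --------------------------------------------------------------------------

def peclet(phi_b_local, sigma_f, Pm, S_over_V):
    """Transvascular Peclet number Pe = phi_b (1 - sigma_f) / (Pm S/V)."""
    return phi_b_local * (1.0 - sigma_f) / (Pm * S_over_V)


def peclet_factor(Pe):
    """Pe / (e^Pe - 1), with the removable singularity at Pe = 0 handled
    by the series 1 - Pe/2 + Pe^2/12 for |Pe| < 1e-4."""
    Pe = np.asarray(Pe, dtype=float)
    small = np.abs(Pe) < 1e-4
    safe = np.where(small, 1.0, Pe)
    with np.errstate(over="ignore"):
        full = safe / np.expm1(safe)
    series = 1.0 - Pe / 2.0 + Pe ** 2 / 12.0
    return np.where(small, series, full)


def rate_fields(domain: TissueDomain, ifp: IFPSolution, sdm: SDMParams,
                inter: InterstitialParams) -> dict[str, np.ndarray]:
    """Per-cell L1..L5 plus the Peclet field.  Cells without vessel
    surface have no transvascular exchange (L1 = 0, L2 = lymphatic only)."""
    t = domain.tumor_mask
    sv = domain.S_over_V
    Pi = ifp.Pi.values
    Pm = np.where(t, sdm.Pm_tumor, sdm.Pm_normal)
    fb = phi_b(domain, Pi, inter)
    fl = phi_L(domain, Pi, inter)
    vessel = sv > 0
    Pe = np.zeros_like(sv)
    Pe[vessel] = peclet(fb[vessel], sdm.sigma_f, Pm[vessel], sv[vessel])
    diff_term = np.where(vessel, Pm * sv * peclet_factor(Pe), 0.0)
    L1 = np.where(vessel, fb * (1.0 - sdm.sigma_f) + diff_term, 0.0)
    L2 = diff_term + fl
    scale = np.where(t, 1.0, sdm.normal_rate_scale)
    return {
        "L1": L1, "L2": L2, "Pe": Pe,
        "L3": sdm.L3_tumor * scale,
        "L4": sdm.L4_tumor * scale,
        "L5": sdm.L5_tumor * scale,
    }


def compute_L1(domain: TissueDomain, ifp: IFPSolution, sdm: SDMParams,
               inter: InterstitialParams) -> np.ndarray:
    """Plasma -> extracellular rate: convective filtration plus Peclet-
    moderated transvascular diffusion.  1/s."""
    return rate_fields(domain, ifp, sdm, inter)["L1"]


def compute_L2(domain: TissueDomain, ifp: IFPSolution, sdm: SDMParams,
               inter: InterstitialParams) -> np.ndarray:
    """Extracellular loss rate: transvascular diffusion back to plasma
    plus lymphatic drainage (normal tissue only).  1/s."""
    return rate_fields(domain, ifp, sdm, inter)["L2"]


# --------------------------------------------------------------------------
# PDE stepping
# --------------------------------------------------------------------------

def _neumann_laplacian(n: int, h: float) -> sp.csr_matrix:
    """Symmetric 5-point Laplacian with no-flux boundaries (zero row sums)."""
    idx = np.arange(n * n).reshape(n, n)
    rows, cols, vals = [], [], []
    w = 1.0 / h ** 2
    for di, dj in ((0, 1), (1, 0)):
        a = idx[: n - di, : n - dj].ravel()
        b = idx[di:, dj:].ravel()
        rows.extend(a); cols.extend(b); vals.extend(np.full(len(a), w))
        rows.extend(b); cols.extend(a); vals.extend(np.full(len(a), w))
        rows.extend(a); cols.extend(a); vals.extend(np.full(len(a), -w))
        rows.extend(b); cols.extend(b); vals.extend(np.full(len(a), -w))
    return sp.csr_matrix((vals, (rows, cols)), shape=(n * n, n * n))


class _DiffusionSolver:
    """Cached LU factorization of (I - dt D_eff lap) for backward Euler."""

    def __init__(self, n: int, h: float, D: float, dt: float):
        A = sp.identity(n * n, format="csr") - dt * D * _neumann_laplacian(n, h)
        self.lu = spla.splu(A.tocsc())
        self.n = n

    def step(self, C: np.ndarray) -> np.ndarray:
        return self.lu.solve(C.ravel()).reshape(self.n, self.n)


def _upwind_advect(C: np.ndarray, vx: np.ndarray, vy: np.ndarray,
                   h: float, dt: float) -> np.ndarray:
    """Explicit first-order upwind step of -v . grad(C) (advective form)."""
    dcdx_m = np.zeros_like(C)
    dcdx_p = np.zeros_like(C)
    dcdx_m[:, 1:] = (C[:, 1:] - C[:, :-1]) / h   # backward difference
    dcdx_p[:, :-1] = (C[:, 1:] - C[:, :-1]) / h  # forward difference
    dcdy_m = np.zeros_like(C)
    dcdy_p = np.zeros_like(C)
    dcdy_m[1:, :] = (C[1:, :] - C[:-1, :]) / h
    dcdy_p[:-1, :] = (C[1:, :] - C[:-1, :]) / h
    adv = (np.where(vx > 0, vx * dcdx_m, vx * dcdx_p)
           + np.where(vy > 0, vy * dcdy_m, vy * dcdy_p))
    return C - dt * adv


class _ReactionPropagator:
    """Exact per-cell propagator of the local linear reaction system.

    The rate fields are constant in time, so the 3x3 system (plus the
    plasma forcing column) has a closed one-step solution via a 4x4 matrix
    exponential, precomputed once per cell; each step is then a 3x3
    matvec.  Cp is treated as constant over the step (callers pass the
    mid-step value for second-order accuracy).
    """

    def __init__(self, L: dict[str, np.ndarray], dt: float):
        from scipy.linalg import expm

        shape = L["L1"].shape
        ncell = int(np.prod(shape))
        flat = {k: np.broadcast_to(L[k], shape).reshape(ncell) for k in
                ("L1", "L2", "L3", "L4", "L5")}
        self.E = np.empty((ncell, 3, 3))
        self.S = np.empty((ncell, 3))
        M = np.zeros((4, 4))
        # cache: many cells share identical rate tuples (tumor/normal/no-vessel)
        seen: dict[tuple, tuple] = {}
        for k in range(ncell):
            key = tuple(flat[name][k] for name in ("L1", "L2", "L3", "L4", "L5"))
            hit = seen.get(key)
            if hit is None:
                l1, l2, l3, l4, l5 = key
                M[:] = 0.0
                M[0, 0] = -(l2 + l3)
                M[0, 1] = l4
                M[1, 0] = l3
                M[1, 1] = -(l4 + l5)
                M[2, 1] = l5
                M[0, 3] = l1
                E4 = expm(M * dt)
                hit = (E4[:3, :3].copy(), E4[:3, 3].copy())
                seen[key] = hit
            self.E[k] = hit[0]
            self.S[k] = hit[1]
        self.shape = shape

    def step(self, Ci, Ce, Cm, cp):
        y = np.stack([Ci.reshape(-1), Ce.reshape(-1), Cm.reshape(-1)], axis=1)
        out = np.einsum("kij,kj->ki", self.E, y) + self.S * cp
        return (out[:, 0].reshape(self.shape), out[:, 1].reshape(self.shape),
                out[:, 2].reshape(self.shape))


def step_sdm(state: ConcentrationState, vi: VectorField, cp_t: float,
             L: dict[str, np.ndarray], params: SDMParams, dt: float,
             diffusion: "_DiffusionSolver | None" = None,
             reaction: "_ReactionPropagator | None" = None) -> ConcentrationState:
    """One operator-split step: upwind advection -> implicit diffusion ->
    exact local reaction propagation.  ``cp_t`` is the plasma level over
    the step (mid-step value recommended).  Raises if the advection CFL
    contract is violated."""
    h = state.Ci.grid_spacing
    vmax = float(np.max(np.hypot(vi.vx, vi.vy)))
    if vmax * dt / h > 1.0:
        raise ValueError(
            f"advection CFL violated: v_max dt/h = {vmax * dt / h:.2f} > 1; "
            f"reduce dt below {h / vmax:.3g} s")
    Ci = _upwind_advect(state.Ci.values, vi.vx, vi.vy, h, dt)
    if diffusion is None and params.D_eff > 0:
        diffusion = _DiffusionSolver(Ci.shape[0], h, params.D_eff, dt)
    if diffusion is not None:
        Ci = diffusion.step(Ci)
    if reaction is None:
        reaction = _ReactionPropagator(L, dt)
    Ci_new, Ce_new, Cm_new = reaction.step(Ci, state.Ce.values,
                                           state.Cm.values, cp_t)
    tiny = -1e-12
    for arr in (Ci_new, Ce_new, Cm_new):
        low = float(arr.min())
        if low < tiny * max(1.0, float(np.abs(arr).max())):
            logger.warning("concentration undershoot %.3e clipped", low)
        np.clip(arr, 0.0, None, out=arr)
    mk = lambda v, name: ScalarField(v, h, "kBq/ml", name)
    return ConcentrationState(state.t + dt, mk(Ci_new, "c_i"),
                              mk(Ce_new, "c_e"), mk(Cm_new, "c_m"))


# --------------------------------------------------------------------------
# well-mixed 5K ODE reference
# --------------------------------------------------------------------------

def ode_5k_reference(cp, K: KineticConstants, duration_s: float,
                     times: np.ndarray | None = None) -> pd.DataFrame:
    """Well-mixed 4-compartment 5-rate model:

        dCi/dt = K1 Cp - (K2 + K3) Ci + K4 Ce
        dCe/dt = K3 Ci - (K4 + K5) Ce
        dCm/dt = K5 Ce

    integrated with a stiff-capable solver; returns a time-indexed frame.
    """
    from scipy.integrate import solve_ivp

    if times is None:
        times = np.linspace(0.0, duration_s, 361)

    A = np.array([
        [-(K.K2 + K.K3), K.K4, 0.0],
        [K.K3, -(K.K4 + K.K5), 0.0],
        [0.0, K.K5, 0.0],
    ])

    def rhs(t, y):
        return A @ y + np.array([K.K1 * float(cp(t)), 0.0, 0.0])

    sol = solve_ivp(rhs, (0.0, duration_s), np.zeros(3), t_eval=times,
                    method="LSODA", rtol=1e-9, atol=1e-12, max_step=10.0)
    if not sol.success:
        raise RuntimeError(f"5K ODE integration failed: {sol.message}")
    return pd.DataFrame({"time_s": sol.t, "Ci": sol.y[0], "Ce": sol.y[1],
                         "Cm": sol.y[2],
                         "Ctot": sol.y[0] + sol.y[1] + sol.y[2]})


# --------------------------------------------------------------------------
# full uptake simulation
# --------------------------------------------------------------------------

def simulate_uptake(domain: TissueDomain, ifp: IFPSolution,
                    aif: InputFunction, config: SimulationConfig,
                    store_frames: bool = True,
                    ) -> tuple[list[ConcentrationState], TimeActivityCurve, dict]:
    """Integrate the tracer PDEs over the configured duration.

    Returns frame snapshots (at the configured frame times), regional
    time-activity curves sampled every step, and diagnostics including the
    running mass-balance error |dM - dt sum(L1 Cp - L2 Ci)| / M.
    """
    sdm = config.sdm
    inter = config.interstitial
    n = domain.tumor_mask.shape[0]
    h = domain.grid_spacing
    L = rate_fields(domain, ifp, sdm, inter)
    dt = sdm.dt_s
    nsteps = int(round(sdm.duration_s / dt))
    diffusion = (_DiffusionSolver(n, h, sdm.D_eff, dt)
                 if sdm.D_eff > 0 else None)
    reaction = _ReactionPropagator(L, dt)
    mk = lambda v, name: ScalarField(v, h, "kBq/ml", name)
    state = ConcentrationState(0.0, mk(np.zeros((n, n)), "c_i"),
                               mk(np.zeros((n, n)), "c_e"),
                               mk(np.zeros((n, n)), "c_m"))
    tmask = domain.tumor_mask
    frames: list[ConcentrationState] = []
    frame_steps = {int(round(f / dt)) for f in sdm.frame_times_s
                   if 0 < f <= sdm.duration_s}
    rows = []
    max_balance_err = 0.0
    mass_prev = 0.0
    for k in range(nsteps):
        cp_t = float(aif((k + 0.5) * dt))  # mid-step plasma level
        ci_prev = state.Ci.values
        state = step_sdm(state, ifp.vi, cp_t, L, sdm, dt, diffusion, reaction)
        state.t = (k + 1) * dt  # avoid float accumulation drift
        mass = float((state.Ci.values + state.Ce.values + state.Cm.values).sum())
        # trapezoidal accounting of the plasma exchange over the step
        ci_mid = 0.5 * (ci_prev + state.Ci.values)
        exchange = float((dt * (L["L1"] * cp_t - L["L2"] * ci_mid)).sum())
        denom = max(mass, 1e-12)
        max_balance_err = max(max_balance_err,
                              abs(mass - mass_prev - exchange) / denom)
        mass_prev = mass
        row = {"time_s": state.t}
        for name, fld in (("ci", state.Ci), ("ce", state.Ce),
                          ("cm", state.Cm)):
            row[f"tumor_{name}"] = float(fld.values[tmask].mean())
            row[f"normal_{name}"] = float(fld.values[~tmask].mean())
        row["tumor_ctot"] = row["tumor_ci"] + row["tumor_ce"] + row["tumor_cm"]
        row["normal_ctot"] = (row["normal_ci"] + row["normal_ce"]
                              + row["normal_cm"])
        rows.append(row)
        if store_frames and (k + 1) in frame_steps:
            frames.append(state)
    tac = TimeActivityCurve(pd.DataFrame(rows))
    diagnostics = {"max_mass_balance_rel_err": max_balance_err,
                   "n_steps": nsteps}
    return frames, tac, diagnostics
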