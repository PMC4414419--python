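"""Per-cell IL-2 receptor dynamics.

Each non-secreting cell carries three pools: free surface receptors R_s,
surface cytokine/receptor complexes C, and an internalized receptor pool
R_i.  Receptor expression is induced by occupied receptors through a Hill
function (cooperativity from the multi-step IL-2R signal transduction):

    v(C) = v0 + v1 * C^n / (K^n + C^n)

and the pools exchange through binding (k_on, k_off), internalization of
free and bound receptor (k_iR, k_iC), recycling (k_rec) and degradation
(k_deg).  Internalized ligand is degraded, so the net cytokine uptake
flux handed back to the extracellular field is k_on c R_s - k_off C.

The positive feedback of uptake on receptor expression makes the cell
bistable in a window of ambient concentration: this hysteresis is what
turns graded cytokine exposure into an all-or-none activation decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import CellKineticParams, MOLEC_PER_UM3_PER_NM


@dataclass
class ReceptorState:
    """Pools of one cell (molecules/cell); all non-negative."""

    R_s: float = 100.0
    C: float = 0.0
    R_i: float = 0.0

    def __post_init__(self):
        if min(self.R_s, self.C, self.R_i) < 0:
            raise ValueError("receptor pools must be non-negative")

    @property
    def surface_total(self) -> float:
        return self.R_s + self.C

    def as_array(self) -> np.ndarray:
        return np.array([self.R_s, self.C, self.R_i], dtype=float)


def expression_rate(C, p: CellKineticParams):
    """Hill-type receptor expression rate v(C), molecules/cell/h."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("complex count must be non-negative")
    h = C ** p.hill_n / (p.K ** p.hill_n + C ** p.hill_n)
    return p.v0 + p.v1 * h


def cell_ode_rhs(state, c_surf_nM: float, p: CellKineticParams):
    """Time derivative of (R_s, C, R_i) at ambient concentration c_surf.

    ``c_surf_nM`` is the cytokine concentration at the cell surface in nM.
    Returns (dstate/dt, uptake) where uptake = k_on c R_s - k_off C is the
    net molecular flux (molecules/h) removed from the extracellular field.
    """
    if isinstance(state, ReceptorState):
        state = state.as_array()
    R_s, C, R_i = state
    if min(R_s, C, R_i) < 0 or c_surf_nM < 0:
        raise ValueError("negative state or concentration")
    bind = p.k_on * c_surf_nM * R_s
    v = expression_rate(C, p)
    dR_s = v - bind + p.k_off * C - p.k_iR * R_s + p.k_rec * R_i
    dC = bind - (p.k_off + p.k_iC) * C
    dR_i = p.k_iR * R_s + p.k_iC * C - (p.k_rec + p.k_deg) * R_i
    uptake = bind - p.k_off * C
    return np.array([dR_s, dC, dR_i]), uptake


def is_activated(state: ReceptorState | np.ndarray, threshold: float = 4000.0,
                 count: str = "surface_total") -> bool:
    """Activation flag: total surface receptor number strictly above the
    threshold (default 4000 molecules).  ``count='free'`` uses R_s only."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(state, ReceptorState):
        R_s, C = state.R_s, state.C
    else:
        R_s, C = state[0], state[1]
    total = R_s if count == "free" else R_s + C
    return bool(total > threshold)


def integrate_cell(state0, c_surf_nM: float, t_span_h: tuple[float, float],
                   p: CellKineticParams, rtol: float = 1e-8,
                   t_eval=None):
    """Integrate one cell at a held ambient concentration (oracle path)."""
    y0 = state0.as_array() if isinstance(state0, ReceptorState) else \
        np.asarray(state0, dtype=float)

    def rhs(t, y):
        return cell_ode_rhs(np.maximum(y, 0.0), c_surf_nM, p)[0]

    sol = solve_ivp(rhs, t_span_h, y0, method="LSODA", rtol=rtol,
                    atol=1e-10, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"cell ODE integration failed: {sol.message}")
    return sol


def steady_states(c_surf_nM: float, p: CellKineticParams,
                  R_max: float = 1e6) -> list[ReceptorState]:
    """All non-negative fixed points of the cell at a held concentration.

    At fixed c the system reduces to a scalar fixed-point problem in R_s:
    C* and R_i* are linear in R_s, so R_s* solves
    v(beta R_s) = gamma(c) R_s with
    beta = k_on c/(k_off + k_iC) and gamma collecting the linear losses.
    Between one and three solutions exist; three indicate bistability
    (outer two stable).
    """
    if c_surf_nM < 0:
        raise ValueError("concentration must be non-negative")
    beta = p.k_on * c_surf_nM / (p.k_off + p.k_iC)
    pool = (p.k_iR + p.k_iC * beta) / (p.k_rec + p.k_deg)
    gamma = (p.k_on * c_surf_nM - p.k_off * beta + p.k_iR
             - p.k_rec * pool)

    def g(R_s):
        return float(expression_rate(beta * R_s, p)) - gamma * R_s

    if gamma <= 0:
        return []  # unbounded growth; no finite steady state
    hi = max(R_max, 2 * (p.v0 + p.v1) / gamma)
    # log-spaced grid: the naive and induced fixed points differ by orders
    # of magnitude and can sit close together near the saddle node
    grid = np.concatenate([[0.0], np.geomspace(1e-2, hi, 3000)])
    vals = np.array([g(x) for x in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-10))
    states = []
    for R_s in roots:
        C = beta * R_s
        R_i = (p.k_iR * R_s + p.k_iC * C) / (p.k_rec + p.k_deg)
        states.append(ReceptorState(R_s=R_s, C=C, R_i=R_i))
    return states


def hysteresis_scan(p: CellKineticParams, c_grid_nM) -> dict:
    """Follow the stable steady state up and then down a concentration ramp.

    Returns the surface receptor number along both sweeps and the window of
    concentrations with three coexisting fixed points (bistable region).
    """
    c_grid_nM = np.asarray(c_grid_nM, dtype=float)
    up, down = [], []
    bistable = []
    state = None
    for c in c_grid_nM:
        ss = steady_states(c, p)
        if len(ss) >= 3:
            bistable.append(c)
        state = _follow(state, ss, branch="low")
        up.append(state)
    state = None
    for c in c_grid_nM[::-1]:
        ss = steady_states(c, p)
        state = _follow(state, ss, branch="high")
        down.append(state)
    down = down[::-1]
    return {
        "c_nM": c_grid_nM,
        "up_surface": np.array([s.surface_total for s in up]),
        "down_surface": np.array([s.surface_total for s in down]),
        "bistable_c_nM": np.array(bistable),
    }


def _follow(prev, ss, branch: str):
    if not ss:
        raise RuntimeError("no steady state found (gamma <= 0)")
    if len(ss) == 1:
        return ss[0]
    stable = [ss[0], ss[-1]]  # outer fixed points are the stable ones
    if prev is None:
        return stable[0] if branch == "low" else stable[-1]
    # continuation: keep the branch closest to the previous state
    d = [abs(s.surface_total - prev.surface_total) for s in stable]
    return stable[int(np.argmin(d))]


def nM_from_field(c_molec_um3: float) -> float:
    return c_molec_um3 / MOLEC_PER_UM3_PER_NM
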