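"""Scripted computational experiments on the tissue simulator.

These functions reproduce the headline population-scale analyses:
activation statistics of a dense Th culture, the all-or-none suppression
threshold imposed by regulatory T cells, the logarithmic scaling of the
paracrine signaling range with the effective secretion rate, and
bulk-versus-local concentration reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .geometry import (TissueGeometry, build_geometry, ROLE_SECRETOR,
                       ROLE_RESPONDER, ROLE_TREG)
from .params import ModelParams
from .tissue import SimConfig, Trajectory, run


def activation_summary(trajectory: Trajectory, threshold: float | None = None,
                       t_eval: float | None = None) -> dict:
    """Activated/total counts per role at time ``t_eval`` (default: end).

    A cell is activated when its total surface receptor number R_s + C
    exceeds the threshold (default 4000 molecules).
    """
    mask = trajectory.activated_mask(t_eval, threshold)
    roles = trajectory.geometry.roles
    out = {}
    for role in (ROLE_SECRETOR, ROLE_RESPONDER, ROLE_TREG):
        sel = roles == role
        if sel.any():
            out[role] = {"activated": int(mask[sel].sum()),
                         "total": int(sel.sum())}
    return out


@dataclass
class ScanResult:
    """Activation outcome of a parameter scan."""

    parameter: str
    values: np.ndarray
    seeds: np.ndarray
    activated_fraction: np.ndarray   # (n_values, n_seeds), responders
    activated_count: np.ndarray

    def mean_fraction(self) -> np.ndarray:
        return self.activated_fraction.mean(axis=1)


def treg_threshold_scan(q_eff_grid, seeds=(0,), *, lattice_dims=(6, 6, 6),
                        frac_secreting: float = 0.25, frac_treg: float = 0.25,
                        params: ModelParams = None, config: SimConfig = None,
                        refine: int = 0) -> tuple[ScanResult, float]:
    """Scan the effective secretion rate in a Th-Treg coculture.

    Returns the scan table and the estimated activation threshold: the
    midpoint between the largest q_eff with zero responder activation and
    the smallest with nonzero activation, optionally sharpened by up to
    ``refine`` bisection runs of the first seed (simulations are
    expensive, so the refinement budget is explicit).  With Tregs present
    the response is all-or-none; without them it is graded.
    """
    params = params or ModelParams()
    config = config or SimConfig()
    q_eff_grid = np.sort(np.asarray(q_eff_grid, dtype=float))
    seeds = np.asarray(seeds, dtype=int)

    def run_one(q, seed):
        geom = build_geometry(lattice_dims, frac_secreting, frac_treg,
                              cell_radius=params.rho,
                              cell_spacing=params.L_cell, seed=int(seed))
        cfg = SimConfig(**{**config.__dict__, "q_eff": float(q)})
        summ = activation_summary(run(geom, params, cfg))
        return summ.get(ROLE_RESPONDER, {"activated": 0, "total": 1})

    frac = np.zeros((len(q_eff_grid), len(seeds)))
    count = np.zeros_like(frac, dtype=int)
    for i, q in enumerate(q_eff_grid):
        for j, seed in enumerate(seeds):
            resp = run_one(q, seed)
            count[i, j] = resp["activated"]
            frac[i, j] = resp["activated"] / resp["total"]
    mean = frac.mean(axis=1)
    if np.any(np.diff(mean) < -0.05):
        warnings.warn("activation not monotone in q_eff across the grid",
                      RuntimeWarning)
    zero = np.flatnonzero(mean == 0)
    nonzero = np.flatnonzero(mean > 0)
    if len(zero) and len(nonzero) and nonzero.min() > 0:
        lo = q_eff_grid[zero.max()]
        hi = q_eff_grid[nonzero[nonzero > zero.max()].min()]
        for _ in range(refine):
            mid = 0.5 * (lo + hi)
            resp = run_one(mid, seeds[0])
            if resp["activated"] > 0:
                hi = mid
            else:
                lo = mid
        threshold = 0.5 * (lo + hi)
    elif len(nonzero) and nonzero.min() == 0:
        threshold = q_eff_grid[0] / 2.0   # already active at the bottom
    else:
        threshold = np.inf                # never active on this grid
    result = ScanResult(parameter="q_eff", values=q_eff_grid, seeds=seeds,
                        activated_fraction=frac, activated_count=count)
    return result, float(threshold)


@dataclass
class RangeFit:
    """Least-squares fit of signal range = a ln(q_eff/x0)."""

    a: float
    x0: float
    q_eff: np.ndarray
    ranges: np.ndarray      # most-distant activated cell, pitch units
    residuals: np.ndarray

    def __call__(self, q):
        return self.a * np.log(np.asarray(q, dtype=float) / self.x0)


def fit_log_range(q_eff, ranges) -> RangeFit:
    """Fit f(x) = a ln(x/x0) to (secretion rate, signal range) pairs.

    Only strictly positive ranges participate (a range of zero means no
    cell was activated, which the logarithm cannot represent).
    """
    q_eff = np.asarray(q_eff, dtype=float)
    ranges = np.asarray(ranges, dtype=float)
    ok = ranges > 0
    if ok.sum() < 2:
        raise ValueError("need at least two nonzero ranges to fit")
    # linear in ln q: r = a ln q - a ln x0
    coef = np.polyfit(np.log(q_eff[ok]), ranges[ok], 1)
    a0, b0 = coef[0], coef[1]
    x0_0 = np.exp(-b0 / a0) if a0 != 0 else 1.0

    def f(x, a, x0):
        return a * np.log(x / x0)

    popt, _ = curve_fit(f, q_eff[ok], ranges[ok], p0=(a0, x0_0))
    res = ranges[ok] - f(q_eff[ok], *popt)
    return RangeFit(a=float(popt[0]), x0=float(abs(popt[1])),
                    q_eff=q_eff[ok], ranges=ranges[ok], residuals=res)


def signal_range(trajectory: Trajectory, threshold: float | None = None
                 ) -> float:
    """Distance from the domain center to the most distant activated cell,
    in center-to-center cell distances (the paracrine signal range)."""
    geom = trajectory.geometry
    mask = trajectory.activated_mask(None, threshold)
    if not mask.any():
        return 0.0
    center = geom.domain_size / 2.0
    d = np.linalg.norm(geom.centers - center, axis=1)
    return float(d[mask].max() / geom.pitch)


def range_scan(q_eff_grid, *, lattice_dims=(13, 13, 13),
               params: ModelParams = None, config: SimConfig = None,
               seed: int = 0) -> tuple[dict, RangeFit | None]:
    """Single-central-secretor runs over a grid of secretion rates.

    Returns per-q_eff activated counts and signal ranges plus the
    logarithmic fit over the nonzero ranges (None, with a notice, if
    nothing activated anywhere).
    """
    params = params or ModelParams()
    config = config or SimConfig()
    q_eff_grid = np.sort(np.asarray(q_eff_grid, dtype=float))
    counts, ranges, trajs = [], [], []
    for q in q_eff_grid:
        geom = build_geometry(lattice_dims, single_central_secretor=True,
                              cell_radius=params.rho,
                              cell_spacing=params.L_cell, seed=seed)
        cfg = SimConfig(**{**config.__dict__, "q_eff": float(q)})
        traj = run(geom, params, cfg)
        summ = activation_summary(traj)
        counts.append(summ.get(ROLE_RESPONDER, {"activated": 0})["activated"])
        ranges.append(signal_range(traj))
        trajs.append(traj)
    table = {"q_eff": q_eff_grid, "activated": np.array(counts),
             "range_cells": np.array(ranges)}
    try:
        fit = fit_log_range(q_eff_grid, np.array(ranges))
    except ValueError:
        warnings.warn("no activation anywhere on the grid; log fit skipped",
                      RuntimeWarning)
        fit = None
    return table, fit


def bulk_vs_local_report(trajectory: Trajectory) -> dict:
    """Volume-averaged vs. cell-surface concentrations over time.

    Reports the bulk time course, its peak time, the final per-cell
    surface averages and the ratio of the largest local surface
    concentration to the bulk value (spatial-gradient strength).
    """
    bulk = trajectory.bulk_nM
    times = trajectory.times
    local_final = trajectory.c_surf_nM[-1]
    bulk_final = float(bulk[-1])
    ratio = float(np.nanmax(local_final) / bulk_final) if bulk_final > 0 \
        else 1.0
    return {
        "times_h": times,
        "bulk_nM": bulk,
        "bulk_final_pM": bulk_final * 1e3,
        "peak_time_h": float(times[int(np.argmax(bulk))]),
        "surface_final_nM": local_final,
        "local_over_bulk_max": ratio,
    }
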