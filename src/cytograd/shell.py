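"""Radially symmetric secretion/uptake around a single secreting cell.

A cytokine-secreting cell of radius ``rho`` releases ``q`` molecules/s
homogeneously over its surface.  At steady state the extracellular
concentration obeys the Laplace equation, so c(r) = A/r + B.  Two
scenarios are solved in closed form:

``low_density``
    responder cells are far away; c vanishes at infinity (B = 0).
``high_density``
    N responder cells with ``R_resp`` receptors each sit on a concentric
    shell at surface-to-surface distance L and absorb the outward flux
    through a Robin condition.

The secreted flux partitions into autocrine recapture
J_auto = k_on c(rho) R and the paracrine remainder J_para = q - J_auto.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .params import ModelParams


@dataclass(frozen=True)
class ShellScenario:
    """Geometry and receptor configuration of the shell model."""

    regime: Literal["low_density", "high_density"] = "high_density"
    rho: float = 5.0          # secreting-cell radius, um
    L: float = 5.0            # shell gap (surface to surface), um
    R: float = 4000.0         # receptors on the secreting cell
    R_resp: float = 100.0     # receptors per responder cell
    N: int = 12               # responder cells on the shell
    q: float = 10.0           # secretion rate, molecules/s
    D: float = 10.0           # um^2/s
    k_on_um3_s: float = ModelParams().k_on_um3_per_s  # um^3/(molecule s)

    @classmethod
    def from_params(cls, params: ModelParams, **kwargs) -> "ShellScenario":
        base = dict(rho=params.rho, L=params.L_cell, q=params.q, D=params.D,
                    k_on_um3_s=params.k_on_um3_per_s)
        base.update(kwargs)
        return cls(**base)

    def __post_init__(self):
        if self.rho <= 0 or self.q < 0 or self.D <= 0:
            raise ValueError("rho and D must be positive, q non-negative")
        if self.R < 0 or self.R_resp < 0:
            raise ValueError("receptor numbers must be non-negative")
        if self.regime == "high_density":
            if self.L <= 0:
                raise ValueError("high_density scenario requires L > 0")
            if self.N < 1:
                raise ValueError("high_density scenario requires N >= 1")


@dataclass(frozen=True)
class RadialProfile:
    """Steady-state profile c(r) = A/r + B (molecules/um^3)."""

    A: float
    B: float
    r_min: float
    r_max: float  # inf for the low-density scenario

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r < self.r_min - 1e-12) or np.any(r > self.r_max + 1e-12):
            raise ValueError("radius outside the profile domain")
        return self.A / r + self.B


@dataclass(frozen=True)
class FluxBreakdown:
    """Partition of the secreted flux (molecules/s); unused entries None."""

    q: float
    J_auto: float
    J_para: float | None = None
    J_synapse: float | None = None
    J_escape: float | None = None

    @property
    def fractions(self) -> dict:
        out = {}
        for name in ("J_auto", "J_para", "J_synapse", "J_escape"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v / self.q if self.q > 0 else 0.0
        return out

    def to_dict(self) -> dict:
        d = {"q": self.q, "J_auto": self.J_auto, "J_para": self.J_para,
             "J_synapse": self.J_synapse, "J_escape": self.J_escape}
        d["fractions"] = self.fractions
        return d


def solve_shell(sc: ShellScenario) -> tuple[RadialProfile, FluxBreakdown]:
    """Closed-form steady state of the shell boundary-value problem.

    Inner boundary (secreting cell surface, r = rho):
        -4 pi rho^2 D c'(rho) = q - k_on c(rho) R
    Outer boundary: c -> 0 (low density) or Robin uptake by the N
    responder cells at r = rho + L (high density).
    """
    kon, D, rho, q = sc.k_on_um3_s, sc.D, sc.rho, sc.q
    if sc.regime == "low_density":
        # c = A/r; inner BC: 4 pi D A = q - kon R A / rho
        A = q / (4.0 * math.pi * D + kon * sc.R / rho)
        B = 0.0
        r_max = math.inf
    else:
        # c = A/r + B on [rho, rho+L]; flux through any shell is 4 pi D A.
        # inner: 4 pi D A = q - kon R (A/rho + B)
        # outer: 4 pi D A = kon N R_resp (A/(rho+L) + B)
        rL = rho + sc.L
        g_in = kon * sc.R
        g_out = kon * sc.N * sc.R_resp
        M = np.array([
            [4.0 * math.pi * D + g_in / rho, g_in],
            [4.0 * math.pi * D - g_out / rL, -g_out],
        ])
        rhs = np.array([q, 0.0])
        if abs(np.linalg.det(M)) < 1e-300:
            raise ValueError("degenerate shell scenario: no steady state "
                             "(no receptors anywhere)")
        A, B = np.linalg.solve(M, rhs)
        r_max = rL
    profile = RadialProfile(A=float(A), B=float(B), r_min=rho, r_max=r_max)
    J_auto = kon * sc.R * profile(rho)
    flux = FluxBreakdown(q=q, J_auto=float(J_auto), J_para=float(q - J_auto))
    return profile, flux


def fast_diffusion_limit(sc: ShellScenario) -> FluxBreakdown:
    """Flux partition in the well-mixed (infinitely fast diffusion) limit.

    With a spatially uniform concentration the partition is set purely by
    the receptor numbers: J_auto = q R/(R + N R_resp).
    """
    if sc.regime != "high_density":
        raise ValueError("fast-diffusion limit applies to the high_density "
                         "scenario")
    total = sc.R + sc.N * sc.R_resp
    if total <= 0:
        raise ValueError("no receptors: no steady state exists in the "
                         "fast-diffusion limit")
    J_auto = sc.q * sc.R / total
    return FluxBreakdown(q=sc.q, J_auto=J_auto, J_para=sc.q - J_auto)


def solve_shell_fd(sc: ShellScenario, n: int = 20000) -> RadialProfile:
    """Independent finite-difference oracle for the shell problem.

    Solves the spherically symmetric Laplace problem on a fine radial grid
    with the same boundary conditions and returns an equivalent A/r + B
    profile fitted through the two endpoint values.  For the low-density
    scenario the outer boundary at R_far carries the exact decay condition
    c'(R_far) + c(R_far)/R_far = 0, so no truncation error is introduced.
    """
    kon, D, rho = sc.k_on_um3_s, sc.D, sc.rho
    if sc.regime == "low_density":
        # the decay condition at r_out is exact for A/r solutions, so a
        # short domain costs no truncation error and buys resolution
        r_out = 4.0 * rho
    else:
        r_out = rho + sc.L
    r = np.linspace(rho, r_out, n)
    h = r[1] - r[0]
    # discretize (r^2 c')' = 0 with second-order central differences
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    rhs = np.zeros(n)
    rp = (r[:-1] + r[1:]) / 2.0  # midpoints
    for i in range(1, n - 1):
        wl = rp[i - 1] ** 2 / h
        wu = rp[i] ** 2 / h
        lower[i - 1] = wl
        upper[i] = wu
        main[i] = -(wl + wu)
    # inner Robin BC via ghost flux: -4 pi rho^2 D c'(rho) = q - kon R c
    #   c'(rho) ~ (c1 - c0)/h  (first order is enough on this fine grid;
    #   use second-order one-sided for accuracy)
    main[0] = -4.0 * math.pi * rho ** 2 * D * (-3.0 / (2 * h)) + kon * sc.R
    upper[0] = -4.0 * math.pi * rho ** 2 * D * (4.0 / (2 * h))
    rhs[0] = sc.q
    # need the c2 term of the one-sided stencil: fold into a dense row fix
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla
    Amat = sp.diags([lower, main, upper], [-1, 0, 1], format="lil")
    Amat[0, 2] = -4.0 * math.pi * rho ** 2 * D * (-1.0 / (2 * h))
    if sc.regime == "low_density":
        # c' + c/r = 0 at r_out, second-order one-sided
        Amat[n - 1, n - 1] = 3.0 / (2 * h) + 1.0 / r_out
        Amat[n - 1, n - 2] = -4.0 / (2 * h)
        Amat[n - 1, n - 3] = 1.0 / (2 * h)
        rhs[n - 1] = 0.0
    else:
        g_out = kon * sc.N * sc.R_resp
        rL = r_out
        Amat[n - 1, n - 1] = -4.0 * math.pi * rL ** 2 * D * (3.0 / (2 * h)) \
            - g_out
        Amat[n - 1, n - 2] = -4.0 * math.pi * rL ** 2 * D * (-4.0 / (2 * h))
        Amat[n - 1, n - 3] = -4.0 * math.pi * rL ** 2 * D * (1.0 / (2 * h))
        rhs[n - 1] = 0.0
    c = spla.spsolve(Amat.tocsr(), rhs)
    # recover A, B from the endpoints of the numerical solution
    c0, c1 = c[0], c[-1]
    if sc.regime == "low_density":
        A = c0 * rho
        B = 0.0
    else:
        A = (c0 - c1) / (1.0 / rho - 1.0 / r_out)
        B = c0 - A / rho
    return RadialProfile(A=float(A), B=float(B), r_min=rho,
                         r_max=math.inf if sc.regime == "low_density"
                         else r_out)
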