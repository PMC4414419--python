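"""Steady-state cytokine diffusion in the immunological-synapse cleft.

The synapse is a cylinder of radius ``a`` (contact area) and height ``l``
(synaptic distance, 20 nm for a tight synapse).  The secreting cell forms
the z=0 face, the opposed cell the z=l face; the rim r=a is open and
absorbing (molecules that leave do not return).  Secretion (q) and
receptor uptake (k_on R c) act on the faces; both are expressed as uniform
flux densities over the contact discs, q/(pi a^2) and k_on R c/(pi a^2),
which makes the Robin coefficients independent of r so that each Bessel
mode decouples:

    c(r, z) = sum_n f_n(z) J0(alpha_n r / a),   J0(alpha_n) = 0.

The axial profiles f_n are combinations of exp(-k_n z) and
exp(-k_n (l - z)) with k_n = alpha_n / a, evaluated in this scaled form so
that the extreme aspect ratio of a tight synapse (a/l = 100) never
overflows the hyperbolic functions.

The secreted flux partitions into autocrine recapture (J_auto, z=0 disc),
synaptic transfer (J_synapse, z=l disc) and rim escape (J_escape), with
J_auto + J_synapse + J_escape = q.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import jn_zeros, j0, j1

from .params import ModelParams, MOLEC_PER_UM3_PER_NM
from .shell import FluxBreakdown


@dataclass(frozen=True)
class SynapseScenario:
    """Geometry and receptor configuration of one synapse."""

    a: float = 2.0            # contact radius, um
    l: float = 0.02           # cleft height, um (20 nm tight synapse)
    R: float = 100.0          # receptors on the secreting face
    R_resp: float = 100.0     # receptors on the opposed face
    q: float = 10.0           # secretion rate, molecules/s
    D: float = 10.0           # um^2/s
    k_on_um3_s: float = ModelParams().k_on_um3_per_s
    n_modes: int = 200

    @classmethod
    def from_params(cls, params: ModelParams, **kwargs) -> "SynapseScenario":
        base = dict(a=params.a, l=params.l_syn, q=params.q, D=params.D,
                    k_on_um3_s=params.k_on_um3_per_s)
        base.update(kwargs)
        return cls(**base)

    def __post_init__(self):
        if self.a <= 0 or self.l <= 0:
            raise ValueError("a and l must be positive")
        if self.R < 0 or self.R_resp < 0:
            raise ValueError("receptor numbers must be non-negative")
        if self.q < 0 or self.D <= 0:
            raise ValueError("q must be non-negative, D positive")
        if self.n_modes < 10:
            raise ValueError("n_modes must be >= 10")


@dataclass(frozen=True)
class CylinderField:
    """Bessel-mode representation of the steady concentration field.

    Mode n is ``P[n] exp(-k[n] z) + Q[n] exp(-k[n](l-z))`` times
    ``J0(alpha[n] r/a)``; amplitudes carry molecules/um^3.
    """

    scenario: SynapseScenario
    alpha: np.ndarray  # positive roots of J0
    P: np.ndarray
    Q: np.ndarray

    @property
    def k(self) -> np.ndarray:
        return self.alpha / self.scenario.a

    def f(self, z) -> np.ndarray:
        """Axial mode profiles at height(s) z; shape (n_modes,) + z.shape."""
        z = np.asarray(z, dtype=float)
        k = self.k.reshape((-1,) + (1,) * z.ndim)
        P = self.P.reshape(k.shape)
        Q = self.Q.reshape(k.shape)
        l = self.scenario.l
        return P * np.exp(-k * z) + Q * np.exp(-k * (l - z))

    def __call__(self, r, z):
        """Concentration (molecules/um^3) at broadcastable (r, z)."""
        r, z = np.broadcast_arrays(np.asarray(r, dtype=float),
                                   np.asarray(z, dtype=float))
        radial = j0(np.multiply.outer(self.alpha / self.scenario.a, r))
        return np.sum(self.f(z) * radial, axis=0)

    def concentration_nM(self, r, z):
        return self(r, z) / MOLEC_PER_UM3_PER_NM


def _solve_modes(sc: SynapseScenario, n_modes: int):
    a, l, D = sc.a, sc.l, sc.D
    area = math.pi * a ** 2
    sigma = sc.q / area                        # molecules/(um^2 s)
    g0 = sc.k_on_um3_s * sc.R / area           # um/s
    gl = sc.k_on_um3_s * sc.R_resp / area
    alpha = jn_zeros(0, n_modes)
    k = alpha / a
    e = np.exp(-k * l)
    sigma_n = sigma * 2.0 / (alpha * j1(alpha))
    # z=l uptake condition fixes Q/P; z=0 source condition fixes the scale.
    ratio = e * (D * k - gl) / (D * k + gl)    # Q = ratio * P
    denom = (D * k + g0) + (g0 - D * k) * e * ratio
    P = sigma_n / denom
    Q = ratio * P
    return alpha, P, Q


def solve_synapse(sc: SynapseScenario) -> CylinderField:
    """Solve the cylinder boundary-value problem by Bessel-mode expansion.

    The truncation order is doubled (up to 8x) until the escape flux is
    stable to 1e-4 relative; a warning with diagnostics is emitted if that
    never happens.
    """
    n = sc.n_modes
    field = CylinderField(sc, *_solve_modes(sc, n))
    J_prev = flux_breakdown(field, check=False).J_escape
    for _ in range(3):
        n *= 2
        field2 = CylinderField(sc, *_solve_modes(sc, n))
        J_new = flux_breakdown(field2, check=False).J_escape
        scale = max(abs(J_new), sc.q, 1e-300)
        if abs(J_new - J_prev) / scale < 1e-4:
            return field2
        field, J_prev = field2, J_new
    warnings.warn(
        f"synapse mode expansion not converged at n_modes={n}: "
        f"relative escape-flux change {abs(J_new - J_prev) / scale:.2e}",
        RuntimeWarning)
    return field


def flux_breakdown(field: CylinderField, scenario: SynapseScenario = None,
                   check: bool = True) -> FluxBreakdown:
    """Integrate the face and rim fluxes of a solved synapse field.

    J_auto and J_synapse are the receptor uptake integrals over the two
    discs, J_escape the diffusive outflux through the rim.  Conservation
    J_auto + J_synapse + J_escape = q is asserted to 1e-6 relative when
    ``check`` is true.
    """
    sc = scenario or field.scenario
    a, l, D, q = sc.a, sc.l, sc.D, sc.q
    area = math.pi * a ** 2
    g0 = sc.k_on_um3_s * sc.R / area
    gl = sc.k_on_um3_s * sc.R_resp / area
    alpha, P, Q, k = field.alpha, field.P, field.Q, field.k
    e = np.exp(-k * l)
    disc = 2.0 * math.pi * a ** 2 * j1(alpha) / alpha  # integral of J0 mode
    f0 = P + Q * e
    fl = P * e + Q
    J_auto = float(g0 * np.sum(f0 * disc))
    J_syn = float(gl * np.sum(fl * disc))
    # rim outflux: -D dc/dr at r=a integrated over the rim surface
    int_f = (P + Q) * (1.0 - e) / k
    J_escape = float(2.0 * math.pi * a * D * np.sum(j1(alpha) * k * int_f))
    # analytic tail: the truncated Bessel projection of the uniform source
    # integrates to q_N = 4 q sum(1/alpha_n^2) < q (Rayleigh sum -> 1/4).
    # High modes are neither absorbed at the discs (uptake ~ g/(D k_n) -> 0)
    # nor attenuated before the rim, so the missing source escapes.
    J_escape += q * float(1.0 - 4.0 * np.sum(1.0 / alpha ** 2))
    if check and q > 0:
        balance = abs(J_auto + J_syn + J_escape - q) / q
        if balance > 1e-6:
            raise ArithmeticError(
                f"synapse flux conservation violated: |sum - q|/q = "
                f"{balance:.2e} (truncation or quadrature bug)")
    return FluxBreakdown(q=q, J_auto=J_auto, J_synapse=J_syn,
                         J_escape=J_escape)


def effective_secretion_rate(sc: SynapseScenario) -> float:
    """Escape flux of the synapse in molecules/h (the q_eff used as the
    polarized source strength of tissue-scale simulations)."""
    flux = flux_breakdown(solve_synapse(sc))
    return flux.J_escape * 3600.0


def solve_synapse_fd(sc: SynapseScenario, nr: int = 400, nz: int = 60
                     ) -> FluxBreakdown:
    """Independent axisymmetric finite-difference oracle.

    Discretizes the (r, z) Laplace problem with the same boundary
    conditions on a tensor grid (cell-centered in r to handle the axis,
    vertex-centered in z) and integrates the same three fluxes.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    a, l, D = sc.a, sc.l, sc.D
    area = math.pi * a ** 2
    sigma = sc.q / area
    g0 = sc.k_on_um3_s * sc.R / area
    gl = sc.k_on_um3_s * sc.R_resp / area
    dr = a / nr
    dz = l / nz
    r = (np.arange(nr) + 0.5) * dr             # cell centers in r
    z = np.arange(nz + 1) * dz                 # vertices in z
    NZ = nz + 1

    def idx(i, jz):
        return i * NZ + jz

    rows, cols, vals = [], [], []
    rhs = np.zeros(nr * NZ)

    r_faces = np.arange(nr + 1) * dr           # radial faces
    for i in range(nr):
        # radial FV weights: (1/r)(r c_r)_r -> face areas r_face
        rw_in = r_faces[i] / (r[i] * dr * dr)
        rw_out = r_faces[i + 1] / (r[i] * dr * dr)
        for jz in range(NZ):
            me = idx(i, jz)
            diag = 0.0
            if i > 0:
                rows.append(me); cols.append(idx(i - 1, jz)); vals.append(rw_in)
                diag -= rw_in
            # i == 0: axis, zero flux, nothing to add
            if i < nr - 1:
                rows.append(me); cols.append(idx(i + 1, jz)); vals.append(rw_out)
                diag -= rw_out
            else:
                # Dirichlet rim c(a, z) = 0 via ghost value -c
                diag -= 2.0 * rw_out
            if 0 < jz < nz:
                rows.append(me); cols.append(idx(i, jz - 1)); vals.append(1.0 / dz ** 2)
                rows.append(me); cols.append(idx(i, jz + 1)); vals.append(1.0 / dz ** 2)
                diag -= 2.0 / dz ** 2
            elif jz == 0:
                # Robin: -D c_z = sigma - g0 c  => ghost elimination
                rows.append(me); cols.append(idx(i, jz + 1)); vals.append(2.0 / dz ** 2)
                diag -= 2.0 / dz ** 2
                diag -= 2.0 * g0 / (D * dz)
                rhs[me] = -2.0 * sigma / (D * dz)
            else:
                # Robin: -D c_z = gl c at z=l
                rows.append(me); cols.append(idx(i, jz - 1)); vals.append(2.0 / dz ** 2)
                diag -= 2.0 / dz ** 2
                diag -= 2.0 * gl / (D * dz)
            rows.append(me); cols.append(me); vals.append(diag)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(nr * NZ, nr * NZ))
    c = spla.spsolve(A, rhs).reshape(nr, NZ)

    ring = 2.0 * math.pi * r * dr              # annulus areas
    J_auto = g0 * float(np.sum(c[:, 0] * ring))
    J_syn = gl * float(np.sum(c[:, nz] * ring))
    J_escape = sc.q - J_auto - J_syn
    return FluxBreakdown(q=sc.q, J_auto=J_auto, J_synapse=J_syn,
                         J_escape=J_escape)
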