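"""Physical parameters, units, and the Berg-Purcell encounter time.

All model modules draw their physical constants from :class:`ModelParams`,
which defaults to the experimentally established IL-2 parameter set
(diffusion constant, secretion rate, binding rate, receptor numbers and
expression rates for helper and regulatory T cells).

Unit conventions
----------------
Lengths are in micrometers, times in the unit stated per field (rates per
hour for cell biology, seconds for diffusion), receptor quantities in
molecules per cell.  Extracellular concentrations are handled internally in
molecules/um^3; conversion to molar units uses the exact Avogadro constant:

    1 nM = 1e-9 * N_A molecules / (1e15 um^3) = 0.6022... molecules/um^3
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

#: exact CODATA Avogadro constant (1/mol)
N_AVOGADRO = 6.02214076e23

#: molecules/um^3 corresponding to 1 nM (the paper rounds this to 6/10)
MOLEC_PER_UM3_PER_NM = N_AVOGADRO * 1e-9 / 1e15  # = 0.602214076

_CONC_FACTORS = {
    # factor converting 1 unit -> molecules/um^3
    "molecules/um3": 1.0,
    "nM": MOLEC_PER_UM3_PER_NM,
    "pM": MOLEC_PER_UM3_PER_NM * 1e-3,
}
# accept common spelling variants
_CONC_ALIASES = {
    "molecules/μm³": "molecules/um3",
    "molecules/um^3": "molecules/um3",
    "nm": "nM",
    "pm": "pM",
}


def _canonical_unit(unit: str) -> str:
    u = _CONC_ALIASES.get(unit, unit)
    u = _CONC_ALIASES.get(u.lower(), u) if u not in _CONC_FACTORS else u
    if u not in _CONC_FACTORS:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(_CONC_FACTORS)}"
        )
    return u


def concentration_convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a concentration between nM, pM and molecules/um^3.

    Uses the exact Avogadro factor, so round trips are identity to floating
    precision.  ``value`` must be non-negative.
    """
    if value < 0:
        raise ValueError(f"concentration must be non-negative, got {value}")
    f = _CONC_FACTORS[_canonical_unit(from_unit)]
    t = _CONC_FACTORS[_canonical_unit(to_unit)]
    return value * f / t


@dataclass(frozen=True)
class CellKineticParams:
    """Receptor expression and trafficking rates of one cell type.

    ``v0``/``v1`` are the basal and cytokine-induced receptor expression
    rates (molecules/cell/h), ``K`` the half-saturation constant of the
    Hill-type induction (complexes/cell), ``hill_n`` its Hill coefficient.
    ``k_on`` is in 1/(nM h); all other rates are first order in 1/h.
    """

    v0: float = 150.0
    v1: float = 3000.0
    K: float = 1000.0
    hill_n: float = 3.0
    k_on: float = 111.6
    k_off: float = 0.83
    k_iR: float = 1.6
    k_iC: float = 2.9
    k_rec: float = 5.0
    k_deg: float = 1.0

    def __post_init__(self):
        for name in ("v0", "v1", "K", "k_on", "k_off", "k_iR", "k_iC",
                     "k_rec", "k_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")


#: presets per Table-1 expression rates; trafficking defaults shared
TH_RESPONDER = CellKineticParams(v0=150.0, v1=3000.0)
TREG = CellKineticParams(v0=1000.0, v1=8000.0)


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the IL-2 signaling model.

    Defaults are the published values for IL-2 in dense T-cell environments;
    trafficking rates (``k_off`` ... ``k_deg``) follow the experimentally
    calibrated IL-2R trafficking literature and are deliberately explicit
    fields so that any study can override them.
    """

    D: float = 10.0            # diffusion coefficient, um^2/s
    rho: float = 5.0           # cell radius, um
    L_cell: float = 5.0        # surface-to-surface cell distance, um
    q: float = 10.0            # secretion rate, molecules/s
    q_eff: float = 7200.0      # effective (post-synapse) secretion, molecules/h
    k_on: float = 111.6        # association rate, 1/(nM h)
    k_off: float = 0.83        # dissociation rate, 1/h
    k_d: float = 0.1           # extracellular degradation, 1/h
    a: float = 2.0             # synapse contact radius, um
    l_syn: float = 0.02        # synaptic distance, um (20 nm)
    R_low: float = 100.0       # basal IL-2R number, molecules/cell
    R_high: float = 4000.0     # upregulated IL-2R number, molecules/cell
    frac_secreting: float = 0.25
    v0_Th: float = 150.0       # molecules/cell/h
    v0_Treg: float = 1000.0
    v1_Th: float = 3000.0
    v1_Treg: float = 8000.0
    K: float = 1000.0          # half-saturation, complexes/cell
    hill_n: float = 3.0
    k_iR: float = 1.6         # free-receptor internalization, 1/h
    k_iC: float = 2.9          # complex internalization, 1/h
    k_rec: float = 5.0         # receptor recycling, 1/h
    k_deg: float = 1.0         # internalized receptor degradation, 1/h
    d_R: float = 1e-4          # receptor diameter, um (0.1 nm)

    def __post_init__(self):
        positive = ("D", "rho", "L_cell", "q", "k_on", "a", "l_syn", "d_R")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        nonneg = ("q_eff", "k_off", "k_d", "R_low", "R_high", "v0_Th",
                  "v0_Treg", "v1_Th", "v1_Treg", "K", "k_iR", "k_iC",
                  "k_rec", "k_deg")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.frac_secreting <= 1.0:
            raise ValueError("frac_secreting must lie in [0, 1]")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")

    # -- unit helpers ---------------------------------------------------
    @property
    def k_on_um3_per_s(self) -> float:
        """k_on expressed in um^3/(molecule s) for molecules/um^3 fields."""
        return self.k_on / MOLEC_PER_UM3_PER_NM / 3600.0

    @property
    def k_on_um3_per_h(self) -> float:
        return self.k_on / MOLEC_PER_UM3_PER_NM

    @property
    def D_um2_per_h(self) -> float:
        return self.D * 3600.0

    def kinetics(self, cell_type: str) -> CellKineticParams:
        """Kinetic preset for ``'responder_th'`` or ``'treg'`` cells."""
        common = dict(K=self.K, hill_n=self.hill_n, k_on=self.k_on,
                      k_off=self.k_off, k_iR=self.k_iR, k_iC=self.k_iC,
                      k_rec=self.k_rec, k_deg=self.k_deg)
        key = cell_type.lower()
        if key in ("responder_th", "th", "responder"):
            return CellKineticParams(v0=self.v0_Th, v1=self.v1_Th, **common)
        if key == "treg":
            return CellKineticParams(v0=self.v0_Treg, v1=self.v1_Treg, **common)
        raise ValueError(f"unknown cell type {cell_type!r}")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)


def load_kinetics_preset(cell_type: str) -> CellKineticParams:
    """Load a bundled kinetic preset (``responder_th`` or ``treg``) from
    the shipped YAML file."""
    import importlib.resources as res
    with res.as_file(res.files("cytograd") / "data" /
                     "kinetics_presets.yaml") as f:
        presets = yaml.safe_load(Path(f).read_text())
    key = cell_type.lower()
    if key not in presets:
        raise ValueError(f"unknown kinetic preset {cell_type!r}; available: "
                         f"{sorted(presets)}")
    return CellKineticParams(**presets[key])


def berg_purcell_time(c: float, R: float, params: ModelParams | None = None,
                      c_unit: str = "pM") -> float:
    """Characteristic time (s) for a ligand to find a cell-surface receptor.

    The classical two-stage estimate: diffusion to the cell of radius rho,
    then search for one of R receptor patches of diameter d_R,

        tau = 1/(4 pi D rho c) + 1/(4 D d_R R c),

    with c converted to molecules/um^3.  Diverges as c or R approach zero.
    """
    if params is None:
        params = ModelParams()
    if c <= 0:
        raise ValueError("encounter time is infinite for c <= 0")
    if R <= 0:
        raise ValueError("encounter time is infinite for R <= 0")
    c3 = concentration_convert(c, c_unit, "molecules/um3")
    t_cell = 1.0 / (4.0 * math.pi * params.D * params.rho * c3)
    t_receptor = 1.0 / (4.0 * params.D * params.d_R * R * c3)
    return t_cell + t_receptor


def fast_diffusion_range_cells(params: ModelParams | None = None) -> float:
    """Spatial range of fast diffusion sqrt(D/k_d), in center-to-center
    cell distances (2 rho + L_cell)."""
    if params is None:
        params = ModelParams()
    lam = math.sqrt(params.D_um2_per_h / params.k_d)  # um
    return lam / (2.0 * params.rho + params.L_cell)
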