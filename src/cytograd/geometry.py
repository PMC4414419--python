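"""Seeded generator of multicellular lattice geometries.

T cells are spheres of radius ``cell_radius`` on a regular cubic lattice
with surface-to-surface spacing ``cell_spacing`` (defaults 5 um + 5 um,
i.e. 15 um center pitch, the dense-culture geometry).  A seeded RNG
assigns roles -- ``secretor`` (IL-2 producing Th), ``responder_th`` or
``treg`` -- and draws one uniformly distributed surface point per secretor
as its polarized secretion site (the synapse position).  The space between
cells is freely diffusive extracellular medium (APCs are not represented
explicitly; they fill the gaps and only motivate the polarized source).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLE_SECRETOR = "secretor"
ROLE_RESPONDER = "responder_th"
ROLE_TREG = "treg"


@dataclass(frozen=True)
class TissueGeometry:
    """Lattice of spherical cells with roles and secretion points."""

    lattice_dims: tuple[int, int, int]
    cell_radius: float
    cell_spacing: float          # surface-to-surface
    centers: np.ndarray          # (n, 3) um
    roles: np.ndarray            # (n,) str
    secretion_dirs: np.ndarray   # (n, 3); zero rows for non-secretors
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def pitch(self) -> float:
        """Center-to-center lattice distance."""
        return 2.0 * self.cell_radius + self.cell_spacing

    @property
    def domain_size(self) -> np.ndarray:
        return np.asarray(self.lattice_dims, dtype=float) * self.pitch

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    @property
    def secretion_points(self) -> np.ndarray:
        """Surface points of secretors, (n_secretors, 3)."""
        sec = self.indices(ROLE_SECRETOR)
        return self.centers[sec] + self.cell_radius * self.secretion_dirs[sec]

    def lattice_offsets(self) -> np.ndarray:
        """Integer lattice coordinates of each cell, (n, 3)."""
        return np.rint(self.centers / self.pitch - 0.5).astype(int)


def build_geometry(lattice_dims, frac_secreting: float = 0.25,
                   frac_treg: float = 0.0, *, cell_radius: float = 5.0,
                   cell_spacing: float = 5.0,
                   single_central_secretor: bool = False,
                   seed: int = 0) -> TissueGeometry:
    """Build a seeded lattice population.

    Exactly ``round(frac * n_cells)`` cells receive each special role;
    Tregs are drawn from the non-secretors.  With
    ``single_central_secretor`` the one secretor is the cell nearest the
    domain center and all other cells are responders (the signaling-range
    setup).  Identical arguments and seed give identical geometries.
    """
    if isinstance(lattice_dims, int):
        lattice_dims = (lattice_dims,) * 3
    lattice_dims = tuple(int(d) for d in lattice_dims)
    if any(d < 1 for d in lattice_dims):
        raise ValueError("lattice dimensions must be >= 1")
    if cell_spacing <= 0:
        raise ValueError("cells overlap: cell_spacing must be > 0")
    if frac_secreting < 0 or frac_treg < 0 or frac_secreting + frac_treg > 1:
        raise ValueError("role fractions must be non-negative and sum <= 1")

    pitch = 2.0 * cell_radius + cell_spacing
    grids = np.meshgrid(*[(np.arange(d) + 0.5) * pitch for d in lattice_dims],
                        indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1)
    n = len(centers)
    rng = np.random.default_rng(seed)
    roles = np.full(n, ROLE_RESPONDER, dtype=object)

    if single_central_secretor:
        center = np.asarray(lattice_dims, dtype=float) * pitch / 2.0
        sec = np.array([int(np.argmin(np.linalg.norm(centers - center,
                                                     axis=1)))])
    else:
        n_sec = int(round(frac_secreting * n))
        sec = rng.choice(n, size=n_sec, replace=False)
    roles[sec] = ROLE_SECRETOR
    if frac_treg > 0 and not single_central_secretor:
        n_treg = int(round(frac_treg * n))
        rest = np.flatnonzero(roles != ROLE_SECRETOR)
        roles[rng.choice(rest, size=n_treg, replace=False)] = ROLE_TREG

    dirs = np.zeros((n, 3))
    for i in sec:
        v = rng.normal(size=3)
        dirs[i] = v / np.linalg.norm(v)
    return TissueGeometry(lattice_dims=lattice_dims, cell_radius=cell_radius,
                          cell_spacing=cell_spacing, centers=centers,
                          roles=np.asarray(roles, dtype=object),
                          secretion_dirs=dirs, seed=int(seed))
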