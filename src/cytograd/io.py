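"""Configuration loading, run manifests and file output.

Configs are YAML or JSON mappings with up to three sections --
``params`` (physical constants), ``scenario`` (geometry / roles) and
``sim`` (numerical settings).  Absent fields fall back to the published
IL-2 defaults; unknown keys are rejected with an explicit message.

Outputs: concentration snapshots as legacy ASCII VTK structured points
(readable by ParaView and friends), per-cell time series as CSV, run
summary and manifest as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams
from .tissue import SimConfig, Trajectory


@dataclass(frozen=True)
class ScenarioConfig:
    """Geometry / population section of a run configuration."""

    lattice_dims: tuple = (6, 6, 6)
    frac_secreting: float = 0.25
    frac_treg: float = 0.0
    single_central_secretor: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.frac_secreting < 0 or self.frac_treg < 0 \
                or self.frac_secreting + self.frac_treg > 1:
            raise ValueError("role fractions must be non-negative, sum <= 1")


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    scenario: ScenarioConfig
    sim: SimConfig

    def to_dict(self) -> dict:
        return {"params": asdict(self.params),
                "scenario": asdict(self.scenario),
                "sim": asdict(self.sim)}


def _build_section(cls, d: dict, section: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}")
    if "lattice_dims" in d:
        d = {**d, "lattice_dims": tuple(d["lattice_dims"])}
    return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An empty file resolves to the full default (published) parameter set.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data)}")
    unknown = set(data) - {"params", "scenario", "sim"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        params=_build_section(ModelParams, data.get("params", {}), "params"),
        scenario=_build_section(ScenarioConfig, data.get("scenario", {}),
                                "scenario"),
        sim=_build_section(SimConfig, data.get("sim", {}), "sim"),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    d["scenario"]["lattice_dims"] = list(d["scenario"]["lattice_dims"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def manifest(cfg: RunConfig, seeds=None) -> dict:
    """Run manifest: resolved config, parameter hash, software version."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return {
        "config": cfg.to_dict(),
        "parameter_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seeds": list(seeds) if seeds is not None else [cfg.scenario.seed],
        "version": __version__,
    }


def write_vtk_structured_points(path: str | Path, field: np.ndarray,
                                spacing: float, name: str = "concentration"
                                ) -> None:
    """Write a 3D scalar field as legacy ASCII VTK STRUCTURED_POINTS.

    NaNs (cell interiors) are written as -1 so viewers can threshold
    them away.
    """
    f = np.asarray(field, dtype=float)
    if f.ndim != 3:
        raise ValueError("field must be 3D")
    vals = np.where(np.isnan(f), -1.0, f)
    nx, ny, nz = f.shape
    lines = [
        "# vtk DataFile Version 3.0",
        name,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN 0 0 0",
        f"SPACING {spacing} {spacing} {spacing}",
        f"POINT_DATA {nx * ny * nz}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    # VTK expects x fastest: transpose to (z, y, x) then ravel
    body = " \n".join(" ".join(f"{v:.6g}" for v in row)
                      for row in vals.T.reshape(nz * ny, nx))
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def write_outputs(trajectory: Trajectory, out_dir: str | Path,
                  cfg: RunConfig | None = None) -> list[Path]:
    """Write VTK snapshots, per-cell CSV time series and JSON summaries.

    Returns the list of files written.  Filenames are deterministic; the
    CSV round-trips the time series at full float precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    spacing = trajectory.geometry.domain_size[0] / \
        trajectory.final_field.shape[0]

    snaps = trajectory.snapshots or [(trajectory.times[-1],
                                      trajectory.final_field)]
    for t, grid in snaps:
        p = out / f"field_t{t:08.3f}h.vtk"
        write_vtk_structured_points(p, grid, spacing)
        written.append(p)

    frames = []
    for i, t in enumerate(trajectory.times):
        df = pd.DataFrame({
            "time_h": t,
            "cell": np.arange(trajectory.geometry.n_cells),
            "role": trajectory.geometry.roles,
            "R_s": trajectory.R_s[i],
            "C": trajectory.C[i],
            "R_i": trajectory.R_i[i],
            "c_surf_nM": trajectory.c_surf_nM[i],
        })
        frames.append(df)
    csv_path = out / "cells.csv"
    pd.concat(frames, ignore_index=True).to_csv(
        csv_path, index=False, float_format="%.17g")
    written.append(csv_path)

    summary = {
        "times_h": trajectory.times.tolist(),
        "bulk_nM": trajectory.bulk_nM.tolist(),
        "ledger": {k: v.tolist() for k, v in trajectory.ledger.items()},
        "mass_balance_error": trajectory.mass_balance_error,
        "activated_final": int(trajectory.activated_mask().sum()),
    }
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    written.append(json_path)

    if cfg is not None:
        man_path = out / "manifest.json"
        man_path.write_text(json.dumps(manifest(cfg), indent=1,
                                       sort_keys=True))
        written.append(man_path)
    return written
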