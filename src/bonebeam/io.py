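"""Validated readers/writers and run configuration.

CSV dialect shared by all tables: comma-delimited, '.' decimal, UTF-8,
'#' comment lines, header required.  The trajectory dialect has columns
``specimen_id, t, eps_C_ue, eps_T_ue`` with strictly increasing life
fractions per specimen (unsorted input is an error, never silently sorted).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .core import SolverOptions, SpecimenGeometry, StrainRecord
from .synthetic import TrajectoryGeneratorParams
from .trajectory import StrainTrajectory, TrajectoryConfig

__all__ = [
    "RunConfig",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_config",
    "trajectory_config_from_run",
]

_TRAJ_COLUMNS = ["specimen_id", "t", "eps_C_ue", "eps_T_ue"]


def read_trajectory_csv(path: str | Path) -> StrainTrajectory:
    """Read one strain trajectory from the documented CSV dialect."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    ids = df["specimen_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"{path}: expected a single specimen, found {list(ids)}")
    for col in ("t", "eps_C_ue", "eps_T_ue"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {row}")
    t = df["t"].to_numpy(dtype=float)
    nonmono = (t[1:] <= t[:-1]).nonzero()[0]
    if nonmono.size:
        row = int(nonmono[0]) + 3
        raise ValueError(
            f"{path}: life fractions not strictly increasing at line {row} "
            f"(t={t[nonmono[0] + 1]} after t={t[nonmono[0]]})"
        )
    records = tuple(
        StrainRecord(life_fraction_t=float(r.t), eps_C=float(r.eps_C_ue), eps_T=float(r.eps_T_ue))
        for r in df.itertuples()
    )
    return StrainTrajectory(records=records, specimen_id=str(ids[0]))


def write_trajectory_csv(traj: StrainTrajectory, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "specimen_id": traj.specimen_id,
            "t": traj.t,
            "eps_C_ue": traj.eps_C,
            "eps_T_ue": traj.eps_T,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (geometry, loading, model, solver, generator, fem)."""

    geometry: SpecimenGeometry = field(default_factory=SpecimenGeometry)
    sigma_max: float = 120.0
    sigma_min: float = 12.0
    sigma_meas: float = 66.0
    h_ref: float = 6.0
    E0_mode: str = "homogeneous_initial"
    E0_value: float | None = None
    solver: SolverOptions = field(default_factory=SolverOptions)
    generator: TrajectoryGeneratorParams = field(default_factory=TrajectoryGeneratorParams)
    fem_nx: int = 126
    fem_ny: int = 24
    fem_nu: float = 0.3
    output_dir: str = "results"

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_SECTION_TYPES = {
    "geometry": SpecimenGeometry,
    "solver": SolverOptions,
    "generator": TrajectoryGeneratorParams,
}


def _build_section(cls, payload: dict[str, Any], name: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in config section {name!r}: {sorted(unknown)}")
    return cls(**payload)


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config; unknown keys are rejected, not ignored."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in payload.items():
        if key in _SECTION_TYPES and isinstance(value, dict):
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def trajectory_config_from_run(cfg: RunConfig) -> TrajectoryConfig:
    return TrajectoryConfig(
        geometry=cfg.geometry,
        measurement_stress=cfg.sigma_meas,
        h_ref=cfg.h_ref,
        E0_mode=cfg.E0_mode,
        E0_value=cfg.E0_value,
        solver=cfg.solver,
    )
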