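"""End-to-end pipeline: simulate/ingest -> invert -> fits -> modulus -> FEM check.

Each stage writes its artifact to the configured output directory; a run
manifest (config echo, seed, package versions, residual summaries) makes the
run reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fem import compare_fem_analytical
from .io import RunConfig, read_trajectory_csv, trajectory_config_from_run, write_trajectory_csv
from .synthetic import generate_trajectory
from .trajectory import (
    analyze_trajectory,
    fit_linear,
    fit_two_segments,
    modulus_evolution_report,
)

__all__ = ["run_pipeline"]


def run_pipeline(
    config: RunConfig,
    trajectory_csv: str | Path | None = None,
    run_fem: bool = True,
) -> dict:
    """Execute the full analysis and write all artifacts.

    With no ``trajectory_csv`` the synthetic generator supplies the input
    trajectory (written alongside the outputs).  Returns the manifest dict;
    stage failures raise with the stage named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: input trajectory
    if trajectory_csv is not None:
        traj = read_trajectory_csv(trajectory_csv)
    else:
        traj = generate_trajectory(config.generator)
        write_trajectory_csv(traj, out / "trajectory.csv")

    # --- stage 2: per-instant inversion
    tcfg = trajectory_config_from_run(config)
    try:
        result = analyze_trajectory(traj, tcfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'solve' failed: {exc}") from exc
    solved = result.to_frame()
    solved.to_csv(out / "solved_states.csv", index=False, float_format="%.12g")

    # --- stage 3: strain-phase fits
    fits: dict = {}
    try:
        if len(traj) >= 5:
            seg = fit_two_segments(traj.t, traj.eps_C)
            fits["compressive_two_phase"] = {
                "breakpoint_t": seg.breakpoint_t,
                "slope_1_ue": seg.slope_1,
                "intercept_1_ue": seg.intercept_1,
                "slope_2_ue": seg.slope_2,
                "intercept_2_ue": seg.intercept_2,
                "r_squared": seg.r_squared,
            }
        if len(traj) >= 3:
            slope_T, intercept_T, r2_T = fit_linear(traj.t, traj.eps_T)
            fits["tensile_linear"] = {
                "slope_ue": slope_T,
                "intercept_ue": intercept_T,
                "r_squared": r2_T,
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'fits' failed: {exc}") from exc
    (out / "fits.json").write_text(json.dumps(fits, indent=2))

    # --- stage 4: modulus evolution table
    modulus_evolution_report(result).to_csv(
        out / "modulus_evolution.csv", index=False, float_format="%.12g"
    )

    # --- stage 5: FEM cross-check
    fem_summary = None
    if run_fem:
        try:
            cmp_df = compare_fem_analytical(
                result, nx=config.fem_nx, ny=config.fem_ny, nu=config.fem_nu
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'fem' failed: {exc}") from exc
        cmp_df.to_csv(out / "fem_comparison.csv", index=False, float_format="%.12g")
        fem_summary = {
            "max_abs_deviation_pct": float(cmp_df["deviation_pct"].abs().max()),
            "nx": config.fem_nx,
            "ny": config.fem_ny,
            "nu": config.fem_nu,
        }

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.generator.seed,
        "input": str(trajectory_csv) if trajectory_csv else "synthetic",
        "n_records": len(traj),
        "E0_MPa": result.E0,
        "residuals": {
            "max_abs_force": float(np.max(np.abs(solved["force_residual"]))),
            "max_abs_moment": float(np.max(np.abs(solved["moment_residual"]))),
        },
        "fits": fits,
        "fem": fem_summary,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
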