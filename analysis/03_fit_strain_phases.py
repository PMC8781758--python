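#!/usr/bin/env python
"""Fit the two-phase compressive and linear tensile strain laws.

Uses the noisy replicate (the realistic case): a segmented least-squares fit
with the breakpoint searched over the observed life fractions for the
compressive strain, and a single line for the tensile strain.  Writes
results/fits.json.
"""

import json
from pathlib import Path

from bonebeam.io import read_trajectory_csv
from bonebeam.trajectory import fit_linear, fit_two_segments

OUT = Path(__file__).resolve().parents[1] / "results"

traj = read_trajectory_csv(OUT / "trajectory_noisy.csv")
seg = fit_two_segments(traj.t, traj.eps_C)
slope_T, intercept_T, r2_T = fit_linear(traj.t, traj.eps_T)

fits = {
    "compressive_two_phase": {
        "breakpoint_t": seg.breakpoint_t,
        "slope_1_ue": seg.slope_1,
        "slope_2_ue": seg.slope_2,
        "r_squared": seg.r_squared,
    },
    "tensile_linear": {"slope_ue": slope_T, "r_squared": r2_T},
}
(OUT / "fits.json").write_text(json.dumps(fits, indent=2))

print(f"compressive breakpoint at t = {seg.breakpoint_t:.2f} of life "
      f"(phase slopes {seg.slope_1:.0f} vs {seg.slope_2:.0f} ue per unit life), "
      f"pooled r^2 = {seg.r_squared:.3f}")
print(f"tensile strain: slope {slope_T:.0f} ue per unit life, r^2 = {r2_T:.3f}")
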