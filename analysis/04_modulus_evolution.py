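#!/usr/bin/env python
"""Tabulate the through-thickness modulus field E(y, t) over fatigue life.

Re-solves the noise-free trajectory and samples the recovered gradient
profiles on a fixed grid about the neutral axis, writing the long-format
table results/modulus_evolution.csv.  The finding: the compression-side
surface modulus degrades far more than the tension side, while the
neutral-axis modulus stays at E0 by construction.
"""

from pathlib import Path

import numpy as np

from bonebeam.core import modulus_profile
from bonebeam.io import read_trajectory_csv
from bonebeam.trajectory import analyze_trajectory, modulus_evolution_report

OUT = Path(__file__).resolve().parents[1] / "results"

traj = read_trajectory_csv(OUT / "trajectory_noiseless.csv")
res = analyze_trajectory(traj)
table = modulus_evolution_report(res)
table.to_csv(OUT / "modulus_evolution.csv", index=False, float_format="%.12g")

first, last = res.states[0], res.states[-1]
E_top0 = modulus_profile(first.model, first.axis.h_C)
E_top1 = modulus_profile(last.model, last.axis.h_C)
E_bot0 = modulus_profile(first.model, -first.axis.h_T)
E_bot1 = modulus_profile(last.model, -last.axis.h_T)
print(f"{len(table)} samples of E(y, t) written")
print(f"compression surface: {E_top0/1000:.2f} -> {E_top1/1000:.2f} GPa "
      f"({100 * (E_top1 / E_top0 - 1):+.1f}%)")
print(f"tension surface:     {E_bot0/1000:.2f} -> {E_bot1/1000:.2f} GPa "
      f"({100 * (E_bot1 / E_bot0 - 1):+.1f}%)")
print(f"neutral axis:        {res.E0/1000:.2f} GPa throughout")
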