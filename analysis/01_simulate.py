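#!/usr/bin/env python
"""Generate the study-shaped synthetic strain trajectories.

Writes two trajectory CSVs to results/: the deterministic noise-free
trajectory used for the qualitative fatigue analysis, and one noisy
replicate at the default 20-microstrain read noise.  Baselines are the
measured average initial strains (2819 / 2807 microstrain); the compressive
strain rises in two linear phases with a kink at 28% of life, the tensile
strain rises 4% linearly.
"""

from pathlib import Path

from bonebeam.io import write_trajectory_csv
from bonebeam.synthetic import TrajectoryGeneratorParams, generate_trajectory

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

noiseless = generate_trajectory(TrajectoryGeneratorParams(noise_sd=0.0))
write_trajectory_csv(noiseless, OUT / "trajectory_noiseless.csv")

noisy = generate_trajectory(TrajectoryGeneratorParams(noise_sd=20.0, seed=1))
write_trajectory_csv(noisy, OUT / "trajectory_noisy.csv")

print(f"wrote {len(noiseless)} noise-free records: eps_C "
      f"{noiseless.eps_C[0]:.0f} -> {noiseless.eps_C[-1]:.0f} ue (kink at t=0.28), "
      f"eps_T {noiseless.eps_T[0]:.0f} -> {noiseless.eps_T[-1]:.0f} ue")
print(f"wrote noisy replicate (sd=20 ue, seed=1) to {OUT}")
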