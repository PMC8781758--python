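"""Synthetic strain trajectories emulating the four-point-bend fatigue study.

No raw strain data is deposited for the study this package models, so this
module generates trajectories with the same statistical structure that the
measurements show: a two-phase piecewise-linear compressive strain with a
breakpoint near 28% of fatigue life, a slowly rising tensile strain
(about +4% over the whole life), initial magnitudes matching the measured
averages, and additive Gaussian read noise.  It also builds exact
forward-model fixtures (strains computed from known gradient-parameter
paths) for recovery tests.

Default baselines come from the study's measured initial strains
(compressive 2819 microstrain, tensile 2807 microstrain, averaged over four
specimens).  The phase rises are not printed in the study; the defaults
(500 then 280 microstrain) reproduce the reported fast-then-slow shape with
a total compressive rise of about 28% of the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    SpecimenGeometry,
    StrainRecord,
    bending_moment_from_stress,
    forward_strains,
)
from .trajectory import StrainTrajectory

__all__ = [
    "TrajectoryGeneratorParams",
    "ForwardFixture",
    "generate_trajectory",
    "generate_forward_fixture",
    "MEASURED_INITIAL_STRAINS",
    "MEASURED_AVERAGE_STRAINS",
]

# Measured initial strains per specimen (eps_C, eps_T, microstrain) and the
# printed per-study average row.
MEASURED_INITIAL_STRAINS: tuple[tuple[float, float], ...] = (
    (3157.0, 2953.0),
    (2749.0, 2731.0),
    (2726.0, 2604.0),
    (2644.0, 2544.0),
)
MEASURED_AVERAGE_STRAINS: tuple[float, float] = (2819.0, 2807.0)


@dataclass(frozen=True)
class TrajectoryGeneratorParams:
    """Shape and noise parameters of the emulated strain trajectories.

    ``phase1_rise`` / ``phase2_rise`` are the compressive strain increments
    (microstrain) accumulated over [0, breakpoint] and [breakpoint, 1];
    ``tensile_total_rise_frac`` scales the tensile baseline linearly over the
    whole life.  ``noise_sd`` is additive i.i.d. Gaussian noise per reading,
    on the order of DIC strain resolution.
    """

    eps_C0: float = MEASURED_AVERAGE_STRAINS[0]
    eps_T0: float = MEASURED_AVERAGE_STRAINS[1]
    breakpoint_t: float = 0.28
    phase1_rise: float = 500.0
    phase2_rise: float = 280.0
    tensile_total_rise_frac: float = 0.04
    n_points: int = 11
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.breakpoint_t < 1.0:
            raise ValueError("breakpoint_t must lie strictly inside (0, 1)")
        if self.n_points < 5:
            raise ValueError("n_points must be >= 5")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _life_grid(breakpoint_t: float, n_points: int) -> np.ndarray:
    """Life fractions 0..1 with the breakpoint always on the grid.

    Points are allocated to the two phases in proportion to their length
    (at least two per phase, endpoints and breakpoint included).
    """
    k1 = min(max(2, round(breakpoint_t * (n_points - 1)) + 1), n_points - 1)
    k2 = n_points + 1 - k1
    return np.unique(
        np.concatenate(
            [np.linspace(0.0, breakpoint_t, k1), np.linspace(breakpoint_t, 1.0, k2)]
        )
    )


def eps_C_true(params: TrajectoryGeneratorParams, t: np.ndarray) -> np.ndarray:
    """Noise-free two-phase compressive strain (microstrain)."""
    t = np.asarray(t, dtype=float)
    bp = params.breakpoint_t
    phase1 = params.eps_C0 + params.phase1_rise * t / bp
    phase2 = (
        params.eps_C0
        + params.phase1_rise
        + params.phase2_rise * (t - bp) / (1.0 - bp)
    )
    return np.where(t <= bp, phase1, phase2)


def eps_T_true(params: TrajectoryGeneratorParams, t: np.ndarray) -> np.ndarray:
    """Noise-free linear tensile strain (microstrain)."""
    t = np.asarray(t, dtype=float)
    return params.eps_T0 * (1.0 + params.tensile_total_rise_frac * t)


def generate_trajectory(params: TrajectoryGeneratorParams | None = None) -> StrainTrajectory:
    """Draw one reproducible synthetic trajectory (same seed, same output)."""
    p = params or TrajectoryGeneratorParams()
    t = _life_grid(p.breakpoint_t, p.n_points)
    eC = eps_C_true(p, t)
    eT = eps_T_true(p, t)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        eC = eC + rng.normal(0.0, p.noise_sd, size=t.size)
        eT = eT + rng.normal(0.0, p.noise_sd, size=t.size)
    records = tuple(
        StrainRecord(life_fraction_t=float(ti), eps_C=float(ci), eps_T=float(si))
        for ti, ci, si in zip(t, eC, eT)
    )
    return StrainTrajectory(records=records, specimen_id=f"synthetic-{p.seed}")


@dataclass(frozen=True)
class ForwardFixture:
    """Exact forward-model trajectory with its ground-truth parameter paths."""

    alpha_C_series: np.ndarray
    alpha_T_series: np.ndarray
    E0: float
    geometry: SpecimenGeometry
    moment: float
    trajectory: StrainTrajectory
    noise_sd: float = 0.0


def generate_forward_fixture(
    alpha_C_path: np.ndarray,
    alpha_T_path: np.ndarray,
    E0: float,
    geom: SpecimenGeometry | None = None,
    sigma_meas: float = 66.0,
    n_points: int | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    h_ref: float = 6.0,
) -> ForwardFixture:
    """Build an exact-strain trajectory from known gradient-parameter paths.

    The alpha paths are sampled at ``n_points`` evenly spaced life fractions
    (defaulting to the path length); each point runs the forward model, so by
    construction the noiseless strains satisfy both balance equations.
    Inadmissible parameters at any life fraction raise with that t named.
    """
    geom = geom or SpecimenGeometry()
    aC = np.asarray(alpha_C_path, dtype=float)
    aT = np.asarray(alpha_T_path, dtype=float)
    if aC.shape != aT.shape:
        raise ValueError("alpha paths must have equal length")
    n = n_points or aC.size
    if n != aC.size:
        t_src = np.linspace(0.0, 1.0, aC.size)
        t = np.linspace(0.0, 1.0, n)
        aC = np.interp(t, t_src, aC)
        aT = np.interp(t, t_src, aT)
    else:
        t = np.linspace(0.0, 1.0, n)
    M = bending_moment_from_stress(sigma_meas, geom)
    records = []
    for ti, ac, at in zip(t, aC, aT):
        try:
            rec = forward_strains(ac, at, E0, geom, M, h_ref=h_ref, life_fraction_t=float(ti))
        except Exception as exc:
            raise type(exc)(f"forward model failed at life fraction t={ti:.4g}: {exc}") from exc
        records.append(rec)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        records = [
            replace(
                r,
                eps_C=r.eps_C + rng.normal(0.0, noise_sd),
                eps_T=r.eps_T + rng.normal(0.0, noise_sd),
            )
            for r in records
        ]
    traj = StrainTrajectory(records=tuple(records), specimen_id=f"forward-fixture-{seed}")
    return ForwardFixture(
        alpha_C_series=aC,
        alpha_T_series=aT,
        E0=E0,
        geometry=geom,
        moment=M,
        trajectory=traj,
        noise_sd=noise_sd,
    )
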