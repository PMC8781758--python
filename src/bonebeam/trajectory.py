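"""Fatigue-trajectory analysis: per-instant inversion and strain-phase fits.

Runs the bimodular gradient-beam inversion across a full strain trajectory
(one strain pair per sampled life fraction), tracks the neutral-axis
migration and extreme-fiber stresses, tabulates the modulus field E(y, t),
and fits the two-phase piecewise-linear behavior of the compressive strain
(rapid rise up to a breakpoint near 28% of life, slow rise after).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    NoSolutionError,
    SolvedState,
    SolverOptions,
    SpecimenGeometry,
    StrainRecord,
    bending_moment_from_stress,
    calibrate_E0,
    modulus_profile,
    solve_alphas,
    stress_profile,
)

__all__ = [
    "StrainTrajectory",
    "SegmentedFit",
    "TrajectoryResult",
    "TrajectoryConfig",
    "analyze_trajectory",
    "fit_linear",
    "fit_two_segments",
    "modulus_evolution_report",
]


@dataclass(frozen=True)
class StrainTrajectory:
    """Ordered strain records over fatigue life for one specimen (or an average)."""

    records: tuple[StrainRecord, ...]
    specimen_id: str = "specimen"

    def __post_init__(self) -> None:
        t = [r.life_fraction_t for r in self.records]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("life fractions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def t(self) -> np.ndarray:
        return np.array([r.life_fraction_t for r in self.records])

    @property
    def eps_C(self) -> np.ndarray:
        return np.array([r.eps_C for r in self.records])

    @property
    def eps_T(self) -> np.ndarray:
        return np.array([r.eps_T for r in self.records])


@dataclass(frozen=True)
class SegmentedFit:
    """Two independent least-squares lines joined at a breakpoint life fraction."""

    breakpoint_t: float
    slope_1: float
    intercept_1: float
    slope_2: float
    intercept_2: float
    r_squared: float
    sse: float


@dataclass(frozen=True)
class TrajectoryConfig:
    """Inputs the inversion needs beyond the strains themselves."""

    geometry: SpecimenGeometry = field(default_factory=SpecimenGeometry)
    measurement_stress: float = 66.0
    h_ref: float = 6.0
    E0_mode: str = "homogeneous_initial"
    E0_value: float | None = None
    solver: SolverOptions = field(default_factory=SolverOptions)
    skip_unsolvable: bool = False


@dataclass(frozen=True)
class TrajectoryResult:
    """Per-record solved states plus derived neutral-axis and stress histories."""

    states: tuple[SolvedState, ...]
    neutral_axis_offsets: np.ndarray  # h_T - h/2, signed; < 0 => axis below mid-depth (toward tension)
    extreme_fiber_stresses: np.ndarray  # columns: sigma(h_C), sigma(-h_T), MPa
    E0: float
    config: TrajectoryConfig
    skipped_t: tuple[float, ...] = ()

    @property
    def alpha_C(self) -> np.ndarray:
        return np.array([s.model.alpha_C for s in self.states])

    @property
    def alpha_T(self) -> np.ndarray:
        return np.array([s.model.alpha_T for s in self.states])

    @property
    def t(self) -> np.ndarray:
        return np.array([s.strain.life_fraction_t for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        """Solved-state table, one row per life fraction."""
        return pd.DataFrame(
            {
                "t": self.t,
                "eps_C_ue": [s.strain.eps_C for s in self.states],
                "eps_T_ue": [s.strain.eps_T for s in self.states],
                "h_C_mm": [s.axis.h_C for s in self.states],
                "h_T_mm": [s.axis.h_T for s in self.states],
                "rho_mm": [s.axis.rho for s in self.states],
                "alpha_C": self.alpha_C,
                "alpha_T": self.alpha_T,
                "force_residual": [s.force_residual for s in self.states],
                "moment_residual": [s.moment_residual for s in self.states],
            }
        )


def analyze_trajectory(traj: StrainTrajectory, config: TrajectoryConfig | None = None) -> TrajectoryResult:
    """Invert the gradient model at every sampled life fraction.

    E0 is calibrated once from the first (pre-fatigue) record and held
    constant; each record then yields (alpha_C, alpha_T), the neutral-axis
    offset from mid-depth (negative when the axis has migrated toward the
    tension side), and the extreme-fiber stress pair.
    """
    cfg = config or TrajectoryConfig()
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    geom = cfg.geometry
    E0 = calibrate_E0(
        traj.records[0], cfg.measurement_stress, geom, mode=cfg.E0_mode, value=cfg.E0_value
    )
    M = bending_moment_from_stress(cfg.measurement_stress, geom)
    states: list[SolvedState] = []
    skipped: list[float] = []
    for rec in traj.records:
        try:
            states.append(
                solve_alphas(rec, geom, E0, M, options=cfg.solver, h_ref=cfg.h_ref)
            )
        except NoSolutionError as exc:
            if cfg.skip_unsolvable:
                skipped.append(rec.life_fraction_t)
                continue
            raise NoSolutionError(
                f"record at life fraction t={rec.life_fraction_t} unsolvable: {exc}"
            ) from exc
    offsets = np.array([s.axis.h_T - geom.height_h / 2.0 for s in states])
    stresses = np.array(
        [
            [
                stress_profile(s.model, s.axis, s.axis.h_C),
                stress_profile(s.model, s.axis, -s.axis.h_T),
            ]
            for s in states
        ]
    )
    return TrajectoryResult(
        states=tuple(states),
        neutral_axis_offsets=offsets,
        extreme_fiber_stresses=stresses,
        E0=E0,
        config=cfg,
        skipped_t=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# strain-phase fits


def fit_linear(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares y = slope*t + intercept with pooled r^2.

    When the response is exactly constant (SST = 0) the fit is perfect by
    convention and r^2 = 1.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if np.ptp(t) == 0.0:
        raise ValueError("degenerate design: all t identical")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    return float(slope), float(intercept), r2


def _segment_ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    sse = float(np.sum((y - (slope * t + intercept)) ** 2))
    return float(slope), float(intercept), sse


def fit_two_segments(t: np.ndarray, y: np.ndarray) -> SegmentedFit:
    """Two-phase piecewise-linear fit with the breakpoint on the observed grid.

    Every interior observation is tried as the breakpoint; the sample at the
    breakpoint belongs to both segments, each segment is fit by ordinary
    least squares, and the breakpoint minimizing the pooled residual sum of
    squares wins (ties go to the earliest candidate).  r^2 pools both
    segments against the global mean.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points for a segmented fit")
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("t must be strictly increasing")
    best: SegmentedFit | None = None
    sst = float(np.sum((y - y.mean()) ** 2))
    for k in range(1, t.size - 1):
        left = slice(0, k + 1)
        right = slice(k, t.size)
        if t[left].size < 2 or t[right].size < 2:
            continue
        s1, b1, sse1 = _segment_ols(t[left], y[left])
        s2, b2, sse2 = _segment_ols(t[right], y[right])
        sse = sse1 + sse2
        if best is None or sse < best.sse:
            r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
            best = SegmentedFit(
                breakpoint_t=float(t[k]),
                slope_1=s1,
                intercept_1=b1,
                slope_2=s2,
                intercept_2=b2,
                r_squared=r2,
                sse=sse,
            )
    if best is None:
        raise ValueError("no candidate breakpoint admits 2 points per segment")
    return best


def modulus_evolution_report(result: TrajectoryResult, y_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Sample E(y, t) on a fixed through-thickness grid, long format.

    ``y_grid`` is measured from the *current* neutral axis at each life
    fraction; by default 41 points spanning the section of the first state.
    Rows outside the admissible section at a given t are clipped to the
    section edges.
    """
    if y_grid is None:
        h = result.config.geometry.height_h
        y_grid = np.linspace(-h / 2.0, h / 2.0, 41)
    rows = []
    for s in result.states:
        y = np.clip(y_grid, -s.axis.h_T, s.axis.h_C)
        E = modulus_profile(s.model, y)
        for yi, Ei in zip(y, np.atleast_1d(E)):
            rows.append((s.strain.life_fraction_t, float(yi), float(Ei)))
    return pd.DataFrame(rows, columns=["t", "y_mm", "E_MPa"])
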