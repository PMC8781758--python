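"""Bimodular functionally-graded beam model for a four-point-bent bone specimen.

A rectangular cortical-bone beam in pure bending is modeled as a bimodular
functionally graded material: the longitudinal elastic modulus varies
logarithmically with distance ``y`` from the (migrating) neutral axis, with
independent gradient parameters on the compression side (``alpha_C``,
``0 <= y <= h_C``) and the tension side (``alpha_T``, ``-h_T <= y <= 0``)::

    E(y) = E0 * [1 - ln(1 + alpha_C * y / h_ref)]   (compression, y >= 0)
    E(y) = E0 * [1 - ln(1 - alpha_T * y / h_ref)]   (tension,     y <= 0)

``E0`` is the modulus at the neutral axis (assumed constant over fatigue
life); positive ``alpha`` means the side softens with distance from the
axis.  Given the surface strain pair measured at one fatigue instant, the
neutral-axis split (h_C, h_T) and curvature radius rho follow from plane
sections, and (alpha_C, alpha_T) are recovered from transverse force balance
and moment balance over the cross-section.

Units: a consistent MPa-mm-N system.  Strains are dimensionless internally;
converters from microstrain live at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SpecimenGeometry",
    "LoadingProtocol",
    "GradientModulusModel",
    "NeutralAxisState",
    "StrainRecord",
    "SolverOptions",
    "SolvedState",
    "AdmissibilityError",
    "NoSolutionError",
    "neutral_axis_from_strains",
    "modulus_profile",
    "stress_profile",
    "side_integral",
    "force_balance_residual",
    "moment_balance_residual",
    "load_from_stress",
    "bending_moment_from_stress",
    "calibrate_E0",
    "solve_alphas",
    "forward_strains",
    "alpha_admissible_interval",
    "UE_PER_STRAIN",
]

#: microstrain per unit dimensionless strain
UE_PER_STRAIN = 1.0e6

# E(y) > 0 requires 1 + alpha*y/h_ref < e, so alpha < (e-1)*h_ref/depth;
# the log domain requires alpha > -h_ref/depth.
_E_POS_FACTOR = math.e - 1.0


class AdmissibilityError(ValueError):
    """Gradient parameters violate the log domain or make E(y) <= 0."""


class NoSolutionError(RuntimeError):
    """No admissible root found for the requested balance equations."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class SpecimenGeometry:
    """Four-point-bend specimen cross-section and fixture spans (mm).

    ``lever_arm_a`` is the distance between an outer support and the adjacent
    inner loading point; ``loading_span_b`` is the inner span under constant
    bending moment.
    """

    width_w: float = 6.0
    height_h: float = 6.0
    lever_arm_a: float = 4.0
    loading_span_b: float = 34.0

    def __post_init__(self) -> None:
        _require_positive(
            width_w=self.width_w,
            height_h=self.height_h,
            lever_arm_a=self.lever_arm_a,
            loading_span_b=self.loading_span_b,
        )

    @property
    def outer_span(self) -> float:
        return self.loading_span_b + 2.0 * self.lever_arm_a


@dataclass(frozen=True)
class LoadingProtocol:
    """Cyclic-loading protocol: stresses in MPa, frequency in Hz.

    ``measurement_stress`` is the stress at which the machine pauses and
    strain images are captured; the fatigue cycle oscillates between
    ``min_stress`` and ``fatigue_stress_sigma_xx``.
    """

    fatigue_stress_sigma_xx: float = 120.0
    min_stress: float = 12.0
    measurement_stress: float = 66.0
    frequency: float = 10.0
    cycle_interval_Ne: int = 200

    def __post_init__(self) -> None:
        if not (0 <= self.min_stress < self.measurement_stress <= self.fatigue_stress_sigma_xx):
            raise ValueError(
                "require 0 <= min_stress < measurement_stress <= fatigue_stress_sigma_xx, got "
                f"{self.min_stress}, {self.measurement_stress}, {self.fatigue_stress_sigma_xx}"
            )


@dataclass(frozen=True)
class GradientModulusModel:
    """Through-thickness modulus law E(y) about the neutral axis.

    Parameters
    ----------
    E0 : float
        Modulus at the neutral axis (MPa), constant over fatigue life.
    alpha_C, alpha_T : float
        Dimensionless gradient parameters; positive values soften the
        respective side with distance from the axis.
    h_ref : float
        Reference length (mm) scaling the logarithm argument; defaults to
        the 6 mm nominal specimen height.
    """

    E0: float
    alpha_C: float
    alpha_T: float
    h_ref: float = 6.0

    def __post_init__(self) -> None:
        _require_positive(E0=self.E0, h_ref=self.h_ref)


@dataclass(frozen=True)
class NeutralAxisState:
    """Neutral-axis split of the section and curvature radius (mm).

    ``h_C`` is the compressed depth above the axis, ``h_T`` the stretched
    depth below; ``rho`` is the radius of curvature of the neutral layer.
    """

    h_C: float
    h_T: float
    rho: float

    def __post_init__(self) -> None:
        _require_positive(h_C=self.h_C, h_T=self.h_T, rho=self.rho)

    @property
    def height(self) -> float:
        return self.h_C + self.h_T


@dataclass(frozen=True)
class StrainRecord:
    """One fatigue instant: life fraction and surface strain magnitudes (microstrain)."""

    life_fraction_t: float
    eps_C: float
    eps_T: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.life_fraction_t <= 1.0):
            raise ValueError(f"life_fraction_t must be in [0, 1], got {self.life_fraction_t!r}")
        _require_positive(eps_C=self.eps_C, eps_T=self.eps_T)


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and bracketing controls for the nested root solver."""

    alpha_xtol: float = 1.0e-14
    bracket_margin: float = 1.0e-6
    scan_points: int = 64

    def force_tol(self, height_h: float) -> float:
        return 1.0e-9 * height_h**2

    def moment_tol(self, height_h: float) -> float:
        return 1.0e-9 * height_h**3


@dataclass(frozen=True)
class SolvedState:
    """A strain pair with its recovered neutral axis, model and residuals."""

    strain: StrainRecord
    axis: NeutralAxisState
    model: GradientModulusModel
    force_residual: float
    moment_residual: float


# ---------------------------------------------------------------------------
# kinematics


def neutral_axis_from_strains(eps_C: float, eps_T: float, height_h: float) -> NeutralAxisState:
    """Locate the neutral axis from the surface strain pair.

    Plane sections give ``eps = depth / rho`` on each side, so the section
    splits in proportion to the strains and ``rho = h / (eps_C + eps_T)``.
    Strains are dimensionless here (divide microstrain by 1e6 first).
    """
    _require_positive(eps_C=eps_C, eps_T=eps_T, height_h=height_h)
    total = eps_C + eps_T
    return NeutralAxisState(
        h_C=height_h * eps_C / total,
        h_T=height_h * eps_T / total,
        rho=height_h / total,
    )


# ---------------------------------------------------------------------------
# constitutive profile


def _log_arg(alpha: float, y: float, h_ref: float, side: str) -> float:
    # compression: 1 + a*y/r on y>=0 ; tension: 1 - a*y/r on y<=0
    return 1.0 + alpha * y / h_ref if side == "compression" else 1.0 - alpha * y / h_ref


def modulus_profile(model: GradientModulusModel, y: float | np.ndarray) -> float | np.ndarray:
    """Evaluate E(y) (MPa); ``y`` measured from the neutral axis, compression up."""
    y_arr = np.asarray(y, dtype=float)
    arg = np.where(
        y_arr >= 0.0,
        1.0 + model.alpha_C * y_arr / model.h_ref,
        1.0 - model.alpha_T * y_arr / model.h_ref,
    )
    if np.any(arg <= 0.0):
        raise AdmissibilityError(
            f"logarithm argument <= 0 at y={y_arr[arg <= 0.0] if y_arr.ndim else y}; "
            "gradient parameter outside its admissible interval"
        )
    E = model.E0 * (1.0 - np.log(arg))
    if np.any(E <= 0.0):
        raise AdmissibilityError("modulus E(y) <= 0; gradient parameter too large")
    return float(E) if np.isscalar(y) or np.asarray(y).ndim == 0 else E


def stress_profile(
    model: GradientModulusModel, axis: NeutralAxisState, y: float | np.ndarray
) -> float | np.ndarray:
    """Longitudinal stress sigma(y) = E(y) * y / rho (MPa); zero at the axis."""
    E = modulus_profile(model, y)
    return E * np.asarray(y, dtype=float) / axis.rho if not np.isscalar(E) else E * y / axis.rho


# ---------------------------------------------------------------------------
# side integrals (closed forms)

# Series switch: below this |alpha*d/h_ref| the closed forms lose digits to
# cancellation, the Maclaurin series is exact to ~1e-26 relative.
_SERIES_X = 1.0e-2
_SERIES_TERMS = 14


def _check_admissible(alpha: float, depth: float, h_ref: float) -> None:
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth!r}")
    x = alpha * depth / h_ref
    if x <= -1.0:
        raise AdmissibilityError(
            f"log domain violated: alpha*depth/h_ref = {x:.6g} <= -1"
        )
    if x >= _E_POS_FACTOR:
        raise AdmissibilityError(
            f"E(y) <= 0 at the surface: alpha*depth/h_ref = {x:.6g} >= e-1"
        )


def _J1(alpha: float, depth: float, h_ref: float) -> float:
    """int_0^d [1 - ln(1 + alpha*y/r)] y dy, the first-order side integral."""
    d, r = depth, h_ref
    x = alpha * d / r
    if abs(x) < _SERIES_X:
        # d^2/2 - sum_{k>=1} (-1)^(k+1) x^k d^2 / (k (k+2))
        acc = 0.5
        for k in range(1, _SERIES_TERMS + 1):
            acc -= (-1.0) ** (k + 1) * x**k / (k * (k + 2))
        return acc * d * d
    L = math.log1p(x)
    return d * d * (3.0 - 2.0 * L) / 4.0 - d * r / (2.0 * alpha) + r * r * L / (2.0 * alpha**2)


def _J2(alpha: float, depth: float, h_ref: float) -> float:
    """int_0^d [1 - ln(1 + alpha*y/r)] y^2 dy, the second-order side integral."""
    d, r = depth, h_ref
    x = alpha * d / r
    if abs(x) < _SERIES_X:
        acc = 1.0 / 3.0
        for k in range(1, _SERIES_TERMS + 1):
            acc -= (-1.0) ** (k + 1) * x**k / (k * (k + 3))
        return acc * d**3
    L = math.log1p(x)
    return (
        d**3 * (4.0 - 3.0 * L) / 9.0
        - d * d * r / (6.0 * alpha)
        + d * r * r / (3.0 * alpha**2)
        - r**3 * L / (3.0 * alpha**3)
    )


def side_integral(alpha: float, depth: float, h_ref: float, side: str, order: int) -> float:
    """Closed-form weighted modulus integral over one side of the section.

    ``order`` 1 gives the force-balance integrals (AFC for compression over
    ``[0, depth]``, AFT for tension over ``[-depth, 0]``); order 2 gives the
    moment-balance integrals AMC / AMT.  Tension-side integrals are obtained
    from the compression form by the mirror substitution y -> -y, so AFT is
    the negative of the generic first-order integral and AMT equals the
    generic second-order one.
    """
    if side not in ("compression", "tension"):
        raise ValueError(f"side must be 'compression' or 'tension', got {side!r}")
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order!r}")
    _check_admissible(alpha, depth, h_ref)
    if order == 1:
        value = _J1(alpha, depth, h_ref)
        return -value if side == "tension" else value
    return _J2(alpha, depth, h_ref)


# ---------------------------------------------------------------------------
# balance residuals


def force_balance_residual(model: GradientModulusModel, axis: NeutralAxisState) -> float:
    """AFC + AFT (mm^2): transverse force balance of the stress resultant."""
    return side_integral(model.alpha_C, axis.h_C, model.h_ref, "compression", 1) + side_integral(
        model.alpha_T, axis.h_T, model.h_ref, "tension", 1
    )


def moment_balance_residual(
    model: GradientModulusModel,
    axis: NeutralAxisState,
    moment_M: float,
    width_w: float,
) -> float:
    """AMC + AMT - M*rho/(w*E0) (mm^3): section moment balance."""
    _require_positive(moment_M=moment_M, width_w=width_w)
    amc = side_integral(model.alpha_C, axis.h_C, model.h_ref, "compression", 2)
    amt = side_integral(model.alpha_T, axis.h_T, model.h_ref, "tension", 2)
    return amc + amt - moment_M * axis.rho / (width_w * model.E0)


# ---------------------------------------------------------------------------
# loading


def load_from_stress(sigma: float, geom: SpecimenGeometry) -> float:
    """Total machine load F = sigma*w*h^2/(3a) (N) producing surface stress sigma."""
    _require_positive(sigma=sigma)
    return sigma * geom.width_w * geom.height_h**2 / (3.0 * geom.lever_arm_a)


def bending_moment_from_stress(sigma: float, geom: SpecimenGeometry) -> float:
    """Inner-span bending moment M = (F/2)*a = sigma*w*h^2/6 (N*mm).

    Independent of the lever arm: a cancels between the load formula and the
    moment arm.
    """
    return 0.5 * load_from_stress(sigma, geom) * geom.lever_arm_a


def calibrate_E0(
    initial: StrainRecord,
    sigma_meas: float,
    geom: SpecimenGeometry,
    mode: str = "homogeneous_initial",
    value: float | None = None,
) -> float:
    """Fix the neutral-axis modulus E0 (MPa).

    ``homogeneous_initial`` chooses the homogeneous-beam modulus that makes
    the pre-fatigue strain sum exact with alpha = 0, i.e.
    ``E0 = 2*sigma_meas/(eps_C0 + eps_T0)``; ``fixed`` returns ``value``.
    """
    if mode == "fixed":
        if value is None or value <= 0:
            raise ValueError("mode='fixed' requires a positive value")
        return float(value)
    if mode != "homogeneous_initial":
        raise ValueError(f"unknown E0 calibration mode {mode!r}")
    _require_positive(sigma_meas=sigma_meas)
    strain_sum = (initial.eps_C + initial.eps_T) / UE_PER_STRAIN
    if strain_sum <= 0:
        raise ValueError("initial strain sum must be > 0")
    return 2.0 * sigma_meas / strain_sum


# ---------------------------------------------------------------------------
# inverse and forward solvers


def alpha_admissible_interval(depth: float, h_ref: float, margin: float = 1.0e-6) -> tuple[float, float]:
    """Open interval of gradient parameters keeping E(y) positive over ``[0, depth]``."""
    lo = -h_ref / depth
    hi = _E_POS_FACTOR * h_ref / depth
    pad = margin * (hi - lo)
    return lo + pad, hi - pad


def _solve_alpha_T(
    alpha_C: float, h_C: float, h_T: float, h_ref: float, opts: SolverOptions
) -> float:
    """Inner root: alpha_T such that AFC(alpha_C) + AFT(alpha_T) = 0.

    J1 is strictly decreasing in alpha, so the root is unique when the
    target J1(alpha_C, h_C) lies in the attainable range on the tension side.
    """
    target = _J1(alpha_C, h_C, h_ref)
    lo, hi = alpha_admissible_interval(h_T, h_ref, opts.bracket_margin)
    f_lo = _J1(lo, h_T, h_ref) - target  # largest attainable J1 (alpha small)
    f_hi = _J1(hi, h_T, h_ref) - target
    if f_lo < 0.0 or f_hi > 0.0:
        raise NoSolutionError(
            f"force balance has no admissible alpha_T in ({lo:.4g}, {hi:.4g}) "
            f"for alpha_C={alpha_C:.6g}"
        )
    return brentq(
        lambda a: _J1(a, h_T, h_ref) - target, lo, hi, xtol=opts.alpha_xtol, rtol=8.9e-16
    )


def solve_alphas(
    strain: StrainRecord,
    geom: SpecimenGeometry,
    E0: float,
    moment_M: float,
    options: SolverOptions | None = None,
    h_ref: float = 6.0,
) -> SolvedState:
    """Recover (alpha_C, alpha_T) from one measured strain pair.

    The surface strains fix (h_C, h_T, rho); force balance then defines
    alpha_T implicitly as a function of alpha_C (inner 1-D root, unique by
    monotonicity of the first-order integral in alpha), and the moment
    balance closes the system with an outer 1-D root in alpha_C.  The outer
    residual is strictly decreasing in alpha_C, so the solution is unique.
    """
    opts = options or SolverOptions()
    _require_positive(E0=E0, moment_M=moment_M)
    axis = neutral_axis_from_strains(
        strain.eps_C / UE_PER_STRAIN, strain.eps_T / UE_PER_STRAIN, geom.height_h
    )
    target_moment = moment_M * axis.rho / (geom.width_w * E0)

    def outer(alpha_C: float) -> float:
        alpha_T = _solve_alpha_T(alpha_C, axis.h_C, axis.h_T, h_ref, opts)
        return (
            _J2(alpha_C, axis.h_C, h_ref) + _J2(alpha_T, axis.h_T, h_ref) - target_moment
        )

    lo, hi = alpha_admissible_interval(axis.h_C, h_ref, opts.bracket_margin)
    # scan for a sign change; the inner solve can fail near the interval ends
    grid = np.linspace(lo, hi, opts.scan_points)
    vals, alphas = [], []
    for a in grid:
        try:
            vals.append(outer(a))
            alphas.append(a)
        except NoSolutionError:
            continue
    bracket = None
    for (a0, v0), (a1, v1) in zip(zip(alphas, vals), zip(alphas[1:], vals[1:])):
        if v0 == 0.0:
            bracket = (a0, a0)
            break
        if v0 * v1 < 0.0:
            bracket = (a0, a1)
            break
    if bracket is None:
        if not alphas:
            raise NoSolutionError(
                f"force balance admits no alpha_T anywhere on the scanned alpha_C "
                f"interval [{lo:.4g}, {hi:.4g}]"
            )
        raise NoSolutionError(
            f"no sign change of the moment residual for alpha_C in "
            f"[{alphas[0]:.4g}, {alphas[-1]:.4g}] (scanned {len(alphas)} admissible points)"
        )
    alpha_C = (
        bracket[0]
        if bracket[0] == bracket[1]
        else brentq(outer, *bracket, xtol=opts.alpha_xtol, rtol=8.9e-16)
    )
    alpha_T = _solve_alpha_T(alpha_C, axis.h_C, axis.h_T, h_ref, opts)
    model = GradientModulusModel(E0=E0, alpha_C=alpha_C, alpha_T=alpha_T, h_ref=h_ref)
    f_res = force_balance_residual(model, axis)
    m_res = moment_balance_residual(model, axis, moment_M, geom.width_w)
    if abs(f_res) > opts.force_tol(geom.height_h) or abs(m_res) > opts.moment_tol(geom.height_h):
        raise NoSolutionError(
            f"balance residuals above tolerance after solve: |F|={abs(f_res):.3g}, "
            f"|M|={abs(m_res):.3g}"
        )
    return SolvedState(
        strain=strain, axis=axis, model=model, force_residual=f_res, moment_residual=m_res
    )


def forward_strains(
    alpha_C: float,
    alpha_T: float,
    E0: float,
    geom: SpecimenGeometry,
    moment_M: float,
    h_ref: float = 6.0,
    life_fraction_t: float = 0.0,
    options: SolverOptions | None = None,
) -> StrainRecord:
    """Predict the surface strain pair for known gradient parameters.

    Force balance ``J1(alpha_C, h_C) = J1(alpha_T, h - h_C)`` is strictly
    increasing in h_C, so the section split is the unique root; the moment
    balance then yields rho and the surface strains ``h_C/rho``, ``h_T/rho``
    (returned in microstrain).
    """
    opts = options or SolverOptions()
    _require_positive(E0=E0, moment_M=moment_M)
    h = geom.height_h

    def split_residual(h_C: float) -> float:
        return _J1(alpha_C, h_C, h_ref) - _J1(alpha_T, h - h_C, h_ref)

    # restrict to depths keeping both sides admissible
    eps = 1.0e-9 * h
    lo_d, hi_d = eps, h - eps
    if alpha_C < 0:
        hi_d = min(hi_d, -h_ref / alpha_C * (1.0 - 1e-12))
    elif alpha_C > 0:
        hi_d = min(hi_d, _E_POS_FACTOR * h_ref / alpha_C * (1.0 - 1e-12))
    if alpha_T < 0:
        lo_d = max(lo_d, h + h_ref / alpha_T * (1.0 + 1e-12))
    elif alpha_T > 0:
        lo_d = max(lo_d, h - _E_POS_FACTOR * h_ref / alpha_T * (1.0 - 1e-12))
    if not lo_d < hi_d:
        raise NoSolutionError(
            f"no admissible section split for alpha_C={alpha_C:.4g}, alpha_T={alpha_T:.4g}"
        )
    r_lo, r_hi = split_residual(lo_d), split_residual(hi_d)
    if r_lo * r_hi > 0.0:
        raise NoSolutionError(
            f"force balance has no root for h_C in ({lo_d:.4g}, {hi_d:.4g}); "
            f"residuals ({r_lo:.4g}, {r_hi:.4g})"
        )
    h_C = brentq(split_residual, lo_d, hi_d, xtol=1e-15, rtol=8.9e-16)
    h_T = h - h_C
    rho = (
        geom.width_w
        * E0
        * (_J2(alpha_C, h_C, h_ref) + _J2(alpha_T, h_T, h_ref))
        / moment_M
    )
    return StrainRecord(
        life_fraction_t=life_fraction_t,
        eps_C=h_C / rho * UE_PER_STRAIN,
        eps_T=h_T / rho * UE_PER_STRAIN,
    )
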