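"""Unit and property tests for the bimodular graded-beam core model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from bonebeam.core import (
    AdmissibilityError,
    GradientModulusModel,
    NeutralAxisState,
    NoSolutionError,
    SpecimenGeometry,
    StrainRecord,
    alpha_admissible_interval,
    bending_moment_from_stress,
    calibrate_E0,
    force_balance_residual,
    forward_strains,
    load_from_stress,
    modulus_profile,
    moment_balance_residual,
    neutral_axis_from_strains,
    side_integral,
    solve_alphas,
    stress_profile,
)


class TestNeutralAxisFromStrains:
    @pytest.mark.parametrize(
        "eps_C, eps_T, h, exp_hC, exp_hT, exp_rho",
        [
            # study-average baseline pair
            (2819e-6, 2807e-6, 6.0, 3.006398862, 2.993601138, 1066.477071),
            (3000e-6, 1000e-6, 4.0, 3.0, 1.0, 1000.0),
        ],
    )
    def test_splits_section_in_strain_proportion(self, eps_C, eps_T, h, exp_hC, exp_hT, exp_rho):
        axis = neutral_axis_from_strains(eps_C, eps_T, h)
        assert axis.h_C == pytest.approx(exp_hC, rel=1e-9)
        assert axis.h_T == pytest.approx(exp_hT, rel=1e-9)
        assert axis.rho == pytest.approx(exp_rho, rel=1e-9)

    @given(
        eps=st.floats(1e-5, 1e-2),
        h=st.floats(1.0, 10.0),
    )
    def test_equal_strains_give_mid_depth(self, eps, h):
        axis = neutral_axis_from_strains(eps, eps, h)
        assert axis.h_C == pytest.approx(h / 2)
        assert axis.h_T == pytest.approx(h / 2)

    @given(
        eps_C=st.floats(1e-5, 1e-2),
        eps_T=st.floats(1e-5, 1e-2),
        h=st.floats(1.0, 10.0),
    )
    def test_depths_sum_to_height(self, eps_C, eps_T, h):
        axis = neutral_axis_from_strains(eps_C, eps_T, h)
        assert axis.h_C + axis.h_T == pytest.approx(h, rel=1e-12)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError, match="eps_C"):
            neutral_axis_from_strains(0.0, 1e-3, 6.0)
        with pytest.raises(ValueError, match="height_h"):
            neutral_axis_from_strains(1e-3, 1e-3, -1.0)


class TestModulusProfile:
    def test_neutral_axis_value_is_E0_exactly(self):
        m = GradientModulusModel(E0=20000.0, alpha_C=0.7, alpha_T=-0.4)
        assert modulus_profile(m, 0.0) == 20000.0

    def test_homogeneous_limit(self):
        m = GradientModulusModel(E0=20000.0, alpha_C=0.0, alpha_T=0.0)
        y = np.linspace(-3, 3, 13)
        assert np.allclose(modulus_profile(m, y), 20000.0)

    def test_closed_form_value(self):
        # compression side, softening parameter -0.5: E = E0*(1 - ln(0.75))
        m = GradientModulusModel(E0=20000.0, alpha_C=-0.5, alpha_T=0.0, h_ref=6.0)
        assert modulus_profile(m, 3.0) == pytest.approx(20000.0 * (1 - math.log(0.75)), rel=1e-12)

    def test_continuous_at_neutral_axis(self):
        m = GradientModulusModel(E0=17500.0, alpha_C=0.9, alpha_T=-0.6)
        eps = 1e-12
        assert modulus_profile(m, eps) == pytest.approx(m.E0, rel=1e-10)
        assert modulus_profile(m, -eps) == pytest.approx(m.E0, rel=1e-10)

    def test_log_domain_violation_raises(self):
        m = GradientModulusModel(E0=20000.0, alpha_C=-2.5, alpha_T=0.0)
        with pytest.raises(AdmissibilityError):
            modulus_profile(m, 3.0)

    def test_nonpositive_modulus_raises(self):
        # 1 + alpha*y/6 >= e makes E <= 0
        m = GradientModulusModel(E0=20000.0, alpha_C=4.0, alpha_T=0.0)
        with pytest.raises(AdmissibilityError):
            modulus_profile(m, 3.0)


class TestStressProfile:
    def test_zero_at_neutral_axis(self):
        m = GradientModulusModel(E0=20000.0, alpha_C=0.5, alpha_T=-0.3)
        axis = NeutralAxisState(h_C=3.1, h_T=2.9, rho=1000.0)
        assert stress_profile(m, axis, 0.0) == 0.0

    def test_homogeneous_stress_ratio_is_depth_ratio(self):
        m = GradientModulusModel(E0=20000.0, alpha_C=0.0, alpha_T=0.0)
        axis = NeutralAxisState(h_C=3.5, h_T=2.5, rho=800.0)
        top = stress_profile(m, axis, axis.h_C)
        bottom = stress_profile(m, axis, -axis.h_T)
        assert top / bottom == pytest.approx(-axis.h_C / axis.h_T, rel=1e-12)

    def test_sign_follows_side(self):
        m = GradientModulusModel(E0=20000.0, alpha_C=0.4, alpha_T=-0.2)
        axis = NeutralAxisState(h_C=3.0, h_T=3.0, rho=900.0)
        assert stress_profile(m, axis, 1.5) > 0
        assert stress_profile(m, axis, -1.5) < 0


class TestSideIntegrals:
    @pytest.mark.parametrize("order, expected", [(1, 4.5), (2, 9.0)])
    def test_homogeneous_compression_closed_form(self, order, expected):
        # alpha=0: integral of y (d^2/2) and y^2 (d^3/3) over [0, 3]
        assert side_integral(0.0, 3.0, 6.0, "compression", order) == pytest.approx(expected)

    def test_homogeneous_tension_first_order_is_negative(self):
        assert side_integral(0.0, 3.0, 6.0, "tension", 1) == pytest.approx(-4.5)

    def test_matches_adaptive_quadrature(self):
        """Closed forms agree with quadrature to 1e-10 relative on an admissible grid."""
        rng = np.random.default_rng(42)
        h_ref = 6.0
        checked = 0
        for _ in range(120):
            depth = rng.uniform(0.5, 5.5)
            lo, hi = alpha_admissible_interval(depth, h_ref, margin=1e-3)
            alpha = rng.uniform(lo, hi)
            for order in (1, 2):
                oracle, _ = quad(
                    lambda y: (1 - np.log1p(alpha * y / h_ref)) * y**order,
                    0.0,
                    depth,
                    epsabs=1e-13,
                    epsrel=1e-13,
                )
                got = side_integral(alpha, depth, h_ref, "compression", order)
                assert got == pytest.approx(oracle, rel=1e-10)
            checked += 1
        assert checked >= 100

    @given(alpha=st.floats(-1e-6, 1e-6), depth=st.floats(0.5, 5.0))
    def test_series_branch_continuous_with_homogeneous_limit(self, alpha, depth):
        val = side_integral(alpha, depth, 6.0, "compression", 1)
        assert val == pytest.approx(depth**2 / 2, rel=1e-5)

    def test_admissibility_violation_raises(self):
        with pytest.raises(AdmissibilityError):
            side_integral(-2.1, 3.0, 6.0, "compression", 1)
        with pytest.raises(AdmissibilityError):
            side_integral(3.6, 3.0, 6.0, "compression", 2)


class TestForceBalance:
    def test_symmetric_model_balances_exactly(self):
        m = GradientModulusModel(E0=20000.0, alpha_C=0.37, alpha_T=0.37)
        axis = NeutralAxisState(h_C=3.0, h_T=3.0, rho=1000.0)
        assert force_balance_residual(m, axis) == pytest.approx(0.0, abs=1e-14)

    def test_homogeneous_closed_form(self):
        m = GradientModulusModel(E0=20000.0, alpha_C=0.0, alpha_T=0.0)
        axis = NeutralAxisState(h_C=3.1, h_T=2.9, rho=1000.0)
        assert force_balance_residual(m, axis) == pytest.approx((3.1**2 - 2.9**2) / 2)

    def test_residual_increases_with_h_C_at_fixed_total(self):
        """Numerical sweep: residual strictly increasing in h_C for fixed alphas and h."""
        m = GradientModulusModel(E0=20000.0, alpha_C=0.3, alpha_T=-0.1)
        h = 6.0
        vals = []
        for h_C in np.linspace(1.0, 5.0, 25):
            axis = NeutralAxisState(h_C=h_C, h_T=h - h_C, rho=1000.0)
            vals.append(force_balance_residual(m, axis))
        assert np.all(np.diff(vals) > 0)


class TestMomentBalance:
    def test_homogeneous_euler_bernoulli_moment_balances(self, geom):
        E0, rho = 20000.0, 1000.0
        h = geom.height_h
        M = E0 * geom.width_w * h**3 / (12.0 * rho)
        m = GradientModulusModel(E0=E0, alpha_C=0.0, alpha_T=0.0)
        axis = NeutralAxisState(h_C=h / 2, h_T=h / 2, rho=rho)
        res = moment_balance_residual(m, axis, M, geom.width_w)
        assert res == pytest.approx(0.0, abs=1e-12 * h**3)

    def test_invariant_under_scaling_M_and_E0(self, geom):
        axis = NeutralAxisState(h_C=3.2, h_T=2.8, rho=900.0)
        m1 = GradientModulusModel(E0=20000.0, alpha_C=0.2, alpha_T=-0.1)
        m2 = GradientModulusModel(E0=40000.0, alpha_C=0.2, alpha_T=-0.1)
        r1 = moment_balance_residual(m1, axis, 2000.0, geom.width_w)
        r2 = moment_balance_residual(m2, axis, 4000.0, geom.width_w)
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestLoading:
    def test_machine_load_formula(self, geom):
        # F = sigma*w*h^2/(3a) at the 120 MPa fatigue peak
        assert load_from_stress(120.0, geom) == pytest.approx(2160.0)

    def test_inner_span_moment(self, geom):
        # M = sigma*w*h^2/6 at the 66 MPa measurement stress
        assert bending_moment_from_stress(66.0, geom) == pytest.approx(2376.0)

    def test_moment_independent_of_lever_arm(self):
        g1 = SpecimenGeometry(lever_arm_a=4.0)
        g2 = SpecimenGeometry(lever_arm_a=8.0)
        assert bending_moment_from_stress(66.0, g1) == pytest.approx(
            bending_moment_from_stress(66.0, g2)
        )

    def test_rejects_nonpositive_stress(self, geom):
        with pytest.raises(ValueError):
            load_from_stress(-1.0, geom)


class TestCalibrateE0:
    def test_homogeneous_initial_from_baseline(self, geom, baseline_record):
        E0 = calibrate_E0(baseline_record, 66.0, geom)
        assert E0 == pytest.approx(2 * 66.0 / 5626e-6, rel=1e-12)
        assert E0 / 1000.0 == pytest.approx(23.46, abs=0.01)  # GPa, plausible for bovine bone

    def test_fixed_mode_is_identity(self, geom, baseline_record):
        assert calibrate_E0(baseline_record, 66.0, geom, mode="fixed", value=20000.0) == 20000.0

    def test_homogeneous_initial_reproduces_strain_sum(self, geom, baseline_record, moment_meas):
        E0 = calibrate_E0(baseline_record, 66.0, geom)
        rec = forward_strains(0.0, 0.0, E0, geom, moment_meas)
        assert rec.eps_C + rec.eps_T == pytest.approx(
            baseline_record.eps_C + baseline_record.eps_T, rel=1e-12
        )


class TestForwardInverseRoundTrip:
    def test_homogeneous_forward_matches_flexure_formula(self, geom, moment_meas):
        E0 = 20000.0
        rec = forward_strains(0.0, 0.0, E0, geom, moment_meas)
        sigma = 6 * moment_meas / (geom.width_w * geom.height_h**2)
        assert rec.eps_C * 1e-6 == pytest.approx(sigma / E0, rel=1e-12)
        assert rec.eps_T * 1e-6 == pytest.approx(sigma / E0, rel=1e-12)

    def test_equal_alphas_give_mid_depth_split(self, geom, moment_meas):
        rec = forward_strains(0.45, 0.45, 21000.0, geom, moment_meas)
        assert rec.eps_C == pytest.approx(rec.eps_T, rel=1e-12)

    def test_homogeneous_strains_invert_to_zero_alphas(self, geom, moment_meas):
        E0 = 20000.0
        sigma = 6 * moment_meas / (geom.width_w * geom.height_h**2)
        eps = sigma / E0 * 1e6
        state = solve_alphas(StrainRecord(0.0, eps, eps), geom, E0, moment_meas)
        assert state.model.alpha_C == pytest.approx(0.0, abs=1e-9)
        assert state.model.alpha_T == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "alpha_C, alpha_T",
        [(0.3, -0.2), (0.8, -0.3), (-0.4, 0.5), (0.05, 0.05), (1.5, -0.8)],
    )
    def test_round_trip_recovers_alphas(self, geom, moment_meas, alpha_C, alpha_T):
        E0 = 23000.0
        rec = forward_strains(alpha_C, alpha_T, E0, geom, moment_meas)
        state = solve_alphas(rec, geom, E0, moment_meas)
        assert state.model.alpha_C == pytest.approx(alpha_C, abs=1e-6)
        assert state.model.alpha_T == pytest.approx(alpha_T, abs=1e-6)
        assert abs(state.force_residual) < 1e-9 * geom.height_h**2
        assert abs(state.moment_residual) < 1e-9 * geom.height_h**3

    def test_swapped_strains_mirror_the_solution(self, geom, moment_meas):
        E0 = 23000.0
        rec = forward_strains(0.6, -0.25, E0, geom, moment_meas)
        direct = solve_alphas(rec, geom, E0, moment_meas)
        swapped = solve_alphas(
            StrainRecord(0.0, rec.eps_T, rec.eps_C), geom, E0, moment_meas
        )
        assert swapped.model.alpha_C == pytest.approx(direct.model.alpha_T, abs=1e-8)
        assert swapped.model.alpha_T == pytest.approx(direct.model.alpha_C, abs=1e-8)

    def test_solved_h_C_shrinks_as_compression_side_stiffens(self, geom, moment_meas):
        """Force balance: stiffening the compression side pulls the axis toward it."""
        E0 = 23000.0
        h_Cs = [
            neutral_axis_from_strains(
                *(np.array([forward_strains(a, 0.1, E0, geom, moment_meas).eps_C,
                            forward_strains(a, 0.1, E0, geom, moment_meas).eps_T]) * 1e-6),
                geom.height_h,
            ).h_C
            # decreasing alpha_C = stiffening away from the axis in this convention
            for a in np.linspace(0.4, -0.4, 9)
        ]
        assert np.all(np.diff(h_Cs) < 0)

    def test_inadmissible_strains_raise_no_solution(self, geom, moment_meas):
        # wildly asymmetric strain pair far outside the admissible alpha region
        with pytest.raises(NoSolutionError):
            solve_alphas(StrainRecord(0.0, 50000.0, 10.0), geom, 23000.0, moment_meas)
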