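import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from neovanc.pk_structural import (
    FINAL_THETA,
    CovariateModelSpec,
    DomainError,
    FixedEffects,
    ResidualSpec,
    StructuralParams,
    covariate_factor,
    individual_params,
    predict_concentration,
    steady_state_auc24,
    typical_clearance,
    typical_volume,
)
from neovanc.types import DoseEvent


def power_spec(center=1.0, exp=1.0, covariate="WT"):
    return CovariateModelSpec(covariate=covariate, target="CL", form="power",
                              center=center, params={"exp": exp})


class TestCovariateFactor:
    @pytest.mark.parametrize("theta", [-1.3, 0.0, 0.75, 2.2])
    def test_power_centering_identity(self, theta):
        spec = power_spec(center=2.9, exp=theta)
        assert covariate_factor(spec, 2.9) == pytest.approx(1.0)

    def test_maturation_midpoint(self):
        spec = CovariateModelSpec(covariate="PMA", target="CL", form="maturation",
                                  params={"tm50": 40.0, "hill": 3.4})
        assert covariate_factor(spec, 40.0) == pytest.approx(0.5)

    def test_maturation_rises_with_age(self):
        spec = CovariateModelSpec(covariate="PMA", target="CL", form="maturation",
                                  params={"tm50": 40.0, "hill": 3.4})
        ages = np.array([25.0, 35.0, 45.0, 80.0, 500.0])
        mf = covariate_factor(spec, ages)
        assert np.all(np.diff(mf) > 0)
        assert mf[-1] > 0.99  # approaches 1 in the mature limit

    def test_maturation_printed_orientation_falls(self):
        spec = CovariateModelSpec(covariate="PMA", target="CL", form="maturation",
                                  params={"tm50": 40.0, "hill": 3.4}, as_printed=True)
        assert covariate_factor(spec, 40.0) == pytest.approx(0.5)
        assert covariate_factor(spec, 80.0) < covariate_factor(spec, 20.0)

    def test_wt_exponent_kmax_zero_reduces_to_power(self):
        spec3 = CovariateModelSpec(
            covariate="WT", target="CL", form="wt_exponent", center=2.9,
            params={"exp0": 1.55, "kmax": 1e-300, "k50": 3.0, "hill": 2.0},
        )
        spec1 = power_spec(center=2.9, exp=1.55)
        for wt in (1.4, 2.9, 5.6):
            assert covariate_factor(spec3, wt) == pytest.approx(
                covariate_factor(spec1, wt), rel=1e-12
            )

    def test_age_exponent_uses_modifier(self):
        spec = CovariateModelSpec(
            covariate="WT", target="CL", form="age_exponent", center=2.9,
            params={"exp0": 1.5, "kmax": 0.5, "k50": 40.0, "hill": 2.0},
            modifier="PMA",
        )
        lo = covariate_factor(spec, 5.0, modifier=20.0)
        hi = covariate_factor(spec, 5.0, modifier=80.0)
        # exponent decreases with age, so the factor for WT > center shrinks
        assert hi < lo
        with pytest.raises(DomainError):
            covariate_factor(spec, 5.0)

    def test_linear_is_additive_term(self):
        spec = CovariateModelSpec(covariate="Scr", target="CL", form="linear",
                                  center=23.3, params={"slope": -0.002})
        assert covariate_factor(spec, 23.3) == pytest.approx(0.0)
        assert covariate_factor(spec, 33.3) == pytest.approx(-0.02)

    def test_categorical_reference_level(self):
        spec = CovariateModelSpec(covariate="sex", target="CL", form="categorical",
                                  params={"ratio": 0.8})
        assert covariate_factor(spec, 0.0) == pytest.approx(1.0)
        assert covariate_factor(spec, 1.0) == pytest.approx(0.8)

    def test_tv_baseline_delta_nests_static(self):
        spec = CovariateModelSpec(
            covariate="Scr", target="CL", form="tv_baseline_delta", center=23.3,
            params={"b_slope": -0.004, "d_slope": 0.0},
        )
        # with d_slope = 0 only the baseline matters
        assert covariate_factor(spec, 40.0, baseline=30.0) == pytest.approx(
            1.0 - 0.004 * (30.0 - 23.3)
        )

    def test_tv_baseline_delta_no_effect_when_both_zero(self):
        spec = CovariateModelSpec(
            covariate="Scr", target="CL", form="tv_baseline_delta", center=23.3,
            params={"b_slope": 0.0, "d_slope": 0.0},
        )
        assert covariate_factor(spec, 57.0, baseline=12.0) == pytest.approx(1.0)

    def test_power_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            covariate_factor(power_spec(), -1.0)

    def test_missing_hyperparameter_rejected(self):
        with pytest.raises(DomainError):
            CovariateModelSpec(covariate="WT", target="CL", form="maturation",
                               params={"tm50": 40.0})


class TestTypicalValues:
    def test_clearance_at_reference(self):
        assert typical_clearance(2.9, 23.3) == pytest.approx(0.309, abs=1e-12)

    def test_clearance_scr_doubling(self):
        assert typical_clearance(2.9, 46.6) == pytest.approx(
            0.309 * 2 ** (-0.337), rel=1e-12
        )

    def test_clearance_wt_doubling(self):
        assert typical_clearance(5.8, 23.3) == pytest.approx(0.309 * 2**1.55, rel=1e-12)

    def test_volume_at_reference(self):
        assert typical_volume(2.9) == pytest.approx(2.63, abs=1e-12)

    def test_volume_wt_doubling(self):
        assert typical_volume(5.8) == pytest.approx(2.63 * 2**1.05, rel=1e-12)

    def test_volume_zero_exponent(self):
        theta = FixedEffects(0.309, 1.55, 0.337, 2.63, 0.0)
        for wt in (1.4, 2.9, 5.6):
            assert typical_volume(wt, theta) == pytest.approx(2.63)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            typical_clearance(-1.0, 23.3)
        with pytest.raises(DomainError):
            typical_volume(0.0)

    @given(
        wt=st.floats(0.5, 10.0),
        factor=st.floats(1.01, 3.0),
        scr=st.floats(3.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_clearance_monotone(self, wt, factor, scr):
        assert typical_clearance(wt * factor, scr) > typical_clearance(wt, scr)
        assert typical_clearance(wt, scr * factor) < typical_clearance(wt, scr)

    def test_individual_params(self):
        p0 = individual_params(FINAL_THETA, 0.0, 2.9, 23.3)
        assert p0.cl == pytest.approx(0.309)
        assert p0.v == pytest.approx(2.63)
        p2 = individual_params(FINAL_THETA, math.log(2.0), 2.9, 23.3)
        assert p2.cl == pytest.approx(2 * 0.309)
        assert p2.v == pytest.approx(2.63)
        assert p0.ke == pytest.approx(0.309 / 2.63)


def q8h_regimen(amount=40.0, n=5):
    return [DoseEvent(start_time=8.0 * i, amount=amount) for i in range(n)]


class TestPredictConcentration:
    def test_zero_before_and_at_first_dose(self):
        params = StructuralParams(cl=0.3, v=2.6)
        assert predict_concentration(params, q8h_regimen(), 0.0) == 0.0
        assert predict_concentration(params, q8h_regimen(), np.array([-5.0]))[0] == 0.0

    def test_steady_state_limit_single_infusion(self):
        params = StructuralParams(cl=0.3, v=2.6)
        rate = 10.0
        dose = DoseEvent(start_time=0.0, amount=rate * 1e6, duration=1e6)
        t = 20.0 / params.ke
        c = predict_concentration(params, [dose], t)
        assert c == pytest.approx(rate / params.cl, rel=1e-6)

    def test_matches_ode_integration(self):
        """Closed form vs numerical integration of dA/dt = R(t) − ke·A."""
        params = StructuralParams(cl=0.42, v=3.1)
        doses = q8h_regimen(amount=37.5)

        def rate_in(t):
            return sum(
                d.rate for d in doses if d.start_time <= t < d.start_time + d.duration
            )

        def rhs(t, y):
            return [rate_in(t) - params.ke * y[0]]

        probes = np.linspace(0.5, 48.0, 50)
        breaks = sorted(
            {d.start_time for d in doses} | {d.start_time + d.duration for d in doses}
        )
        sol = solve_ivp(
            rhs, (0.0, 48.0), [0.0], t_eval=probes, rtol=1e-10, atol=1e-12,
            max_step=0.5, method="LSODA",
        )
        expected = sol.y[0] / params.v
        got = predict_concentration(params, doses, probes)
        assert np.allclose(got, expected, rtol=1e-6)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_superposition_linearity(self, scale):
        params = StructuralParams(cl=0.3, v=2.6)
        t = np.linspace(0.0, 50.0, 23)
        base = predict_concentration(params, q8h_regimen(40.0), t)
        scaled = predict_concentration(params, q8h_regimen(40.0 * scale), t)
        assert np.allclose(scaled, scale * base, rtol=1e-12)

    @given(shift=st.floats(0.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_time_shift_invariance(self, shift):
        params = StructuralParams(cl=0.3, v=2.6)
        t = np.linspace(0.0, 50.0, 17)
        base = predict_concentration(params, q8h_regimen(), t)
        shifted_doses = [
            DoseEvent(d.start_time + shift, d.amount, d.duration) for d in q8h_regimen()
        ]
        shifted = predict_concentration(params, shifted_doses, t + shift)
        assert np.allclose(shifted, base, rtol=1e-10, atol=1e-12)


class TestSteadyStateAuc:
    def test_inverse_identity(self):
        cl = 0.309
        assert steady_state_auc24(400.0 * cl, cl) == pytest.approx(400.0)

    def test_abstract_clearance_value(self):
        assert steady_state_auc24(123.6, 0.309) == pytest.approx(400.0)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            steady_state_auc24(100.0, 0.0)

    def test_against_numerical_integration(self):
        """Trapezoid integral of the steady-state profile over 24 h."""
        params = StructuralParams(cl=0.31, v=2.7)
        interval, amount = 8.0, 40.0
        n_doses = 200  # effectively at steady state
        doses = [DoseEvent(i * interval, amount) for i in range(n_doses)]
        t0 = (n_doses - 10) * interval
        t = np.linspace(t0, t0 + 24.0, 4001)
        c = predict_concentration(params, doses, t)
        auc_num = np.trapezoid(c, t)
        auc_formula = steady_state_auc24(amount * 24.0 / interval, params.cl)
        assert auc_num == pytest.approx(auc_formula, rel=1e-3)


class TestResidualSpec:
    def test_forms(self):
        add = ResidualSpec("additive", sigma2_add=0.25)
        assert np.allclose(add.variance([1.0, 10.0]), 0.25)
        prop = ResidualSpec("proportional", sigma2_prop=0.04)
        assert np.allclose(prop.variance([2.0]), 0.04 * 4.0)
        comb = ResidualSpec("combined", 0.04, 0.25)
        assert np.allclose(comb.variance([2.0]), 0.16 + 0.25)

    def test_invalid(self):
        with pytest.raises(DomainError):
            ResidualSpec("additive", sigma2_add=0.0)
        with pytest.raises(DomainError):
            ResidualSpec("weird", sigma2_prop=0.1)
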