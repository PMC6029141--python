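import math

import numpy as np
import pytest

from neovanc.foce_engine import (
    compile_dataset,
    compute_cwres,
    cwres_at,
    exact_objective_quadrature,
    fit,
    foce_objective,
    foce_subject_objective,
    marginal_m2ll_quadrature,
    simulate_dv,
    LOG_2PI,
)
from neovanc.pk_structural import ResidualSpec
from neovanc.synthetic_cohort import CohortConfig, simulate_cohort
from neovanc.types import PopulationDataset


# ---------------------------------------------------------------------------
# objective: degenerate and oracle comparisons
# ---------------------------------------------------------------------------


class TestObjectiveDegenerate:
    def test_omega_zero_is_els_objective(self, study_compiled, final_structure, truth_values):
        theta, _, sigma2 = truth_values
        res = ResidualSpec("proportional", sigma2)
        ov = foce_objective(study_compiled, final_structure, theta, 0.0, res)
        # direct extended-least-squares computation at eta = 0
        from neovanc.foce_engine import _InnerModel

        inner = _InnerModel(study_compiled, final_structure, theta, res)
        f = inner.predict(np.zeros(study_compiled.n_subjects))
        var = res.variance(f)
        expected = float(np.sum((study_compiled.y - f) ** 2 / var + np.log(var)))
        assert ov.value == pytest.approx(expected, rel=1e-12)
        assert np.all(ov.eta_hat == 0.0)

    def test_quadrature_matches_foce_at_omega_zero(self, study_compiled, final_structure, truth_values):
        theta, _, sigma2 = truth_values
        res = ResidualSpec("proportional", sigma2)
        a = foce_objective(study_compiled, final_structure, theta, 0.0, res)
        b = exact_objective_quadrature(study_compiled, final_structure, theta, 0.0, res)
        assert b.value == pytest.approx(a.value, rel=1e-12)

    def test_per_subject_contributions_sum(self, study_compiled, final_structure, truth_values):
        theta, omega2, sigma2 = truth_values
        ov = foce_objective(study_compiled, final_structure, theta, omega2,
                            ResidualSpec("proportional", sigma2))
        assert ov.value == pytest.approx(float(np.sum(ov.per_subject)))
        assert ov.with_constant == pytest.approx(ov.value + 160 * LOG_2PI)


class TestLinearModelOracle:
    """For a model linear in η with additive error the FOCE approximation is
    exact; all three routes must agree with the conjugate closed form."""

    def setup_method(self):
        rng = np.random.default_rng(1234)
        self.a = np.array([1.0, 2.0, 1.5])
        self.b = np.array([0.8, 1.6, 1.1])
        self.y = self.a + rng.normal(0, 0.4, 3)
        self.res = ResidualSpec("additive", sigma2_add=0.16)
        self.omega2 = 0.25

    def fmean(self, eta):
        return self.a + self.b * eta

    def closed_form(self):
        # y = a + b*eta + eps: marginal N(a, sigma2 I + omega2 b b')
        C = 0.16 * np.eye(3) + self.omega2 * np.outer(self.b, self.b)
        r = self.y - self.a
        sign, logdet = np.linalg.slogdet(C)
        return float(logdet + r @ np.linalg.solve(C, r) + 3 * LOG_2PI)

    def test_foce_equals_closed_form(self):
        val, _ = foce_subject_objective(self.y, self.fmean, self.res, self.omega2)
        assert val == pytest.approx(self.closed_form(), abs=1e-8)

    def test_quadrature_equals_closed_form(self):
        val = marginal_m2ll_quadrature(self.y, self.fmean, self.res, self.omega2, nodes=64)
        assert val == pytest.approx(self.closed_form(), abs=1e-6)

    def test_single_observation_conjugate_case(self):
        y = np.array([1.7])
        a, b = np.array([1.0]), np.array([2.0])
        val = marginal_m2ll_quadrature(
            y, lambda eta: a + b * eta, self.res, self.omega2, nodes=64
        )
        var = 0.16 + self.omega2 * 4.0
        expected = math.log(var) + (0.7**2) / var + LOG_2PI
        assert val == pytest.approx(expected, abs=1e-8)


class TestQuadratureOracle:
    def test_node_doubling_stability_additive(self, final_structure, truth_values):
        """Spectral convergence on an additive-error cohort with moderate IIV."""
        theta, _, _ = truth_values
        cfg = CohortConfig(n_subjects=20, seed=11, residual_form="additive",
                           sigma_cv=50.0, omega_cv=25.0)  # 0.5 mg/L additive sd
        dataset, _ = simulate_cohort(cfg)
        res = ResidualSpec("additive", sigma2_add=0.25)
        omega2 = 0.25**2
        compiled = compile_dataset(dataset, final_structure.covariate_names())
        v32 = exact_objective_quadrature(compiled, final_structure, theta, omega2, res, nodes=32)
        v64 = exact_objective_quadrature(compiled, final_structure, theta, omega2, res, nodes=64)
        assert abs(v64.value - v32.value) < 1e-8

    def test_node_doubling_proportional_error(self, small_cohort, final_structure, truth_values):
        """Below-quantitation troughs skew the proportional-error integrand,
        so convergence there is algebraic; the 64-node oracle is still far
        inside the 0.5-per-subject comparison tolerance."""
        dataset, _ = small_cohort
        theta, omega2, sigma2 = truth_values
        res = ResidualSpec("proportional", sigma2)
        compiled = compile_dataset(dataset, final_structure.covariate_names())
        v32 = exact_objective_quadrature(compiled, final_structure, theta, omega2, res, nodes=32)
        v64 = exact_objective_quadrature(compiled, final_structure, theta, omega2, res, nodes=64)
        assert abs(v64.value - v32.value) < 1e-3

    def test_node_minimum(self, study_compiled, final_structure, truth_values):
        theta, omega2, sigma2 = truth_values
        with pytest.raises(ValueError):
            exact_objective_quadrature(study_compiled, final_structure, theta, omega2,
                                       ResidualSpec("proportional", sigma2), nodes=8)

    def test_foce_close_to_quadrature_per_subject(self, study_compiled, final_structure, truth_values):
        theta, omega2, sigma2 = truth_values
        res = ResidualSpec("proportional", sigma2)
        a = foce_objective(study_compiled, final_structure, theta, omega2, res)
        b = exact_objective_quadrature(study_compiled, final_structure, theta, omega2, res)
        assert np.mean(np.abs(a.per_subject - b.per_subject)) < 0.5

    def test_vectorized_foce_matches_generic_per_subject(self, small_cohort, final_structure, truth_values):
        dataset, _ = small_cohort
        theta, omega2, sigma2 = truth_values
        res = ResidualSpec("proportional", sigma2)
        compiled = compile_dataset(dataset, final_structure.covariate_names())
        ov = foce_objective(compiled, final_structure, theta, omega2, res)
        from neovanc.foce_engine import _InnerModel

        inner = _InnerModel(compiled, final_structure, theta, res)
        for i in range(compiled.n_subjects):
            idx = compiled.subject_observation_indices(i)

            def fmean(eta, i=i, idx=idx):
                ev = np.zeros(compiled.n_subjects)
                ev[i] = eta
                return inner.predict(ev)[idx]

            val, _ = foce_subject_objective(compiled.y[idx], fmean, res, omega2)
            assert ov.per_subject_with_constant[i] == pytest.approx(val, abs=5e-4)


class TestObjectiveInvariance:
    def test_subject_order_and_relabeling(self, small_cohort, final_structure, truth_values):
        dataset, _ = small_cohort
        theta, omega2, sigma2 = truth_values
        res = ResidualSpec("proportional", sigma2)
        v1 = foce_objective(dataset, final_structure, theta, omega2, res).value
        import dataclasses

        reordered = PopulationDataset(
            subjects=[
                dataclasses.replace(s, id=f"relabel{k}")
                for k, s in enumerate(reversed(dataset.subjects))
            ]
        )
        v2 = foce_objective(reordered, final_structure, theta, omega2, res).value
        assert v2 == pytest.approx(v1, rel=1e-12)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------


class TestFit:
    def test_noise_free_recovery(self, final_structure):
        cfg = CohortConfig(n_subjects=30, seed=77, omega_cv=0.0, sigma_cv=0.2)
        dataset, _ = simulate_cohort(cfg)
        fr = fit(dataset, final_structure, omega2_init=1e-4,
                 sigma2_prop_init=1e-4, compute_se=False)
        for name, true in [
            ("CL.typical", 0.309), ("CL.WT.exp", 1.55), ("CL.Scr.exp", -0.337),
            ("V.typical", 2.63), ("V.WT.exp", 1.05),
        ]:
            assert fr.estimates[name] == pytest.approx(true, rel=0.01), name

    def test_aic_bic_identities(self, study_fit):
        p = study_fit.n_params
        assert study_fit.aic == pytest.approx(study_fit.ofv + 2 * p)
        assert study_fit.bic == pytest.approx(study_fit.ofv + p * math.log(study_fit.n_obs))
        assert study_fit.condition_number >= 1.0

    def test_fit_outputs_complete(self, study_fit):
        assert study_fit.n_obs == 160
        assert len(study_fit.eta) == 80
        assert len(study_fit.pred) == 160
        assert len(study_fit.obs_table) == 160
        assert study_fit.converged
        assert set(study_fit.rse_percent) == set(study_fit.param_names)

    def test_fit_ofv_not_above_truth_ofv(self, study_compiled, study_fit, final_structure, truth_values):
        theta, omega2, sigma2 = truth_values
        truth_ofv = foce_objective(study_compiled, final_structure, theta, omega2,
                                   ResidualSpec("proportional", sigma2)).value
        assert study_fit.ofv <= truth_ofv + 0.1


# ---------------------------------------------------------------------------
# CWRES
# ---------------------------------------------------------------------------


class TestCwres:
    def test_degenerate_additive_form(self, final_structure):
        """ω = 0 with additive error: CWRES = (DV − PRED)/σ exactly."""
        cfg = CohortConfig(n_subjects=10, seed=31, omega_cv=0.0, sigma_cv=10.0,
                           residual_form="proportional")
        dataset, _ = simulate_cohort(cfg)
        compiled = compile_dataset(dataset, final_structure.covariate_names())
        theta = np.array([0.309, 1.55, -0.337, 2.63, 1.05])
        sigma_add = 0.5
        res = ResidualSpec("additive", sigma2_add=sigma_add**2)
        cw = cwres_at(compiled, final_structure, theta, 0.0, res)
        from neovanc.foce_engine import _InnerModel

        inner = _InnerModel(compiled, final_structure, theta, res)
        pred = inner.predict(np.zeros(compiled.n_subjects))
        assert np.allclose(cw, (compiled.y - pred) / sigma_add, rtol=1e-10)

    def test_calibration_at_fitted_model(self, study_fit):
        """Data simulated from (and refitted by) the model: CWRES ~ N(0,1)."""
        cw = study_fit.cwres
        assert abs(np.mean(cw)) < 0.1
        assert 0.6 < np.var(cw, ddof=1) < 1.4

    def test_perturbed_observation_flagged(self, study_cohort, final_structure, truth_values):
        import copy

        dataset, _ = study_cohort
        theta, omega2, sigma2 = truth_values
        perturbed = copy.deepcopy(dataset)
        obs = perturbed.subjects[0].observations[0]
        import dataclasses

        perturbed.subjects[0].observations[0] = dataclasses.replace(
            obs, value=obs.value * 10.0, below_detection=False, below_calibration=False
        )
        cw = cwres_at(perturbed, final_structure, theta, omega2,
                      ResidualSpec("proportional", sigma2))
        assert abs(cw[0]) > 6.0

    def test_compute_cwres_matches_fit_output(self, study_fit, study_compiled):
        cw = compute_cwres(study_fit, study_compiled)
        assert np.allclose(cw, study_fit.cwres, atol=1e-9)


# ---------------------------------------------------------------------------
# simulation at the observed design
# ---------------------------------------------------------------------------


class TestSimulateDv:
    def test_reproducible(self, study_compiled, final_structure, truth_values):
        theta, omega2, sigma2 = truth_values
        res = ResidualSpec("proportional", sigma2)
        y1 = simulate_dv(study_compiled, final_structure, theta, omega2, res,
                         np.random.default_rng(5))
        y2 = simulate_dv(study_compiled, final_structure, theta, omega2, res,
                         np.random.default_rng(5))
        assert np.array_equal(y1, y2)
        assert np.all(y1 > 0)

    def test_no_noise_returns_predictions(self, study_compiled, final_structure, truth_values):
        theta, _, _ = truth_values
        res = ResidualSpec("proportional", 1e-20)
        y = simulate_dv(study_compiled, final_structure, theta, 0.0, res,
                        np.random.default_rng(0))
        from neovanc.foce_engine import _InnerModel

        inner = _InnerModel(study_compiled, final_structure, theta, res)
        f = inner.predict(np.zeros(study_compiled.n_subjects))
        assert np.allclose(y, f, rtol=1e-6)
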