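import numpy as np
import pytest
import scipy.optimize

from famsrm import (
    RoundRobinData,
    SRMParameterSet,
    StructuralSpec,
    apply_missingness,
    fit_joint_sem,
    fit_srm_fiml,
    fit_srm_ml,
    generate_outcome_condition,
    generate_predictor_condition,
    model_implied_moments,
    wald_tests,
)
from famsrm.estimation import (
    _collect_patterns,
    _MeasurementMVN,
    _MimicMVN,
    _PredictorSEMMVN,
    _start_measurement,
)


def _exact_moment_data(params: SRMParameterSet, n: int = 200, seed: int = 0):
    """A dataset whose sample mean and covariance (ddof=0) are exactly
    (mu(theta), Sigma(theta)): whiten a random draw and recolor."""
    mm = model_implied_moments(params)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 12))
    X = X - X.mean(axis=0)
    S = (X.T @ X) / n
    W = np.linalg.cholesky(np.linalg.inv(S))
    target = np.linalg.cholesky(mm.sigma)
    X = X @ W @ target.T + mm.mean_vector
    return RoundRobinData.from_arrays(X)


class TestMeasurementFit:
    def test_exact_moments_recover_truth(self, default_params):
        data = _exact_moment_data(default_params, n=300, seed=1)
        fit = fit_srm_ml(data, compute_vcov=False)
        assert fit.converged
        truth = np.concatenate([default_params.covariance_vector(),
                                default_params.mu()])
        np.testing.assert_allclose(fit.theta, truth, atol=1e-4)

    def test_fiml_equals_ml_on_complete_data(self, complete_data):
        ml = fit_srm_ml(complete_data, compute_vcov=False)
        fiml = fit_srm_fiml(complete_data, compute_vcov=False)
        assert abs(ml.loglik - fiml.loglik) < 1e-6
        np.testing.assert_allclose(ml.theta, fiml.theta, atol=1e-4)

    def test_parameter_recovery(self, default_params):
        """Estimates at n = 4000 lie within 4 SEs of the generating values."""
        data = generate_predictor_condition(4000, default_params, seed=42)
        fit = fit_srm_ml(data)
        assert fit.converged
        truth = np.concatenate([default_params.covariance_vector(),
                                default_params.mu()])
        se = fit.se()
        assert np.all(np.isfinite(se))
        assert np.all(np.abs(fit.theta - truth) < 4 * se)

    def test_fiml_recovery_under_mar(self, default_params):
        data = generate_predictor_condition(4000, default_params, seed=43)
        data = apply_missingness(data, "dyad_dependent", seed=44, condition="predictor")
        fit = fit_srm_fiml(data)
        assert fit.converged
        truth = np.concatenate([default_params.covariance_vector(),
                                default_params.mu()])
        assert np.all(np.abs(fit.theta - truth) < 4 * fit.se())

    def test_empty_rows_contribute_nothing(self, default_params):
        data = generate_predictor_condition(80, default_params, seed=45)
        fit_a = fit_srm_fiml(data, compute_vcov=False)
        vals = np.vstack([data.values, np.full((5, 12), np.nan)])
        fit_b = fit_srm_fiml(RoundRobinData.from_arrays(vals), compute_vcov=False)
        assert fit_b.patterns.get("empty") == 5
        assert abs(fit_a.loglik - fit_b.loglik) < 1e-6

    def test_requires_two_complete_families(self, default_mm):
        vals = np.tile(default_mm.mean_vector, (3, 1))
        vals[1:, 0] = np.nan
        with pytest.raises(ValueError):
            fit_srm_ml(RoundRobinData.from_arrays(vals))

    def test_vcov_symmetric_psd(self, default_params):
        data = generate_predictor_condition(800, default_params, seed=46)
        fit = fit_srm_ml(data)
        assert fit.converged
        v = fit.vcov
        np.testing.assert_allclose(v, v.T, atol=1e-10)
        assert np.linalg.eigvalsh(v).min() > -1e-8


class TestGradients:
    """Analytic gradients of all three likelihood kinds vs finite differences."""

    @pytest.mark.parametrize("kind", ["measurement", "predictor_sem", "mimic"])
    def test_gradient_matches_numeric(self, kind, default_params):
        if kind == "predictor_sem":
            data = generate_predictor_condition(150, default_params, seed=7)
            V = np.hstack([data.values,
                           np.column_stack([data.outcome(r) for r in "MFTS"])])
            pats, _ = _collect_patterns(V, None)
            model = _PredictorSEMMVN(pats, ["M", "F", "T", "S"])
            theta = np.concatenate([_start_measurement(data),
                                    [0.1, 0.2, 0.1, -0.1, 0.9] * 4])
        elif kind == "mimic":
            data = generate_outcome_condition(150, default_params, seed=8)
            data = apply_missingness(data, "dyad_dependent", 9, condition="outcome")
            pats, _ = _collect_patterns(data.values, data.predictors())
            model = _MimicMVN(pats, 3)
            theta = np.concatenate([_start_measurement(data),
                                    0.05 * np.ones(21)])
        else:
            data = generate_predictor_condition(150, default_params, seed=10)
            data = apply_missingness(data, "dyad_dependent", 11, condition="predictor")
            pats, _ = _collect_patterns(data.values, None)
            model = _MeasurementMVN(pats, 12, 0)
            theta = _start_measurement(data)
        _, g = model.value_and_grad(theta)
        g_num = scipy.optimize.approx_fprime(
            theta, lambda t: model.value_and_grad(t)[0], 1e-6)
        np.testing.assert_allclose(g, g_num, rtol=5e-4, atol=5e-3)


class TestJointSEM:
    def test_zero_structural_collapses_to_measurement(self, default_params):
        gamma = {r: {"intercept": 0.0, "fam": 0.0, "act": 0.0, "par": 0.0,
                     "resid_var": 1.0} for r in "MFTS"}
        data = generate_predictor_condition(1500, default_params, gamma, seed=12)
        joint = fit_joint_sem(data, StructuralSpec("srm_as_predictor"),
                              compute_vcov=False)
        meas = fit_srm_fiml(data, compute_vcov=False)
        assert joint.converged and meas.converged
        np.testing.assert_allclose(joint.theta[:43], meas.theta[:43], atol=0.05)

    def test_predictor_recovery(self, default_params):
        data = generate_predictor_condition(2000, default_params, seed=13)
        fit = fit_joint_sem(data, StructuralSpec("srm_as_predictor"))
        assert fit.converged
        from famsrm import DEFAULT_PREDICTOR_GAMMA

        ses = dict(zip(fit.param_names, fit.se()))
        for r in "MFTS":
            g = DEFAULT_PREDICTOR_GAMMA[r]
            s = fit.structural[r]
            for key, pname in (("fam", f"b_fam_{r}"), ("act", f"b_act_{r}"),
                               ("par", f"b_par_{r}")):
                assert abs(s[f"b_{key}"] - g[key]) < 4 * ses[pname]

    def test_mimic_recovery_and_derived_row(self, default_params):
        from famsrm import DEFAULT_OUTCOME_GAMMA
        from famsrm.estimation import gamma_full_vcov

        data = generate_outcome_condition(3000, default_params, seed=14)
        fit = fit_joint_sem(data, StructuralSpec("srm_as_outcome"))
        assert fit.converged
        # derived fourth rows are exactly minus the sum of the free rows
        np.testing.assert_allclose(fit.gamma[1:5].sum(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.gamma[5:9].sum(axis=0), 0.0, atol=1e-12)
        g_vec, g_vcov = gamma_full_vcov(fit)
        se = np.sqrt(np.diag(g_vcov))
        assert np.all(np.abs(g_vec - DEFAULT_OUTCOME_GAMMA.reshape(-1)) < 4 * se)

    def test_released_constraint_cannot_lower_loglik(self, default_params):
        """MIMIC with free Gamma nests the measurement-only model."""
        data = generate_outcome_condition(400, default_params, seed=15)
        meas = fit_srm_ml(data, compute_vcov=False)
        mimic = fit_joint_sem(data, StructuralSpec("srm_as_outcome"),
                              compute_vcov=False)
        assert mimic.loglik >= meas.loglik - 1e-6

    def test_missing_outcome_column_rejected(self, default_params):
        data = generate_outcome_condition(50, default_params, seed=16)
        with pytest.raises(ValueError):
            fit_joint_sem(data, StructuralSpec("srm_as_predictor"))


class TestWald:
    def test_z_is_estimate_over_se(self, default_params):
        data = generate_predictor_condition(600, default_params, seed=17)
        fit = fit_srm_ml(data)
        table = wald_tests(fit)
        ok = np.isfinite(table["se"])
        np.testing.assert_allclose(table.loc[ok, "z"],
                                   table.loc[ok, "estimate"] / table.loc[ok, "se"])

    def test_zero_estimate_gives_p_one(self):
        from famsrm.estimation import FittedModel

        fit = FittedModel(
            params=SRMParameterSet(), theta=np.array([0.0, 1.0]),
            param_names=("a", "b"), vcov=np.eye(2), loglik=0.0,
            converged=True, implied_pd=True,
        )
        table = wald_tests(fit)
        assert table.loc[0, "z"] == 0.0
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_refuses_non_converged(self):
        from famsrm.estimation import FittedModel

        fit = FittedModel(
            params=SRMParameterSet(), theta=np.zeros(2), param_names=("a", "b"),
            vcov=np.eye(2), loglik=0.0, converged=False, implied_pd=False,
        )
        with pytest.raises(ValueError, match="converge"):
            wald_tests(fit)
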