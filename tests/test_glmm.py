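import numpy as np
import pytest

from fingerkick.errors import ValidationError
from fingerkick.inference import (
    ModelSpec,
    build_design,
    fit_glmm,
    fit_mixed_model,
    marginal_loglik,
)
from fingerkick.simulate import EffectConfig, simulate_parameter_table


def _sim_gaussian(seed, sigma_u=1.2, sigma=0.9, G=21, npg=27, beta=(2.0, 1.5, -0.8)):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(G), npg)
    X = np.column_stack(
        [np.ones(G * npg), rng.normal(size=G * npg), rng.integers(0, 2, G * npg).astype(float)]
    )
    u = rng.normal(0, sigma_u, G)
    y = X @ np.asarray(beta) + u[groups] + rng.normal(0, sigma, G * npg)
    return y, X, groups


class TestGaussianOracles:
    def test_matches_statsmodels_mixedlm_ml(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        y, X, groups = _sim_gaussian(42)
        ours = fit_glmm(y, X, groups, "gaussian")
        ref = MixedLM(y, X, groups).fit(reml=False)
        np.testing.assert_allclose(ours.beta, ref.fe_params, rtol=1e-3)
        np.testing.assert_allclose(ours.loglik, ref.llf, rtol=1e-3)
        np.testing.assert_allclose(
            ours.sigma_u, np.sqrt(np.asarray(ref.cov_re)[0, 0]), rtol=1e-3
        )
        np.testing.assert_allclose(ours.se, ref.bse_fe, rtol=1e-2)

    def test_no_group_variance_matches_ols(self):
        # balanced design (every participant sees every condition equally),
        # where the mixed-model fixed effects coincide with OLS exactly
        cfg = EffectConfig(seed=19)
        cfg.sigma_participant["MH"] = 0.0
        cfg.family_map["MH"] = "gaussian"
        table, _ = simulate_parameter_table(cfg, parameters=["MH"])
        fit = fit_mixed_model(ModelSpec(response="MH", family="gaussian"), table)
        beta_ols, *_ = np.linalg.lstsq(fit.X, fit.y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-4, atol=1e-6)


class TestGammaAndT:
    def test_gamma_intercept_only_closed_form(self):
        rng = np.random.default_rng(1)
        y = rng.gamma(5.0, scale=2.0, size=400)
        fit = fit_glmm(y, np.ones((400, 1)), np.repeat(np.arange(20), 20), "gamma_log")
        # without between-group variation the MLE mean is the sample mean
        assert fit.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-3)
        assert fit.sigma_u < 0.01

    def test_gamma_rejects_nonpositive_response(self):
        y = np.array([1.0, -2.0, 3.0, 4.0])
        with pytest.raises(ValidationError, match="positive"):
            fit_glmm(y, np.ones((4, 1)), np.array([0, 0, 1, 1]), "gamma_log")

    def test_t_family_recovers_scale_and_df_region(self):
        rng = np.random.default_rng(5)
        G, npg = 30, 40
        groups = np.repeat(np.arange(G), npg)
        u = rng.normal(0, 2.0, G)
        y = 10.0 + u[groups] + 1.5 * rng.standard_t(6, G * npg)
        fit = fit_glmm(y, np.ones((G * npg, 1)), groups, "student_t")
        assert fit.converged
        assert fit.dispersion["scale"] == pytest.approx(1.5, rel=0.15)
        assert 3.0 < fit.dispersion["nu"] < 15.0
        assert fit.sigma_u == pytest.approx(2.0, rel=0.25)


class TestLikelihoodProperties:
    def test_loglik_at_least_null_model(self, study_table):
        table, _ = study_table
        fit = fit_mixed_model(ModelSpec(response="MH", family="gaussian"), table)
        # null: intercept-only mean, negligible random-intercept SD
        beta_null = np.zeros_like(fit.beta)
        beta_null[0] = fit.y.mean()
        disp_null = np.array([np.log(fit.y.std())])
        ll_null = marginal_loglik(fit, beta=beta_null, sigma_u=1e-4, disp_raw=disp_null)
        assert fit.loglik >= ll_null

    def test_quadrature_node_invariance(self):
        y, X, groups = _sim_gaussian(3, G=12, npg=15)
        f9 = fit_glmm(y, X, groups, "gaussian", agq_nodes=9)
        f25 = fit_glmm(y, X, groups, "gaussian", agq_nodes=25)
        np.testing.assert_allclose(f9.beta, f25.beta, rtol=1e-3)
        np.testing.assert_allclose(f9.loglik, f25.loglik, rtol=1e-3)

    def test_group_coefficient_is_school_minus_preschool_at_reference(self):
        # construct data with known cell means and tiny noise
        cfg = EffectConfig(
            n_preschool=5, n_school=5, trials_per_condition=20, seed=9,
            mh_group_shift=6.58,
        )
        cfg.sigma_participant["MH"] = 0.05
        cfg.sigma_trial["MH"] = 0.05
        cfg.family_map["MH"] = "gaussian"
        table, truth = simulate_parameter_table(cfg, parameters=["MH"])
        fit = fit_mixed_model(ModelSpec(response="MH", family="gaussian"), table)
        i = fit.terms.index("group[school]")
        assert fit.beta[i] == pytest.approx(truth.effects["MH"]["group[school]"], abs=0.1)
        assert truth.effects["MH"]["group[school]"] == pytest.approx(6.58)

    def test_reference_levels_must_be_present(self, study_table):
        table, _ = study_table
        sub = table[table["group"] == "school"]
        with pytest.raises(ValidationError, match="preschool"):
            fit_mixed_model(ModelSpec(response="MH", family="gaussian"), sub)


class TestDesign:
    def test_design_columns(self, study_table):
        table, _ = study_table
        data = table[table["parameter"] == "MH"].reset_index(drop=True)
        X, names, meta = build_design(data, ModelSpec(response="MH", family="gaussian"))
        assert names[0] == "(Intercept)"
        assert "group[school]" in names
        assert X.shape[1] == 6  # intercept + group + 2 stimulus + 2 interaction
        assert meta["group_levels"][0] == "preschool"
        assert meta["stimulus_levels"][0] == "dots2"

    def test_unknown_family_rejected_eagerly(self):
        with pytest.raises(ValidationError, match="unknown family"):
            ModelSpec(response="MH", family="weibull")
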