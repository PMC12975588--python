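import numpy as np
import pytest

from fingerkick.errors import ValidationError
from fingerkick.inference import (
    ModelSpec,
    emm_contrasts,
    estimated_marginal_means,
    fit_mixed_model,
    r2_nakagawa,
)
from fingerkick.simulate import EffectConfig, simulate_parameter_table


@pytest.fixture(scope="module")
def mh_fit(study_table):
    table, _ = study_table
    return fit_mixed_model(ModelSpec(response="MH", family="gaussian"), table)


class TestContrasts:
    def test_self_contrast_is_zero(self, mh_fit):
        res = emm_contrasts(mh_fit, pairs=[("preschool", "dots2", "dots2")])
        assert res[0].estimate == 0.0
        assert res[0].p_adj == 1.0

    def test_bonferroni_scaling_and_cap(self, mh_fit):
        res1 = emm_contrasts(mh_fit, m=1)
        res4 = emm_contrasts(mh_fit, m=4)
        for a, b in zip(res1, res4):
            assert b.p_adj == pytest.approx(min(1.0, 4 * a.p_raw))
            assert b.p_adj >= a.p_adj  # monotone in m, capped at 1
            assert b.p_adj <= 1.0

    def test_direction_is_first_minus_second(self, mh_fit):
        ab = emm_contrasts(mh_fit, pairs=[("preschool", "baseline", "dots2")])[0]
        ba = emm_contrasts(mh_fit, pairs=[("preschool", "dots2", "baseline")])[0]
        assert ab.estimate == pytest.approx(-ba.estimate)

    def test_balanced_gaussian_contrasts_equal_cell_mean_differences(self):
        cfg = EffectConfig(n_preschool=4, n_school=4, trials_per_condition=15, seed=31)
        cfg.sigma_participant["MH"] = 0.01  # essentially no participant effects
        cfg.family_map["MH"] = "gaussian"
        table, _ = simulate_parameter_table(cfg, parameters=["MH"])
        fit = fit_mixed_model(ModelSpec(response="MH", family="gaussian"), table)
        data = table[table["parameter"] == "MH"]
        emms = estimated_marginal_means(fit)
        for (g, s), emm in emms.items():
            cell = data[(data["group"] == g) & (data["stimulus"] == s)]["value"].mean()
            assert emm == pytest.approx(cell, abs=0.05)
        c = emm_contrasts(fit, pairs=[("school", "dots2", "baseline")])[0]
        d2 = data[(data["group"] == "school") & (data["stimulus"] == "dots2")]["value"].mean()
        bl = data[(data["group"] == "school") & (data["stimulus"] == "baseline")]["value"].mean()
        assert c.estimate == pytest.approx(d2 - bl, abs=0.05)

    def test_absent_level_rejected(self, mh_fit):
        with pytest.raises(ValidationError, match="dots99"):
            emm_contrasts(mh_fit, pairs=[("preschool", "dots99", "dots2")])


class TestR2:
    def test_null_model_marginal_zero(self, study_table):
        table, _ = study_table
        data = table[table["parameter"] == "MH"].reset_index(drop=True)
        from fingerkick.inference import fit_glmm

        fit = fit_glmm(
            data["value"].to_numpy(),
            np.ones((len(data), 1)),
            data["participant_id"].to_numpy(),
            "gaussian",
        )
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.0, abs=1e-6)
        assert r2c > r2m  # participant variance still explains something

    def test_zero_sigma_u_equalizes(self):
        rng = np.random.default_rng(17)
        n = 400
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(0, 1.0, n)
        from fingerkick.inference import fit_glmm

        fit = fit_glmm(y, np.column_stack([np.ones(n), x]), np.repeat(np.arange(20), 20), "gaussian")
        r2m, r2c = r2_nakagawa(fit)
        assert r2c - r2m == pytest.approx(0.0, abs=0.01)

    def test_known_variance_components(self):
        # var_f from a strong group effect; sigma_u and sigma known
        rng = np.random.default_rng(23)
        G, npg = 30, 20
        groups = np.repeat(np.arange(G), npg)
        x = rng.integers(0, 2, G * npg).astype(float)
        sigma_u, sigma, b = 1.0, 1.0, 2.0
        y = b * x + rng.normal(0, sigma_u, G)[groups] + rng.normal(0, sigma, G * npg)
        from fingerkick.inference import fit_glmm

        fit = fit_glmm(y, np.column_stack([np.ones(G * npg), x]), groups, "gaussian")
        r2m, r2c = r2_nakagawa(fit)
        var_f = b**2 * 0.25  # variance of b * Bernoulli(1/2)
        total = var_f + sigma_u**2 + sigma**2
        assert r2m == pytest.approx(var_f / total, abs=0.05)
        assert r2c == pytest.approx((var_f + sigma_u**2) / total, abs=0.05)

    def test_conditional_minus_marginal_tracks_generating_ratio(self):
        # 600 observations; sigma_u precision is set by the participant count,
        # so many participants with few trials each
        cfg = EffectConfig(n_preschool=100, n_school=100, trials_per_condition=1, seed=77)
        cfg.sigma_participant["MH"] = 3.0
        cfg.sigma_trial["MH"] = 3.0
        cfg.family_map["MH"] = "gaussian"
        table, _ = simulate_parameter_table(cfg, parameters=["MH"])
        fit = fit_mixed_model(ModelSpec(response="MH", family="gaussian"), table)
        gen_ratio = 3.0**2 / (3.0**2 + 3.0**2)  # sigma_u^2 / (sigma_u^2 + sigma^2)
        observed = (fit.r2_conditional - fit.r2_marginal) / (1 - fit.r2_marginal)
        assert observed == pytest.approx(gen_ratio, abs=0.05)
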