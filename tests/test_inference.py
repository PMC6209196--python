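"""Mixed-model fitting, AIC selection arithmetic, bootstrap, back-transforms."""

import numpy as np
import pandas as pd
import pytest

from wolfsnow import inference
from wolfsnow.inference import ModelSpec

from conftest import make_mixed_dataset

# Reference fits of the shared make_mixed_dataset(seed=42) fixture computed
# with an independent mixed-model implementation (R lme4: glmer with 9-point
# adaptive quadrature, lmer with REML off). Frozen here as the oracle.
LME4_GLMM = {
    "loglik": -744.567847,
    "sigma": 0.155134,
    "Intercept": -1.039405,
    "time_of_day: night": -0.163803,
    "snowfall_category: control": 0.395395,
    "snowfall_category: two_before": 0.163447,
    "snowfall_category: one_before": 0.575551,
    "snowfall_category: one_after": 0.449367,
    "snowfall_category: two_after": 0.451384,
    "snowfall_category: three_after": 0.457248,
}
LME4_LMM = {
    "loglik": -136.682825,
    "Intercept": 1.032037,
    "time_of_day: night": 0.095226,
}


@pytest.fixture(scope="module")
def oracle_df():
    return make_mixed_dataset(seed=42)


def _spec(response, formula):
    return next(s for s in inference.candidate_models(response) if s.formula == formula)


class TestCandidateSet:
    def test_ten_specs_each_response(self):
        for response in ("log10_speed", "behavior"):
            specs = inference.candidate_models(response)
            assert len(specs) == 10
            assert len({s.formula for s in specs}) == 10

    def test_marginality(self):
        for s in inference.candidate_models("behavior"):
            if s.interaction:
                assert {"snowfall_category", "time_of_day"} <= s.terms

    def test_interaction_without_main_effects_rejected(self):
        with pytest.raises(ValueError, match="interaction"):
            ModelSpec(response="behavior", terms=frozenset({"snow_depth"}),
                      interaction=True, random_structure="intercept_by_wolf")

    def test_random_structures_by_response(self):
        assert all(s.random_structure == "intercept_and_timeofday_slope_by_wolf"
                   for s in inference.candidate_models("log10_speed"))
        assert all(s.random_structure == "intercept_by_wolf"
                   for s in inference.candidate_models("behavior"))


class TestGLMM:
    def test_matches_lme4(self, oracle_df):
        fit = inference.fit_travel_model(oracle_df, _spec("behavior", "snowfall_category + time_of_day"))
        assert fit.converged
        assert fit.loglik == pytest.approx(LME4_GLMM["loglik"], abs=2e-3)
        assert fit.random_effects["sigma"] == pytest.approx(LME4_GLMM["sigma"], abs=2e-3)
        for term, value in LME4_GLMM.items():
            if term in ("loglik", "sigma"):
                continue
            assert fit.params[term] == pytest.approx(value, abs=1e-3), term

    def test_gradient_matches_finite_differences(self, oracle_df):
        spec = _spec("behavior", "time_of_day")
        y, X, names, groups = inference._prepare(oracle_df, spec)
        blocks, _ = inference._glmm_group_blocks(X, y, groups)
        theta = np.array([-0.8, -0.1, np.log(0.25)])
        f0, g = inference._glmm_negloglik_grad(theta, blocks, X.shape[1])
        eps = 1e-6
        for j in range(len(theta)):
            tp = theta.copy(); tp[j] += eps
            tm = theta.copy(); tm[j] -= eps
            fp, _ = inference._glmm_negloglik_grad(tp, blocks, X.shape[1])
            fm, _ = inference._glmm_negloglik_grad(tm, blocks, X.shape[1])
            assert g[j] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4, abs=1e-6)

    def test_zero_variance_agrees_with_plain_glm(self):
        """Data with no wolf effect: GLMM fixed effects within 2 SE of GLM's."""
        import statsmodels.api as sm

        df = make_mixed_dataset(seed=13, re_sd_logit=0.0)
        spec = _spec("behavior", "snowfall_category + time_of_day")
        fit = inference.fit_travel_model(df, spec)
        y, X, names, groups = inference._prepare(df, spec)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        for i, term in enumerate(names):
            assert abs(fit.params[term] - glm.params[i]) < 2 * glm.bse[i], term

    def test_night_effect_recovered_with_bootstrap_ci(self):
        """Simulated night log-odds -0.5 falls inside the bootstrap CI."""
        df = make_mixed_dataset(seed=77)
        fit = inference.fit_travel_model(df, _spec("behavior", "time_of_day"))
        ci = inference.parametric_bootstrap_ci(fit, n_sim=120, seed=5)
        row = ci[ci["term"] == "time_of_day: night"].iloc[0]
        assert row["ci_lower"] < -0.5 < row["ci_upper"]


class TestLMM:
    def test_matches_lme4(self, oracle_df):
        fit = inference.fit_speed_model(oracle_df, _spec("log10_speed", "snowfall_category + time_of_day"))
        assert fit.loglik == pytest.approx(LME4_LMM["loglik"], abs=5e-3)
        assert fit.params["Intercept"] == pytest.approx(LME4_LMM["Intercept"], abs=2e-3)
        assert fit.params["time_of_day: night"] == pytest.approx(LME4_LMM["time_of_day: night"], abs=2e-3)

    def test_travel_rows_only(self, oracle_df):
        fit = inference.fit_speed_model(oracle_df, _spec("log10_speed", "Null model"))
        assert fit.n_obs == (oracle_df["behavior"] == "travel").sum()

    def test_nested_loglik_monotone(self, oracle_df):
        """Adding terms never decreases the ML log-likelihood."""
        fits = {s.formula: inference.fit_speed_model(oracle_df, s)
                for s in inference.candidate_models("log10_speed")}
        nested_pairs = [
            ("Null model", "time_of_day"),
            ("Null model", "snow_depth"),
            ("time_of_day", "snowfall_category + time_of_day"),
            ("snowfall_category + time_of_day", "snowfall_category + time_of_day + snow_depth"),
            ("snowfall_category + time_of_day", "snowfall_category * time_of_day"),
            ("snowfall_category * time_of_day", "snowfall_category * time_of_day + snow_depth"),
        ]
        for small, big in nested_pairs:
            assert fits[big].loglik >= fits[small].loglik - 1e-4, (small, big)


class TestSelection:
    @staticmethod
    def _stub_fits():
        specs = inference.candidate_models("behavior")
        fits = []
        rng = np.random.default_rng(3)
        for i, s in enumerate(specs):
            f = inference.FitResult(
                spec=s, K=inference.expected_K(s), loglik=-1000.0 - 5 * i + rng.normal(),
                params=pd.Series(dtype=float), se=pd.Series(dtype=float),
                random_effects={}, converged=True, n_obs=100,
            )
            fits.append(f)
        return fits

    def test_table_arithmetic(self):
        table = inference.selection_table(self._stub_fits())
        assert len(table) == 10
        np.testing.assert_allclose(table["AIC"], 2 * table["K"] - 2 * table["logL"], atol=1e-10)
        assert table["delta_AIC"].iloc[0] == 0.0
        assert (table["delta_AIC"].diff().dropna() >= 0).all()
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["evidence_ratio"].iloc[0] == 1.0

    def test_single_model_normalizes(self):
        table = inference.selection_table(self._stub_fits()[:1])
        assert table["weight"].iloc[0] == 1.0
        assert table["delta_AIC"].iloc[0] == 0.0

    def test_nonconverged_excluded(self):
        fits = self._stub_fits()
        fits[0].converged = False
        assert len(inference.selection_table(fits)) == 9

    def test_select_best_prefers_parsimony_in_window(self):
        table = pd.DataFrame({
            "formula": ["complex", "simple", "far"],
            "K": [18, 12, 6],
            "AIC": [100.0, 101.9, 120.0],
            "logL": [-32.0, -38.95, -54.0],
            "delta_AIC": [0.0, 1.9, 20.0],
            "weight": [0.6, 0.35, 0.05],
        })
        assert inference.select_best(table)["formula"] == "simple"

    def test_select_best_only_leader_in_window(self):
        table = pd.DataFrame({
            "formula": ["a", "b"], "K": [12, 3],
            "AIC": [100.0, 110.0], "delta_AIC": [0.0, 10.0],
        })
        assert inference.select_best(table)["formula"] == "a"


class TestBackTransform:
    @pytest.mark.parametrize("beta,link,expected", [
        (0.0, "log10", 1.0),
        (0.0, "logit", 1.0),
        (1.0, "log10", 10.0),
        (np.log(2.0), "logit", 2.0),
    ])
    def test_values(self, beta, link, expected):
        assert inference.back_transform(beta, link) == pytest.approx(expected)

    def test_unknown_link(self):
        with pytest.raises(ValueError, match="link"):
            inference.back_transform(1.0, "probit")


class TestBootstrap:
    def test_invalid_level(self, oracle_df):
        fit = inference.fit_travel_model(oracle_df, _spec("behavior", "time_of_day"))
        with pytest.raises(ValueError, match="level"):
            inference.parametric_bootstrap_ci(fit, n_sim=10, level=0.0)

    def test_deterministic_given_seed(self, oracle_df):
        fit = inference.fit_travel_model(oracle_df, _spec("behavior", "time_of_day"))
        a = inference.parametric_bootstrap_ci(fit, n_sim=40, seed=21)
        b = inference.parametric_bootstrap_ci(fit, n_sim=40, seed=21)
        pd.testing.assert_frame_equal(a, b)

    def test_lmm_ci_brackets_estimate(self, oracle_df):
        fit = inference.fit_speed_model(oracle_df, _spec("log10_speed", "time_of_day"))
        ci = inference.parametric_bootstrap_ci(fit, n_sim=60, seed=2)
        assert ((ci["ci_lower"] <= ci["beta"]) & (ci["beta"] <= ci["ci_upper"])).all()
        # transformed columns follow the 10^x map
        np.testing.assert_allclose(ci["beta_transformed"], 10 ** ci["beta"])
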