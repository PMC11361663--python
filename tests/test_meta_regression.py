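"""Excretion-curve fitting, outlier screening, heterogeneity and interactions."""

import numpy as np
import pandas as pd
import pytest

from dairymin import balance_data as bd
from dairymin import meta_regression as mr
from dairymin import synthetic_data as sd


def simulated_obs(mineral="P", seed=0, **overrides):
    params = sd.SimulationParams.for_mineral(mineral, seed=seed, **overrides)
    return params, bd.weighted_observations(sd.simulate_balance_trials(params))


class TestFit:
    def test_noise_free_recovery(self):
        params, obs = simulated_obs(seed=5, beta1=0.2, beta2=1.0,
                                    sigma_study=0.0, sigma_resid=0.0)
        rng = np.random.default_rng(0)
        obs["excretion_mbw"] += rng.normal(0, 1e-7, len(obs))
        fit = mr.fit_excretion_model(obs)
        assert fit.beta1 == pytest.approx(0.2, abs=1e-3)
        assert fit.beta2 == pytest.approx(1.0, abs=1e-3)

    def test_recovers_generating_coefficients_roughly(self, p_fit):
        assert p_fit.beta1 == pytest.approx(0.1352, rel=0.25)
        assert p_fit.beta2 == pytest.approx(1.4010, rel=0.25)
        assert p_fit.var_study > 0 and p_fit.var_resid > 0
        assert p_fit.converged

    def test_single_study_rejected(self):
        _, obs = simulated_obs(seed=1, n_studies=1, treatments_per_study=(6, 6))
        with pytest.raises(ValueError, match="2 studies"):
            mr.fit_excretion_model(obs)

    def test_too_few_observations_rejected(self):
        _, obs = simulated_obs(seed=1, n_studies=3, treatments_per_study=(1, 1))
        with pytest.raises(ValueError, match="fewer than 4"):
            mr.fit_excretion_model(obs.iloc[:3])


class TestPredict:
    def make_fit(self, beta1, beta2):
        return mr.NLMMFit(beta1=beta1, beta2=beta2, se_beta1=0, se_beta2=0,
                          p_beta1=0, p_beta2=0, var_study=0, var_resid=1e-4,
                          loglik=0, n_used=0, n_studies=0, removed_ids=[])

    def test_intercept_at_zero_intake(self):
        fit = self.make_fit(0.1352, 1.4010)
        assert mr.predict_excretion(fit, 0.0) == 0.1352

    @pytest.mark.parametrize("beta1,beta2,intake,expected", [
        (0.1352, 1.4010, 0.62, 0.322),   # P curve at the dataset-mean intake
        (0.3604, 0.5925, 1.45, 0.851),   # Ca curve at the dataset-mean intake
    ])
    def test_curve_values(self, beta1, beta2, intake, expected):
        fit = self.make_fit(beta1, beta2)
        assert mr.predict_excretion(fit, intake) == pytest.approx(expected, abs=5e-4)

    def test_strictly_increasing_when_beta2_positive(self):
        fit = self.make_fit(0.1352, 1.4010)
        grid = np.linspace(0, 2, 50)
        assert (np.diff(mr.predict_excretion(fit, grid)) > 0).all()

    def test_negative_intake_rejected(self):
        with pytest.raises(ValueError):
            mr.predict_excretion(self.make_fit(0.1, 1.0), -0.1)


class TestStudentizedResiduals:
    def test_zero_noise_gives_zero_residuals(self):
        _, obs = simulated_obs(seed=5, sigma_study=0.0, sigma_resid=0.0)
        fit = mr.fit_excretion_model(obs)
        resid = mr.studentized_residuals(fit, obs)
        assert np.abs(resid).max() < 0.01

    def test_mean_near_zero_and_unit_scale(self):
        _, obs = simulated_obs(seed=8, n_studies=300)
        fit = mr.fit_excretion_model(obs)
        resid = mr.studentized_residuals(fit, obs)
        assert abs(resid.mean()) < 0.1
        frac_within_2 = np.mean(np.abs(resid) < 2)
        assert 0.90 < frac_within_2 < 0.99


class TestOutlierLoop:
    def test_planted_outlier_removed(self):
        _, obs = simulated_obs(seed=11)
        target = obs.loc[obs.index[5], "record_id"]
        obs.loc[obs.index[5], "excretion_mbw"] *= 10
        fit = mr.remove_outliers_and_refit(obs)
        assert target in fit.removed_ids
        assert fit.n_used + len(fit.removed_ids) == len(obs)

    def test_clean_data_modest_removal(self):
        _, obs = simulated_obs(seed=13)
        fit = mr.remove_outliers_and_refit(obs, single_pass=True)
        # Gaussian tails: one +/-2 pass removes on the order of 5%
        assert len(fit.removed_ids) <= 0.12 * len(obs)

    def test_runaway_loop_aborts(self):
        _, obs = simulated_obs(seed=11)
        with pytest.raises(mr.FitError, match="50%"):
            mr.remove_outliers_and_refit(obs, threshold=0.05)


class TestHeterogeneity:
    def obs_with_mean_one(self):
        return pd.DataFrame({"excretion_mbw": [0.5, 1.0, 1.5]})

    @pytest.mark.parametrize("var_study,expected_pct,category", [
        (0.0, 0.0, "low"),
        (0.09, 30.0, "moderate"),
        (0.36, 60.0, "high"),
    ])
    def test_categories(self, var_study, expected_pct, category):
        fit = mr.NLMMFit(beta1=1, beta2=1, se_beta1=0, se_beta2=0, p_beta1=0,
                         p_beta2=0, var_study=var_study, var_resid=1e-3,
                         loglik=0, n_used=3, n_studies=2, removed_ids=[])
        rep = mr.heterogeneity_index(fit, self.obs_with_mean_one())
        assert rep.root_var_study_pct == pytest.approx(expected_pct, abs=1e-9)
        assert rep.category == category


class TestInteractions:
    def test_detects_shifted_intercept_stratum(self):
        # double beta1 for studies in the top milk-yield stratum
        params, obs = simulated_obs(seed=21, n_studies=40,
                                    treatments_per_study=(4, 4))
        boost = obs["milk_yield"] > 40
        obs.loc[boost, "excretion_mbw"] += params.beta1 * np.exp(
            params.beta2 * obs.loc[boost, "intake_mbw"])
        res = mr.test_milkyield_interaction(obs)
        assert res.p_intercept_by_group < 0.05

    def test_null_data_gives_large_p(self):
        _, obs = simulated_obs(seed=22, n_studies=40, treatments_per_study=(4, 4))
        res = mr.test_milkyield_interaction(obs)
        assert res.p_intercept_by_group > 0.01
        assert len(res.groups) >= 2

    def test_random_study_detected_random_slope_not(self):
        _, obs = simulated_obs(seed=3)
        res = mr.test_study_by_intake(obs)
        assert res.p_random_study < 0.05
        assert res.p_study_by_intake > 0.05

    def test_requires_three_studies(self):
        _, obs = simulated_obs(seed=2, n_studies=2)
        with pytest.raises(ValueError):
            mr.test_study_by_intake(obs)


class TestMarginalLoglik:
    def test_modes_agree(self, p_obs):
        exact = mr.marginal_loglik(p_obs, 0.14, 1.4, 0.008, 0.005)
        quad = mr.marginal_loglik(p_obs, 0.14, 1.4, 0.008, 0.005,
                                  method="gauss-hermite")
        assert exact == pytest.approx(quad, rel=1e-9)

    def test_unknown_method_rejected(self, p_obs):
        with pytest.raises(ValueError):
            mr.marginal_loglik(p_obs, 0.1, 1.0, 0.01, 0.01, method="mcmc")
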