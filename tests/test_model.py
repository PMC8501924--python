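"""Conditional and marginal likelihood: oracles, invariants, determinism."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import multivariate_normal, poisson

from jointsafety import (AssociationSpec, IntegrationSettings,
                         JointModelParams, RandomEffects, RandomEffectsSpec,
                         SplineSpec, build_longitudinal_design,
                         conditional_loglik, count_log_rate,
                         gh_reference_loglik, longitudinal_mean,
                         marginal_loglik, prepare_likelihood, subject_block)
from jointsafety.model import SubjectBlock, standardized_draws
from jointsafety.simulate import SimulationParams, simulate_trial

from conftest import make_subjects, make_trial

P_LONG = 8


def zero_params(**kw) -> JointModelParams:
    defaults = dict(beta_alt=np.zeros(P_LONG), beta_bili=np.zeros(P_LONG),
                    sigma_eps_alt=1.0, sigma_eps_bili=1.0,
                    beta_conmed=np.zeros(5), beta_ae=np.zeros(5),
                    association=AssociationSpec(),
                    random_effects=RandomEffectsSpec(sds=(0.0, 0.0, 0.0)))
    defaults.update(kw)
    return JointModelParams(**defaults)


@pytest.fixture
def subject():
    return pd.Series({"subject_id": "A", "arm": "AL", "maternal_age": 0.0,
                      "primigravid": False, "trimester": "third",
                      "followup_days": 63.0})


b0 = RandomEffects(0.0, 0.0, 0.0)


class TestLongitudinalMean:
    def test_zero_params_give_zero(self, subject):
        assert longitudinal_mean(zero_params(), subject, 7.0, "alt", b0) == 0.0

    def test_constant_only_returns_the_constant(self, subject):
        beta = np.zeros(P_LONG)
        beta[0] = 2.8221
        p = zero_params(beta_alt=beta)
        for day in (0.0, 14.0, 63.0):
            assert longitudinal_mean(p, subject, day, "alt", b0) \
                == pytest.approx(2.8221)

    def test_additivity_in_the_random_intercept(self, subject):
        p = zero_params()
        delta = 0.37
        base = longitudinal_mean(p, subject, 28.0, "bilirubin", b0)
        shifted = longitudinal_mean(p, subject, 28.0, "bilirubin",
                                    RandomEffects(0.0, delta, 0.0))
        assert shifted - base == pytest.approx(delta)


class TestCountLogRate:
    def test_all_zero_gives_zero_rate(self, subject):
        p = zero_params()
        assert count_log_rate(p, subject, b0, "conmed") == 0.0
        assert count_log_rate(p, subject, b0, "ae", day_eval=63.0) == 0.0

    def test_conmed_intercept_multiplies_rate_via_alpha3(self, subject):
        p = zero_params(association=AssociationSpec(alpha3=1.7487))
        lo = count_log_rate(p, subject, b0, "ae", day_eval=63.0)
        hi = count_log_rate(p, subject, RandomEffects(0.0, 0.0, 1.0), "ae",
                            day_eval=63.0)
        assert np.exp(hi - lo) == pytest.approx(5.7471, abs=1e-4)

    def test_structures_coincide_when_lab_alphas_vanish(self, subject):
        b = RandomEffects(0.4, -0.2, 0.9)
        for a3 in (0.0, 1.2):
            m7 = zero_params(association=AssociationSpec(
                structure="random_effects_m7", alpha3=a3))
            m9 = zero_params(association=AssociationSpec(
                structure="mixed_current_value_m9", alpha3=a3))
            assert count_log_rate(m7, subject, b, "ae") \
                == pytest.approx(count_log_rate(m9, subject, b, "ae",
                                                day_eval=63.0))

    def test_m9_requires_day_eval(self, subject):
        p = zero_params(association=AssociationSpec(alpha1=0.5))
        with pytest.raises(ValueError, match="day_eval"):
            count_log_rate(p, subject, b0, "ae")


class TestConditionalLoglik:
    def test_empty_block_contributes_zero(self, subject):
        block = SubjectBlock(subject=subject, labs=pd.DataFrame(
            columns=["analyte", "day", "log_value"]))
        assert conditional_loglik(zero_params(), block, b0) == 0.0

    def test_perfectly_fitted_lab_record(self, subject):
        sd = 0.7
        labs = pd.DataFrame({"analyte": ["alt"], "day": [0.0],
                             "log_value": [0.0]})
        block = SubjectBlock(subject=subject, labs=labs)
        p = zero_params(sigma_eps_alt=sd)
        expected = -0.5 * np.log(2 * np.pi) - np.log(sd)
        assert conditional_loglik(p, block, b0) == pytest.approx(expected)

    def test_zero_count_term_is_minus_poisson_mean(self, subject):
        block = SubjectBlock(subject=subject,
                             labs=pd.DataFrame(columns=["analyte", "day",
                                                        "log_value"]),
                             ae_count=0, conmed_count=None, day_eval=63.0)
        ll = conditional_loglik(zero_params(), block, b0)
        assert ll == pytest.approx(-63.0 * np.exp(0.0))

    def test_non_integer_count_rejected(self, subject):
        block = SubjectBlock(subject=subject,
                             labs=pd.DataFrame(columns=["analyte", "day",
                                                        "log_value"]),
                             ae_count=1.5, conmed_count=0, day_eval=63.0)
        with pytest.raises(ValueError, match="non-negative integer"):
            conditional_loglik(zero_params(), block, b0)

    def test_increasing_residual_sd_lowers_a_perfect_fit(self, subject):
        labs = pd.DataFrame({"analyte": ["alt"], "day": [0.0],
                             "log_value": [0.0]})
        block = SubjectBlock(subject=subject, labs=labs)
        lls = [conditional_loglik(zero_params(sigma_eps_alt=sd), block, b0)
               for sd in (0.5, 1.0, 2.0)]
        assert lls[0] > lls[1] > lls[2]


class TestMarginalLoglik:
    def test_point_mass_limit_equals_conditional_sum(self, small_sim_trial):
        trial, _ = small_sim_trial
        p = replace(SimulationParams(n_subjects=1).model_params,
                    random_effects=RandomEffectsSpec(sds=(0.0, 0.0, 0.0)))
        ll = marginal_loglik(p, trial, IntegrationSettings(draws=8, seed=0))
        total = sum(conditional_loglik(p, subject_block(trial, sid), b0)
                    for sid in trial.subjects["subject_id"])
        assert ll == pytest.approx(total, abs=1e-8)

    def test_same_seed_is_bit_identical(self, small_sim_trial):
        trial, _ = small_sim_trial
        p = SimulationParams(n_subjects=1).model_params
        s = IntegrationSettings(draws=200, seed=7)
        assert marginal_loglik(p, trial, s) == marginal_loglik(p, trial, s)

    def test_subject_order_invariance(self, small_sim_trial):
        trial, _ = small_sim_trial
        p = SimulationParams(n_subjects=1).model_params
        shuffled = replace(
            trial, subjects=trial.subjects.sample(frac=1, random_state=3)
            .reset_index(drop=True))
        s = IntegrationSettings(draws=100, seed=5)
        assert marginal_loglik(p, trial, s) \
            == marginal_loglik(p, shuffled, s)

    def test_agrees_with_gauss_hermite_reference(self):
        sp = SimulationParams(n_subjects=5, seed=3)
        trial, _ = simulate_trial(sp)
        p = sp.model_params
        qmc = marginal_loglik(p, trial, IntegrationSettings(draws=2000,
                                                            seed=1))
        gh = gh_reference_loglik(p, trial, nodes_per_dim=15)
        assert abs(qmc - gh) < 0.05

    def test_factorizes_when_unlinked(self):
        """alpha = 0 and sd_b = 0: the joint likelihood is the sum of
        independent closed-form Gaussian and Poisson log-likelihoods."""
        sp = SimulationParams(n_subjects=8, seed=9)
        base = sp.model_params
        p = replace(base,
                    association=AssociationSpec(),
                    random_effects=RandomEffectsSpec(sds=(0.0, 0.0, 0.0)))
        trial, _ = simulate_trial(replace(sp, model_params=p))
        ll = marginal_loglik(p, trial, IntegrationSettings(draws=4, seed=0))

        data = prepare_likelihood(trial, p.spline)
        expected = 0.0
        for analyte, beta, sd in (("alt", p.beta_alt, p.sigma_eps_alt),
                                  ("bilirubin", p.beta_bili,
                                   p.sigma_eps_bili)):
            r = data.lab_y[analyte] - data.lab_X[analyte] @ beta
            expected += float(np.sum(-0.5 * np.log(2 * np.pi * sd ** 2)
                                     - r ** 2 / (2 * sd ** 2)))
        for C, beta in ((data.C_cm, p.beta_conmed), (data.C_ae, p.beta_ae)):
            mu = data.T * np.exp(data.X_count @ beta)
            expected += float(poisson.logpmf(C, mu).sum())
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_no_minus_inf_for_extreme_parameters(self, small_sim_trial):
        trial, _ = small_sim_trial
        p = SimulationParams(n_subjects=1).model_params
        wild = replace(p, beta_ae=np.array([30.0, 0, 0, 0, 0]),
                       sigma_eps_alt=1e-3)
        ll = marginal_loglik(wild, trial, IntegrationSettings(draws=16,
                                                              seed=2))
        assert np.isfinite(ll)


class TestGaussHermiteReference:
    def test_matches_closed_form_without_counts(self):
        sp = SimulationParams(n_subjects=5, seed=3)
        trial, _ = simulate_trial(sp)
        p = sp.model_params
        data = prepare_likelihood(trial, p.spline, include_counts=False)
        gh = gh_reference_loglik(p, data, nodes_per_dim=80)

        expected = 0.0
        subs_ix = trial.subjects.set_index("subject_id")
        for analyte, beta, se, sb in (
                ("alt", p.beta_alt, p.sigma_eps_alt,
                 p.random_effects.sds[0]),
                ("bilirubin", p.beta_bili, p.sigma_eps_bili,
                 p.random_effects.sds[1])):
            for sid in trial.subjects["subject_id"]:
                rec = trial.labs[(trial.labs["subject_id"] == sid)
                                 & (trial.labs["analyte"] == analyte)]
                sub = subs_ix.loc[sid].copy()
                sub["subject_id"] = sid
                X = np.stack([build_longitudinal_design(sub, d, p.spline)
                              for d in rec["day"]])
                m = len(rec)
                cov = se ** 2 * np.eye(m) + sb ** 2 * np.ones((m, m))
                expected += multivariate_normal.logpdf(
                    rec["log_value"].to_numpy(), X @ beta, cov)
        assert abs(gh - expected) < 1e-8

    def test_node_sequence_is_cauchy_converging(self):
        sp = SimulationParams(n_subjects=4, seed=13)
        trial, _ = simulate_trial(sp)
        p = sp.model_params
        vals = [gh_reference_loglik(p, trial, g) for g in (7, 15, 21)]
        assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0])

    def test_refuses_student_t_random_effects(self, small_sim_trial):
        trial, _ = small_sim_trial
        p = SimulationParams(n_subjects=1).model_params
        p_t = replace(p, random_effects=RandomEffectsSpec(
            sds=p.random_effects.sds, distribution="student_t", t_df=5))
        with pytest.raises(ValueError, match="gaussian"):
            gh_reference_loglik(p_t, trial, 7)


class TestDraws:
    def test_student_t_draws_are_variance_standardized(self):
        spec = RandomEffectsSpec(sds=(1.0, 1.0, 1.0),
                                 distribution="student_t", t_df=5)
        z = standardized_draws(IntegrationSettings(draws=4000, seed=0), 4,
                               spec)
        assert z.var() == pytest.approx(1.0, abs=0.05)

    def test_antithetic_pairs_mirror(self):
        spec = RandomEffectsSpec(sds=(1.0, 1.0, 1.0))
        z = standardized_draws(
            IntegrationSettings(draws=100, seed=0, antithetic=True), 2, spec)
        assert np.allclose(z[:, :50, :], -z[:, 50:, :])

    def test_draw_count_validated(self):
        with pytest.raises(ValueError, match="draws"):
            IntegrationSettings(draws=0)
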