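"""Likelihood correctness, MAP/MCMC fitting, comparison and contrasts.

The brute-force oracle below replays a session with straight-line
arithmetic (explicit loops, no shared code with the package's vectorized
likelihood) so the two routes are independent.
"""

import numpy as np
import pandas as pd
import pytest

from restless_bandit import (
    FitConfig,
    ModelSpec,
    Params,
    WalkParams,
    compare_models,
    fit_map,
    fit_posterior,
    group_contrast,
    recover_parameters,
    session_log_likelihood,
    simulate_agent,
)
from restless_bandit.inference import SamplerConfig, default_recovery_table

from conftest import make_session

# effectively flat priors: turns MAP into plain maximum likelihood
FLAT = FitConfig(beta_prior_scale=100.0, phi_prior_scale=100.0, rho_prior_sd=100.0)


def bruteforce_loglik(choices_1b, outcomes, beta, phi, rho, wp: WalkParams,
                      prior_mean=50.0, prior_variance=None, bonus_on="sd"):
    """Straight-line bayes+SMEP likelihood trace (the independent oracle)."""
    if prior_variance is None:
        prior_variance = wp.diffusion_sd**2 / (1 - wp.decay**2)
    Q = [prior_mean] * 4
    s2 = [prior_variance] * 4
    last = None
    total = 0.0
    for c1, o in zip(choices_1b, outcomes):
        if c1 is not None:
            c = c1 - 1
            logits = []
            for i in range(4):
                u = s2[i] ** 0.5 if bonus_on == "sd" else s2[i]
                bonus = rho if (last is not None and i == last) else 0.0
                logits.append(beta * Q[i] + phi * u + bonus)
            m = max(logits)
            denom = sum(np.exp(l - m) for l in logits)
            total += logits[c] - m - np.log(denom)
            k = s2[c] / (s2[c] + wp.observation_sd**2)
            Q[c] = Q[c] + k * (o - Q[c])
            s2[c] = (1 - k) * s2[c]
            last = c
        for i in range(4):
            Q[i] = wp.decay * Q[i] + (1 - wp.decay) * wp.decay_center
            s2[i] = wp.decay**2 * s2[i] + wp.diffusion_sd**2
    return total


def test_uniform_policy_closed_form(schedule):
    sess = simulate_agent(ModelSpec("bayes", "SM"), Params(beta=0.0), schedule, seed=1)
    ll = session_log_likelihood(
        ModelSpec("bayes", "SM"), Params(beta=0.0), sess, schedule.walk_params
    )
    assert ll == pytest.approx(300 * np.log(0.25), rel=1e-12)


def test_hand_session_matches_bruteforce(hand_session, walk_params):
    params = Params(beta=0.12, phi=0.7, rho=3.0)
    ll = session_log_likelihood(
        ModelSpec("bayes", "SMEP"), params, hand_session, walk_params
    )
    oracle = bruteforce_loglik(
        [2, 3, 2, None, 1, 4], [60, 45, 70, None, 52, 38],
        0.12, 0.7, 3.0, walk_params,
    )
    assert ll == pytest.approx(oracle, abs=1e-10)


def test_variance_bonus_variant_matches_bruteforce(hand_session, walk_params):
    params = Params(beta=0.12, phi=0.05, rho=3.0)
    ll = session_log_likelihood(
        ModelSpec("bayes", "SMEP", bonus_on="variance"), params,
        hand_session, walk_params,
    )
    oracle = bruteforce_loglik(
        [2, 3, 2, None, 1, 4], [60, 45, 70, None, 52, 38],
        0.12, 0.05, 3.0, walk_params, bonus_on="variance",
    )
    assert ll == pytest.approx(oracle, abs=1e-10)


def test_all_missed_session_has_zero_loglik(walk_params):
    sess = make_session([None] * 6, [None] * 6)
    ll = session_log_likelihood(
        ModelSpec("bayes", "SM"), Params(beta=0.1), sess, walk_params
    )
    assert ll == 0.0


def test_outcome_on_missed_trial_rejected(walk_params):
    sess = make_session([2, None], [60, None])
    sess.loc[1, "outcome"] = 50.0
    with pytest.raises(ValueError, match="missed trial 2"):
        session_log_likelihood(
            ModelSpec("bayes", "SM"), Params(beta=0.1), sess, walk_params
        )


def test_per_trial_probabilities_normalized(smep_session, walk_params):
    from restless_bandit.inference import belief_trace

    spec = ModelSpec("bayes", "SMEP")
    tr = belief_trace(smep_session, spec, walk_params)
    logits = 0.1 * tr.values + 0.8 * tr.uncertainty + 4.0 * tr.persev
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)


def test_fitted_loglik_dominates_generating_params(
    schedule, bayes_smep, smep_params, smep_session
):
    fit = fit_map(bayes_smep, smep_session, schedule.walk_params, FLAT, seed=2)
    gen_ll = session_log_likelihood(
        bayes_smep, smep_params, smep_session, schedule.walk_params
    )
    assert fit.log_likelihood >= gen_ll - 1e-6


def test_nesting_never_hurts_maximized_loglik(schedule, smep_session):
    lls = {}
    for choice_rule in ("SM", "SME", "SMP", "SMEP"):
        fit = fit_map(
            ModelSpec("bayes", choice_rule), smep_session,
            schedule.walk_params, FLAT, seed=3,
        )
        lls[choice_rule] = fit.log_likelihood
    assert lls["SME"] >= lls["SM"] - 1e-6
    assert lls["SMP"] >= lls["SM"] - 1e-6
    assert lls["SMEP"] >= max(lls["SME"], lls["SMP"]) - 1e-6


def test_uniform_data_recovers_near_zero_beta(schedule):
    sess = simulate_agent(ModelSpec("bayes", "SM"), Params(beta=0.0), schedule, seed=9)
    fit = fit_map(ModelSpec("bayes", "SM"), sess, schedule.walk_params, seed=9)
    assert fit.point_estimates.beta < 0.02


def test_fit_is_deterministic(schedule, bayes_smep, smep_session):
    a = fit_map(bayes_smep, smep_session, schedule.walk_params, seed=11)
    b = fit_map(bayes_smep, smep_session, schedule.walk_params, seed=11)
    assert a.point_estimates == b.point_estimates
    assert a.posterior_summaries == b.posterior_summaries


def test_single_trial_session_fits_without_crash(walk_params):
    sess = make_session([2], [60])
    fit = fit_map(ModelSpec("bayes", "SM"), sess, walk_params, seed=0)
    s = fit.posterior_summaries["beta"]
    assert s["lo95"] < s["hi95"]
    assert fit.n_valid_trials == 1
    assert np.isfinite(fit.bic)


def test_information_criteria_consistency(schedule, bayes_smep, smep_session):
    fit = fit_map(bayes_smep, smep_session, schedule.walk_params, seed=1)
    k, ll, n = 3, fit.log_likelihood, fit.n_valid_trials
    assert fit.aic == pytest.approx(2 * k - 2 * ll)
    assert fit.bic == pytest.approx(k * np.log(n) - 2 * ll)
    assert ll <= 0


def test_compare_models_requires_two_specs(smep_session, walk_params):
    with pytest.raises(ValueError, match="at least 2"):
        compare_models(smep_session, [ModelSpec("bayes", "SM")], walk_params)


def test_compare_models_ranks_and_reports(schedule, smep_session):
    specs = [ModelSpec("bayes", c) for c in ("SM", "SMEP")]
    table = compare_models(smep_session, specs, schedule.walk_params, seed=4)
    assert set(table["model"]) == {"bayes+SM", "bayes+SMEP"}
    assert table["bic"].is_monotonic_increasing
    assert (table["error"] == "").all()


def test_posterior_sampling_agrees_with_map(schedule, smep_session):
    spec = ModelSpec("bayes", "SMEP")
    scfg = SamplerConfig(n_walkers=12, n_steps=400, n_burn=200, thin=2)
    post = fit_posterior(spec, smep_session, schedule.walk_params,
                         sampler_config=scfg, seed=21)
    mapfit = fit_map(spec, smep_session, schedule.walk_params, seed=21)
    for name in ("beta", "phi", "rho"):
        mu, sd = post.posterior_summaries[name]["mean"], post.posterior_summaries[name]["sd"]
        assert abs(mu - mapfit.posterior_summaries[name]["mean"]) < 3 * max(sd, 1e-6)
    assert "max_rhat" in post.diagnostics


def test_posterior_sampling_deterministic(schedule, hand_session):
    spec = ModelSpec("bayes", "SM")
    scfg = SamplerConfig(n_walkers=8, n_steps=120, n_burn=60)
    a = fit_posterior(spec, hand_session, schedule.walk_params, sampler_config=scfg, seed=5)
    b = fit_posterior(spec, hand_session, schedule.walk_params, sampler_config=scfg, seed=5)
    assert a.posterior_summaries == b.posterior_summaries


def test_zero_draw_sampler_config_rejected():
    with pytest.raises(ValueError):
        SamplerConfig(n_steps=0)


def _mock_fit(spec, mean):
    from restless_bandit.inference import FitResult

    return FitResult(
        spec=spec,
        point_estimates=Params(beta=mean),
        posterior_summaries={"beta": {"mean": mean, "sd": 0.01,
                                      "lo95": mean - 0.02, "hi95": mean + 0.02}},
        log_likelihood=-100.0,
        n_valid_trials=300,
        aic=0.0,
        bic=0.0,
    )


def test_group_contrast_identical_groups_straddles_zero():
    spec = ModelSpec("bayes", "SM")
    fits = [_mock_fit(spec, m) for m in (0.08, 0.10, 0.12, 0.09)]
    c = group_contrast(fits, fits, "beta", seed=0)
    assert c.m_diff == 0.0
    assert c.lo95 <= 0.0 <= c.hi95


def test_group_contrast_degenerate_single_subjects():
    spec = ModelSpec("bayes", "SM")
    with pytest.warns(UserWarning, match="degenerate"):
        c = group_contrast([_mock_fit(spec, 0.1)], [_mock_fit(spec, 0.2)], "beta")
    assert c.degenerate and c.m_diff == pytest.approx(-0.1)


def test_group_contrast_inactive_parameter_rejected():
    spec = ModelSpec("bayes", "SM")
    fits = [_mock_fit(spec, 0.1), _mock_fit(spec, 0.2)]
    with pytest.raises(ValueError, match="rho"):
        group_contrast(fits, fits, "rho")


def test_recovery_requires_ten_rows(schedule):
    spec = ModelSpec("bayes", "SM")
    with pytest.raises(ValueError, match="at least 10"):
        recover_parameters(spec, pd.DataFrame({"beta": [0.1] * 5}), schedule)


def test_recovery_report_reproducible_and_sane(schedule):
    spec = ModelSpec("bayes", "SM")
    cfg = FitConfig(n_starts=4, laplace_draws=100)
    table = default_recovery_table(spec, 10, seed=3)
    a = recover_parameters(spec, table, schedule, cfg, seed=3)
    b = recover_parameters(spec, table, schedule, cfg, seed=3)
    assert a.table.equals(b.table)
    assert (a.stats["spearman_rho"].abs() <= 1.0).all()
    assert (a.table["error"] == "").all()


def test_greedy_regime_identified(schedule):
    """Near-greedy generating beta comes back large (regime recovery)."""
    spec = ModelSpec("bayes", "SM")
    sess = simulate_agent(spec, Params(beta=2.0), schedule, seed=13)
    fit = fit_map(spec, sess, schedule.walk_params, FLAT, seed=13)
    assert fit.point_estimates.beta > 0.5
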