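"""Learning updates, softmax policies and agent simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restless_bandit import (
    BeliefState,
    ModelSpec,
    Params,
    WalkParams,
    choice_probabilities,
    delta_update,
    diffuse_beliefs,
    generate_schedule,
    init_beliefs,
    kalman_update,
    simulate_agent,
)


def test_default_beliefs_are_symmetric(walk_params):
    b = init_beliefs(ModelSpec("bayes", "SMEP"), walk_params=walk_params)
    assert np.allclose(b.values, 50.0)
    assert np.allclose(b.variances, walk_params.stationary_variance)
    assert b.last_choice is None and (b.trials_since_chosen == 0).all()
    d = init_beliefs(ModelSpec("delta", "SM"))
    assert d.variances is None


def test_negative_prior_variance_rejected():
    with pytest.raises(ValueError, match="prior variance"):
        init_beliefs(ModelSpec("bayes", "SM"), prior_variance=-1.0)


def test_delta_update_arithmetic():
    b = init_beliefs(ModelSpec("delta", "SM"))
    out = delta_update(b, 0, 70.0, alpha=0.5)
    assert out.values[0] == 60.0
    assert np.allclose(out.values[1:], 50.0)
    assert out.last_choice == 0 and out.trials_since_chosen[0] == 0
    # zero prediction error leaves the value untouched for any alpha
    for alpha in (0.1, 0.5, 0.9):
        assert delta_update(b, 2, 50.0, alpha).values[2] == 50.0
    with pytest.raises(ValueError, match="alpha"):
        delta_update(b, 0, 70.0, alpha=1.0)


def test_kalman_update_hand_derived(walk_params):
    # s^2 = 36, sigma_o^2 = 16: kappa = 36/52, Q = 50 + (36/52)*26 = 68
    b = BeliefState(values=np.full(4, 50.0), variances=np.full(4, 36.0))
    out = kalman_update(b, 1, 76.0, walk_params)
    assert out.values[1] == pytest.approx(68.0, abs=1e-12)
    assert out.variances[1] == pytest.approx(16.0 * 36.0 / 52.0, abs=1e-10)
    assert np.allclose(out.values[[0, 2, 3]], 50.0)
    assert np.allclose(out.variances[[0, 2, 3]], 36.0)


def test_kalman_gain_half_when_variance_matches_observation_noise(walk_params):
    s2 = walk_params.observation_sd**2
    b = BeliefState(values=np.full(4, 50.0), variances=np.full(4, s2))
    out = kalman_update(b, 0, 60.0, walk_params)
    assert out.values[0] == pytest.approx(55.0, abs=1e-12)


def test_kalman_uninformative_prior_limit(walk_params):
    b = BeliefState(values=np.full(4, 50.0), variances=np.full(4, 1e12))
    out = kalman_update(b, 0, 83.0, walk_params)
    assert out.values[0] == pytest.approx(83.0, abs=1e-6)


def test_kalman_observation_strictly_shrinks_variance(walk_params):
    b = init_beliefs(ModelSpec("bayes", "SM"), walk_params=walk_params)
    out = kalman_update(b, 0, 55.0, walk_params)
    assert out.variances[0] < b.variances[0]


def test_diffusion_fixed_points(walk_params):
    b = init_beliefs(ModelSpec("bayes", "SM"), prior_mean=50.0, walk_params=walk_params)
    out = diffuse_beliefs(b, walk_params)
    assert np.allclose(out.values, 50.0)  # theta is the mean fixed point
    # variance recursion converges monotonically to sigma_d^2/(1-lambda^2)
    # at geometric rate lambda^2, so the gap shrinks by ~0.967 per step
    target = walk_params.stationary_variance
    b = BeliefState(values=np.full(4, 50.0), variances=np.full(4, 1.0))
    gaps = []
    for _ in range(800):
        b = diffuse_beliefs(b, walk_params)
        gaps.append(abs(b.variances[0] - target))
    assert gaps[499] < 2e-5  # (target - 1) * lambda^(2*500)
    assert gaps[-1] < 1e-6
    assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gaps, gaps[1:]))
    # a bandit starting at the stationary prior sits exactly on the fixed point
    b = init_beliefs(ModelSpec("bayes", "SM"), walk_params=walk_params)
    for _ in range(500):
        b = diffuse_beliefs(b, walk_params)
    assert abs(b.variances[0] - target) < 1e-6


def test_delta_equals_kalman_mean_update_with_pinned_gain(walk_params):
    """Pinning the Kalman gain to alpha reproduces the delta mean update."""
    alpha = 0.3
    s2 = alpha / (1 - alpha) * walk_params.observation_sd**2
    kb = BeliefState(values=np.full(4, 42.0), variances=np.full(4, s2))
    db = BeliefState(values=np.full(4, 42.0))
    k = kalman_update(kb, 2, 77.0, walk_params)
    d = delta_update(db, 2, 77.0, alpha)
    assert k.values[2] == pytest.approx(d.values[2], abs=1e-10)


def test_longest_unchosen_bandit_has_largest_variance(walk_params):
    """Starting equal, the bandit unchosen longest is the most uncertain."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        b = init_beliefs(ModelSpec("bayes", "SMEP"), walk_params=walk_params)
        for _ in range(rng.integers(5, 40)):
            c = int(rng.integers(0, 4))
            b = kalman_update(b, c, float(rng.integers(0, 101)), walk_params)
            b = diffuse_beliefs(b, walk_params)
        counts = b.trials_since_chosen
        if (counts == counts.max()).sum() == 1 and counts.max() > 0:
            assert np.argmax(b.variances) == np.argmax(counts)
            others = np.delete(b.variances, np.argmax(counts))
            assert b.variances[np.argmax(counts)] > others.max()


def test_uniform_and_greedy_softmax_limits():
    b = BeliefState(values=np.array([60.0, 50.0, 40.0, 30.0]))
    spec = ModelSpec("delta", "SM")
    p = choice_probabilities(b, Params(alpha=0.5, beta=0.0), spec)
    assert np.allclose(p, 0.25)
    p = choice_probabilities(b, Params(alpha=0.5, beta=50.0), spec)
    assert p[0] > 1 - 1e-9


def test_softmax_hand_computed_probabilities():
    b = BeliefState(values=np.array([60.0, 50.0, 40.0, 30.0]))
    p = choice_probabilities(b, Params(alpha=0.5, beta=0.1), ModelSpec("delta", "SM"))
    expected = np.exp([6.0, 5.0, 4.0, 3.0])
    expected /= expected.sum()
    assert np.allclose(p, expected, atol=1e-12)
    assert np.allclose(p, [0.6439, 0.2369, 0.0871, 0.0321], atol=5e-5)


@settings(derandomize=True, max_examples=60)
@given(
    q=st.lists(st.floats(-100, 200), min_size=4, max_size=4),
    s2=st.lists(st.floats(0.1, 500), min_size=4, max_size=4),
    beta=st.floats(0, 5),
    phi=st.floats(0, 3),
    rho=st.floats(-8, 8),
    last=st.integers(0, 3),
)
def test_choice_probabilities_sum_to_one(q, s2, beta, phi, rho, last):
    b = BeliefState(
        values=np.array(q), variances=np.array(s2), last_choice=last
    )
    p = choice_probabilities(
        b, Params(beta=beta, phi=phi, rho=rho), ModelSpec("bayes", "SMEP")
    )
    assert abs(p.sum() - 1.0) < 1e-12
    assert (p >= 0).all()


def test_perseveration_bonus_favours_last_choice():
    b = BeliefState(values=np.full(4, 50.0), last_choice=3)
    p = choice_probabilities(
        b, Params(alpha=0.5, beta=0.1, rho=2.0), ModelSpec("delta", "SMP")
    )
    assert p[3] > p[0]


def test_uniform_agent_choice_frequencies(schedule):
    spec = ModelSpec("bayes", "SM")
    sess = simulate_agent(spec, Params(beta=0.0), schedule, seed=4)
    freqs = sess["choice"].value_counts(normalize=True)
    assert np.allclose(freqs, 0.25, atol=3 * np.sqrt(0.25 * 0.75 / 300))


def test_all_missed_session(schedule):
    sess = simulate_agent(
        ModelSpec("bayes", "SM"), Params(beta=0.1), schedule, seed=4, missed_rate=1.0
    )
    assert (sess["missed"] == 1).all()
    assert sess["choice"].isna().all() and sess["outcome"].isna().all()


def test_greedy_bayes_agent_beats_chance(schedule):
    sess = simulate_agent(
        ModelSpec("bayes", "SMEP"),
        Params(beta=1.0, phi=0.5, rho=0.0),
        schedule,
        seed=5,
    )
    best = np.argmax(schedule.means, axis=0) + 1
    hit = (sess["choice"].to_numpy() == best).mean()
    assert hit > 0.4  # well above the 0.25 chance level


def test_simulation_is_deterministic_under_seed(schedule, bayes_smep, smep_params):
    a = simulate_agent(bayes_smep, smep_params, schedule, seed=6, missed_rate=0.03)
    b = simulate_agent(bayes_smep, smep_params, schedule, seed=6, missed_rate=0.03)
    assert a.equals(b)


def test_inactive_parameters_rejected():
    with pytest.raises(ValueError, match="phi"):
        Params(beta=0.1, phi=1.0).validate_for(ModelSpec("bayes", "SM"))
    with pytest.raises(ValueError, match="alpha"):
        Params(beta=0.1).validate_for(ModelSpec("delta", "SM"))
    with pytest.raises(ValueError, match="learning_rule"):
        ModelSpec("qlearn", "SM")


def test_session_shorter_schedule_rejected():
    sched = generate_schedule(n_trials=10, seed=0)
    with pytest.raises(IndexError):
        simulate_agent(
            ModelSpec("bayes", "SM"), Params(beta=0.1), sched, seed=0, n_trials=11
        )
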