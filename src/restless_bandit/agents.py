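"""Learning rules, choice rules and agent simulation.

Eight model variants are formed by crossing two learning rules with four
softmax choice rules:

* learning rules — ``delta`` (Rescorla–Wagner update with learning rate
  alpha) and ``bayes`` (Kalman filter tracking each bandit's posterior mean
  and variance against the known walk dynamics);
* choice rules — ``SM`` (plain softmax), ``SME`` (softmax + exploration
  bonus phi), ``SMP`` (softmax + perseveration bonus rho) and ``SMEP``
  (both bonuses).

The choice propensity of bandit c is

    logit(c) = beta * Q_c + phi * u_c + rho * 1[c == last choice]

where beta (inverse temperature / reward sensitivity) scales only the
estimated value, u_c is the bandit's uncertainty (posterior SD by default
for the Bayesian learner; trials-since-last-chosen recency for the delta
learner, which tracks no variance), and the perseveration indicator
compares against the last *made* choice (missed trials do not reset it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .task import Schedule, WalkParams

__all__ = [
    "LEARNING_RULES",
    "CHOICE_RULES",
    "ALL_SPECS",
    "ModelSpec",
    "Params",
    "BeliefState",
    "init_beliefs",
    "delta_update",
    "kalman_update",
    "diffuse_beliefs",
    "choice_probabilities",
    "simulate_agent",
]

LEARNING_RULES = ("delta", "bayes")
CHOICE_RULES = ("SM", "SME", "SMP", "SMEP")


@dataclass(frozen=True)
class ModelSpec:
    """A learning rule crossed with a choice rule.

    ``bonus_on`` selects whether the exploration bonus of the Bayesian
    learner multiplies the posterior standard deviation (default, the
    classical form) or the posterior variance.
    """

    learning_rule: str
    choice_rule: str
    bonus_on: str = "sd"

    def __post_init__(self) -> None:
        if self.learning_rule not in LEARNING_RULES:
            raise ValueError(
                f"learning_rule must be one of {LEARNING_RULES}, "
                f"got {self.learning_rule!r}"
            )
        if self.choice_rule not in CHOICE_RULES:
            raise ValueError(
                f"choice_rule must be one of {CHOICE_RULES}, "
                f"got {self.choice_rule!r}"
            )
        if self.bonus_on not in ("sd", "variance"):
            raise ValueError(f"bonus_on must be 'sd' or 'variance', got {self.bonus_on!r}")

    @property
    def has_exploration_bonus(self) -> bool:
        return self.choice_rule in ("SME", "SMEP")

    @property
    def has_perseveration_bonus(self) -> bool:
        return self.choice_rule in ("SMP", "SMEP")

    @property
    def active_parameters(self) -> tuple[str, ...]:
        names = []
        if self.learning_rule == "delta":
            names.append("alpha")
        names.append("beta")
        if self.has_exploration_bonus:
            names.append("phi")
        if self.has_perseveration_bonus:
            names.append("rho")
        return tuple(names)

    @property
    def label(self) -> str:
        return f"{self.learning_rule}+{self.choice_rule}"

    @classmethod
    def from_label(cls, label: str, bonus_on: str = "sd") -> "ModelSpec":
        learning, _, choice = label.partition("+")
        return cls(learning_rule=learning, choice_rule=choice, bonus_on=bonus_on)


#: The eight model variants, delta first, in increasing choice-rule order.
ALL_SPECS = tuple(
    ModelSpec(lr, cr) for lr in LEARNING_RULES for cr in CHOICE_RULES
)


@dataclass(frozen=True)
class Params:
    """Decision parameters; only those active for the spec may be set.

    alpha : learning rate, in (0, 1), delta rule only.
    beta  : inverse temperature (reward sensitivity), 1/points, >= 0.
    phi   : exploration bonus weight (per uncertainty unit), SME/SMEP.
    rho   : perseveration bonus, softmax-logit units, SMP/SMEP.
    """

    alpha: float | None = None
    beta: float = 0.1
    phi: float | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    def validate_for(self, spec: ModelSpec) -> None:
        active = set(spec.active_parameters)
        for name in ("alpha", "beta", "phi", "rho"):
            value = getattr(self, name)
            if value is not None and name not in active:
                raise ValueError(
                    f"parameter {name!r} is not active for model {spec.label}"
                )
            if value is None and name in active:
                raise ValueError(
                    f"parameter {name!r} is required for model {spec.label}"
                )

    def to_dict(self) -> dict[str, float | None]:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "phi": self.phi,
            "rho": self.rho,
        }


@dataclass
class BeliefState:
    """Per-bandit value estimates (and Bayesian variances) at a trial.

    ``values`` and, for the Bayesian learner, ``variances`` hold one entry
    per bandit. ``trials_since_chosen`` counts trials since the bandit was
    last chosen (starts at 0 for all bandits, increments every trial, and
    resets on choice); ``last_choice`` is the last *made* choice.
    """

    values: np.ndarray
    variances: np.ndarray | None = None
    last_choice: int | None = None
    trials_since_chosen: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.variances is not None:
            self.variances = np.asarray(self.variances, dtype=float)
            if (self.variances <= 0).any():
                raise ValueError("belief variances must be strictly positive")
        if self.trials_since_chosen is None:
            self.trials_since_chosen = np.zeros(self.values.shape[0], dtype=np.int64)

    @property
    def n_bandits(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "BeliefState":
        return BeliefState(
            values=self.values.copy(),
            variances=None if self.variances is None else self.variances.copy(),
            last_choice=self.last_choice,
            trials_since_chosen=self.trials_since_chosen.copy(),
        )


def init_beliefs(
    spec: ModelSpec,
    n_bandits: int = 4,
    prior_mean: float = 50.0,
    prior_variance: float | None = None,
    walk_params: WalkParams | None = None,
) -> BeliefState:
    """Symmetric initial beliefs.

    The prior mean defaults to the walk's attractor (50 points); the prior
    variance, used by the Bayesian learner only, defaults to the walk's
    stationary variance sigma_d^2 / (1 - lambda^2).
    """
    if prior_variance is None:
        wp = walk_params if walk_params is not None else WalkParams()
        prior_variance = wp.stationary_variance
    if prior_variance <= 0:
        raise ValueError(f"prior variance must be > 0, got {prior_variance}")
    variances = (
        np.full(n_bandits, float(prior_variance))
        if spec.learning_rule == "bayes"
        else None
    )
    return BeliefState(
        values=np.full(n_bandits, float(prior_mean)),
        variances=variances,
        last_choice=None,
        trials_since_chosen=np.zeros(n_bandits, dtype=np.int64),
    )


def _advance_counters(beliefs: BeliefState, choice: int) -> None:
    beliefs.trials_since_chosen += 1
    beliefs.trials_since_chosen[choice] = 0
    beliefs.last_choice = choice


def delta_update(
    beliefs: BeliefState, choice: int, outcome: float, alpha: float
) -> BeliefState:
    """Rescorla–Wagner update of the chosen bandit's value."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if not 0 <= choice < beliefs.n_bandits:
        raise IndexError(f"choice {choice} out of range")
    out = beliefs.copy()
    out.values[choice] += alpha * (outcome - out.values[choice])
    _advance_counters(out, choice)
    return out


def kalman_update(
    beliefs: BeliefState, choice: int, outcome: float, walk_params: WalkParams
) -> BeliefState:
    """Kalman observation step for the chosen bandit.

    gain  kappa = s_c^2 / (s_c^2 + sigma_o^2)
    mean  Q_c  <- Q_c + kappa * (outcome - Q_c)
    var   s_c^2 <- (1 - kappa) * s_c^2
    """
    if beliefs.variances is None:
        raise ValueError("kalman_update requires Bayesian beliefs with variances")
    if not 0 <= choice < beliefs.n_bandits:
        raise IndexError(f"choice {choice} out of range")
    out = beliefs.copy()
    s2 = out.variances[choice]
    kappa = s2 / (s2 + walk_params.observation_sd**2)
    out.values[choice] += kappa * (outcome - out.values[choice])
    out.variances[choice] = (1.0 - kappa) * s2
    _advance_counters(out, choice)
    return out


def diffuse_beliefs(beliefs: BeliefState, walk_params: WalkParams) -> BeliefState:
    """Between-trial prediction step tracking the decaying walk.

    Every bandit's mean decays toward the attractor and its variance grows:
    Q <- lambda*Q + (1-lambda)*theta;  s^2 <- lambda^2*s^2 + sigma_d^2.
    """
    if beliefs.variances is None:
        raise ValueError("diffuse_beliefs requires Bayesian beliefs with variances")
    lam, theta = walk_params.decay, walk_params.decay_center
    out = beliefs.copy()
    out.values = lam * out.values + (1.0 - lam) * theta
    out.variances = lam**2 * out.variances + walk_params.diffusion_sd**2
    return out


def _uncertainty(beliefs: BeliefState, spec: ModelSpec) -> np.ndarray:
    if spec.learning_rule == "bayes":
        assert beliefs.variances is not None
        return (
            np.sqrt(beliefs.variances)
            if spec.bonus_on == "sd"
            else beliefs.variances
        )
    # Delta learner tracks no variance: recency stands in for uncertainty.
    return beliefs.trials_since_chosen.astype(float)


def choice_logits(
    beliefs: BeliefState, params: Params, spec: ModelSpec
) -> np.ndarray:
    logits = params.beta * beliefs.values
    if spec.has_exploration_bonus:
        logits = logits + (params.phi or 0.0) * _uncertainty(beliefs, spec)
    if spec.has_perseveration_bonus and beliefs.last_choice is not None:
        persev = np.zeros(beliefs.n_bandits)
        persev[beliefs.last_choice] = 1.0
        logits = logits + (params.rho or 0.0) * persev
    return logits


def choice_probabilities(
    beliefs: BeliefState, params: Params, spec: ModelSpec
) -> np.ndarray:
    """Softmax choice probabilities (overflow-safe, sums to 1)."""
    logits = choice_logits(beliefs, params, spec)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError(f"non-finite choice logits: {logits}")
    return np.exp(logits - logsumexp(logits))


def simulate_agent(
    spec: ModelSpec,
    params: Params,
    schedule: Schedule,
    seed: int,
    missed_rate: float = 0.0,
    *,
    subject: str = "sim",
    n_trials: int | None = None,
    prior_mean: float = 50.0,
    prior_variance: float | None = None,
) -> pd.DataFrame:
    """Simulate one session and return it as a trials table.

    Per trial: with probability ``missed_rate`` the trial is missed (no
    choice, no outcome, no observation update — the Bayesian prediction
    step still runs); otherwise the choice is sampled from the softmax
    policy, the payout is read from the schedule, the learning update is
    applied and then (Bayesian learner) the beliefs diffuse. Reaction
    times are decorative lognormal draws clipped to the 1.5-s deadline.

    Columns follow the session-file convention: ``subject``, ``trial``
    (1-based), ``block`` (1-based 50-trial blocks), ``choice`` (1-based or
    missing), ``outcome``, ``rt_s``, ``missed`` (0/1), ``schedule_id``.
    """
    params.validate_for(spec)
    if not 0.0 <= missed_rate <= 1.0:
        raise ValueError(f"missed_rate must lie in [0, 1], got {missed_rate}")
    T = schedule.n_trials if n_trials is None else n_trials
    if T > schedule.n_trials:
        raise IndexError(
            f"requested {T} trials but schedule has only {schedule.n_trials}"
        )
    rng = np.random.default_rng(seed)
    wp = schedule.walk_params
    beliefs = init_beliefs(
        spec,
        n_bandits=schedule.n_bandits,
        prior_mean=prior_mean,
        prior_variance=prior_variance,
        walk_params=wp,
    )
    rows: list[dict] = []
    for t in range(T):
        missed = bool(rng.random() < missed_rate)
        if missed:
            choice_1b: float = np.nan
            outcome: float = np.nan
            rt: float = np.nan
            # Time still elapses: recency counters advance, last_choice stays.
            beliefs.trials_since_chosen += 1
        else:
            probs = choice_probabilities(beliefs, params, spec)
            choice = int(rng.choice(schedule.n_bandits, p=probs))
            outcome = float(schedule.payouts[choice, t])
            rt = float(np.clip(rng.lognormal(np.log(0.55), 0.25), 0.15, 1.5))
            if spec.learning_rule == "delta":
                beliefs = delta_update(beliefs, choice, outcome, params.alpha)
            else:
                beliefs = kalman_update(beliefs, choice, outcome, wp)
            choice_1b = choice + 1
        if spec.learning_rule == "bayes":
            beliefs = diffuse_beliefs(beliefs, wp)
        rows.append(
            {
                "subject": subject,
                "trial": t + 1,
                "block": t // 50 + 1,
                "choice": choice_1b,
                "outcome": outcome,
                "rt_s": rt,
                "missed": int(missed),
                "schedule_id": schedule.instantiation_id,
            }
        )
    return pd.DataFrame(rows)
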