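"""Choice-type classification and model-free behavioural metrics.

Every valid trial is labelled with exactly one of three decision types:

* ``exploit`` — the choice had the highest estimated value (ties count as
  exploitation if the chosen bandit is any argmax);
* ``directed`` — a lower-valued choice of the *designated* exploration
  target: the bandit with the most uncertain value (Bayesian learner) or
  the one least recently chosen (delta learner, which tracks no variance).
  Under the Bayesian learner with shared dynamics these two definitions
  coincide. Exactly one bandit per trial is the directed target; recency
  ties break toward the lowest bandit index;
* ``random`` — any other lower-valued choice (decision noise).

Missed trials are labelled ``missed`` and excluded from every behavioural
denominator, matching the convention of dividing by correctly executed
trials only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .agents import BeliefState, ModelSpec, Params
from .inference import belief_trace
from .task import Schedule, WalkParams

__all__ = [
    "LABELS",
    "classify_trial",
    "classify_session",
    "BehaviouralSummary",
    "behavioural_summary",
    "CorrelationResult",
    "correlate_with_score",
]

LABELS = ("exploit", "directed", "random", "missed")


def _classify_arrays(
    values: np.ndarray, target_stat: np.ndarray, choice: int
) -> str:
    """Label one choice from pre-trial values and the exploration statistic."""
    best = values == values.max()
    if best[choice]:
        return "exploit"
    masked = np.where(best, -np.inf, target_stat)
    directed_target = int(np.argmax(masked))  # argmax breaks ties low
    return "directed" if choice == directed_target else "random"


def classify_trial(
    beliefs_before: BeliefState, choice: int | None, spec: ModelSpec
) -> str:
    """Label a single choice given the beliefs holding *before* the trial."""
    if choice is None:
        return "missed"
    if spec.learning_rule == "bayes":
        if beliefs_before.variances is None:
            raise ValueError("Bayesian classification requires belief variances")
        stat = beliefs_before.variances
    else:
        stat = beliefs_before.trials_since_chosen.astype(float)
    return _classify_arrays(beliefs_before.values, stat, choice)


def classify_session(
    session: pd.DataFrame,
    spec: ModelSpec,
    params: Params | None = None,
    walk_params: WalkParams | None = None,
    *,
    n_bandits: int = 4,
    prior_mean: float = 50.0,
    prior_variance: float | None = None,
) -> list[str]:
    """Label every trial of a session along its recorded belief trace.

    ``params`` supplies alpha for delta-rule specs; the Bayesian belief
    trace is parameter-free so ``params`` may be omitted.
    """
    wp = walk_params if walk_params is not None else WalkParams()
    alpha = params.alpha if params is not None else None
    trace = belief_trace(
        session, spec, wp, alpha=alpha,
        n_bandits=n_bandits, prior_mean=prior_mean, prior_variance=prior_variance,
    )
    stat = trace.uncertainty if spec.learning_rule == "bayes" else trace.recency
    labels = []
    for t in range(trace.valid.shape[0]):
        if not trace.valid[t]:
            labels.append("missed")
        else:
            labels.append(
                _classify_arrays(trace.values[t], stat[t], int(trace.choices0[t]))
            )
    return labels


@dataclass
class BehaviouralSummary:
    """Model-free per-subject metrics, overall and per 50-trial block.

    ``overall`` maps metric name to value; ``per_block`` is a long table
    with one row per (block, metric). Probabilities use valid (non-missed)
    trials as the denominator except ``p_missed`` (all trials) and
    ``p_stay`` (valid trials that have a preceding valid choice).
    """

    overall: dict[str, float]
    per_block: pd.DataFrame


def _metrics(
    choice0: np.ndarray,
    outcome: np.ndarray,
    rt: np.ndarray,
    valid: np.ndarray,
    labels: np.ndarray,
    best0: np.ndarray,
    prev_valid_choice: np.ndarray,
) -> dict[str, float]:
    n_valid = int(valid.sum())
    out: dict[str, float] = {"n_trials": float(valid.size), "n_valid": float(n_valid)}
    out["p_missed"] = float((~valid).sum() / valid.size)
    if n_valid == 0:
        for k in ("p_best", "mean_points", "p_exploit", "p_directed", "p_random",
                  "p_stay", "mean_decision_time"):
            out[k] = np.nan
        return out
    out["p_best"] = float(np.mean(choice0[valid] == best0[valid]))
    out["mean_points"] = float(np.mean(outcome[valid]))
    for lab, key in (("exploit", "p_exploit"), ("directed", "p_directed"),
                     ("random", "p_random")):
        out[key] = float(np.mean(labels[valid] == lab))
    has_prev = valid & (prev_valid_choice >= 0)
    out["p_stay"] = (
        float(np.mean(choice0[has_prev] == prev_valid_choice[has_prev]))
        if has_prev.any()
        else np.nan
    )
    out["mean_decision_time"] = (
        float(np.nanmean(rt[valid])) if np.isfinite(rt[valid]).any() else np.nan
    )
    return out


def behavioural_summary(
    session: pd.DataFrame,
    labels: list[str] | np.ndarray,
    schedule: Schedule,
    *,
    block_size: int = 50,
    best_from: str = "latent_mean",
) -> BehaviouralSummary:
    """Compute the model-free metrics for one subject.

    ``best_from`` selects whether the best bandit of a trial is the one
    with the highest scheduled latent mean (default) or the highest
    realized payout on that trial.
    """
    ordered = session.sort_values("trial") if "trial" in session else session
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(ordered):
        raise ValueError(
            f"{len(labels)} labels for {len(ordered)} trials: misaligned"
        )
    T = len(ordered)
    if T > schedule.n_trials:
        raise ValueError(
            f"session has {T} trials but schedule covers {schedule.n_trials}"
        )
    missed = ordered["missed"].to_numpy().astype(bool)
    valid = ~missed
    if np.any(valid != (labels != "missed")):
        raise ValueError("labels mark 'missed' inconsistently with the session")
    choice0 = np.where(valid, np.nan_to_num(ordered["choice"].to_numpy(float)) - 1, -1).astype(int)
    outcome = ordered["outcome"].to_numpy(float)
    rt = ordered["rt_s"].to_numpy(float) if "rt_s" in ordered else np.full(T, np.nan)
    source = schedule.means if best_from == "latent_mean" else schedule.payouts
    best0 = np.argmax(source[:, :T], axis=0)
    prev_valid_choice = np.full(T, -1, dtype=int)
    last = -1
    for t in range(T):
        prev_valid_choice[t] = last
        if valid[t]:
            last = choice0[t]

    overall = _metrics(choice0, outcome, rt, valid, labels, best0, prev_valid_choice)
    block_rows = []
    blocks = (np.arange(T) // block_size) + 1
    for b in np.unique(blocks):
        m = blocks == b
        row = _metrics(
            choice0[m], outcome[m], rt[m], valid[m], labels[m], best0[m],
            prev_valid_choice[m],
        )
        row["block"] = int(b)
        block_rows.append(row)
    per_block = pd.DataFrame(block_rows).set_index("block").reset_index()
    return BehaviouralSummary(overall=overall, per_block=per_block)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between a metric and a clinical score."""

    rho: float
    p_value: float
    n: int
    undefined: bool = False


def correlate_with_score(
    metric_values: np.ndarray | pd.Series,
    scores: np.ndarray | pd.Series,
) -> CorrelationResult:
    """Tie-corrected Spearman correlation with a two-sided p-value."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("metric and score vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(np.nan, np.nan, int(x.size), undefined=True)
    res = spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))
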