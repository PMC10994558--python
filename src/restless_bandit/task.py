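"""Four-armed restless-bandit payout schedules.

Each bandit's latent mean payout follows a decaying (mean-reverting)
Gaussian random walk,

    mu[i, t+1] = lambda * mu[i, t] + (1 - lambda) * theta + nu,
    nu ~ Normal(0, sigma_d^2),

and the realized payout shown to the participant is a noisy, rounded and
clipped observation of the latent mean,

    payout[i, t] = clip(round(Normal(mu[i, t], sigma_o)), floor, ceiling).

Defaults follow the walk used in the classic four-armed restless bandit
paradigm (lambda = 0.9836, theta = 50, sigma_d = 2.8, sigma_o = 4) with
payouts clipped to 0..100 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "WalkParams",
    "Schedule",
    "generate_schedule",
    "payout_at",
    "validate_schedule",
    "schedule_to_frame",
    "schedule_from_frame",
    "BUILTIN_SCHEDULE_SEEDS",
]

#: Canonical seeds for the two experimental sessions ("out of scanner" and
#: "in scanner"). The original two instantiations are not public; these
#: labelled seeds give every pipeline run the same pair of schedules.
BUILTIN_SCHEDULE_SEEDS = {"session_out": 20240, "session_in": 20241}


class WalkParams(BaseModel):
    """Parameters of the decaying Gaussian random walk.

    Attributes
    ----------
    decay : float
        Mean-reversion coefficient lambda, 0 < lambda < 1.
    decay_center : float
        Attractor theta of the walk, in points.
    diffusion_sd : float
        Standard deviation sigma_d of the per-trial innovation, in points.
    observation_sd : float
        Standard deviation sigma_o of payout noise around the latent mean.
    floor, ceiling : float
        Clipping bounds for realized payouts, in points.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    decay: float = 0.9836
    decay_center: float = 50.0
    diffusion_sd: float = 2.8
    observation_sd: float = 4.0
    floor: float = 0.0
    ceiling: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "WalkParams":
        if not 0.0 < self.decay < 1.0:
            raise ValueError(f"walk.decay must lie in (0, 1), got {self.decay}")
        if self.diffusion_sd < 0:
            # 0 is allowed: a degenerate noise-free walk pinned at theta
            raise ValueError(
                f"walk.diffusion_sd must be >= 0, got {self.diffusion_sd}"
            )
        if self.observation_sd < 0:
            raise ValueError(
                f"walk.observation_sd must be >= 0, got {self.observation_sd}"
            )
        if self.floor >= self.ceiling:
            raise ValueError(
                f"walk.floor must be below walk.ceiling, got "
                f"[{self.floor}, {self.ceiling}]"
            )
        return self

    @property
    def stationary_variance(self) -> float:
        """Variance sigma_d^2 / (1 - lambda^2) of the stationary AR(1) walk."""
        return self.diffusion_sd**2 / (1.0 - self.decay**2)


@dataclass(frozen=True)
class Schedule:
    """A pre-generated payout schedule.

    ``means`` and ``payouts`` are (n_bandits, n_trials) arrays; payouts are
    integers within [floor, ceiling]. Regenerating with the same parameters
    and seed reproduces the schedule bit-exactly.
    """

    n_trials: int
    n_bandits: int
    means: np.ndarray
    payouts: np.ndarray
    walk_params: WalkParams
    seed: int
    instantiation_id: str = field(default="custom")

    def __post_init__(self) -> None:
        if self.means.shape != (self.n_bandits, self.n_trials):
            raise ValueError(
                f"means has shape {self.means.shape}, expected "
                f"({self.n_bandits}, {self.n_trials})"
            )
        if self.payouts.shape != (self.n_bandits, self.n_trials):
            raise ValueError(
                f"payouts has shape {self.payouts.shape}, expected "
                f"({self.n_bandits}, {self.n_trials})"
            )


def generate_schedule(
    walk_params: WalkParams | None = None,
    n_trials: int = 300,
    n_bandits: int = 4,
    seed: int = 0,
    *,
    init_at_center: bool = False,
    instantiation_id: str | None = None,
) -> Schedule:
    """Generate a restless-bandit schedule from the decaying Gaussian walk.

    Initial latent means are drawn from the walk's stationary distribution
    Normal(theta, sigma_d^2 / (1 - lambda^2)) unless ``init_at_center`` is
    set, in which case all bandits start exactly at theta.
    """
    wp = walk_params if walk_params is not None else WalkParams()
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if n_bandits < 2:
        raise ValueError(f"n_bandits must be >= 2, got {n_bandits}")

    rng = np.random.default_rng(seed)
    lam, theta = wp.decay, wp.decay_center
    means = np.empty((n_bandits, n_trials))
    if init_at_center:
        means[:, 0] = theta
    else:
        means[:, 0] = rng.normal(theta, np.sqrt(wp.stationary_variance), n_bandits)
    for t in range(1, n_trials):
        means[:, t] = (
            lam * means[:, t - 1]
            + (1.0 - lam) * theta
            + rng.normal(0.0, wp.diffusion_sd, n_bandits)
        )
    raw = rng.normal(means, wp.observation_sd)
    payouts = np.clip(np.rint(raw), wp.floor, wp.ceiling).astype(np.int64)
    return Schedule(
        n_trials=n_trials,
        n_bandits=n_bandits,
        means=means,
        payouts=payouts,
        walk_params=wp,
        seed=seed,
        instantiation_id=instantiation_id
        or next(
            (k for k, v in BUILTIN_SCHEDULE_SEEDS.items() if v == seed), f"seed{seed}"
        ),
    )


def builtin_schedule(label: str, n_trials: int = 300, n_bandits: int = 4) -> Schedule:
    """One of the two canonical session schedules ("session_out" / "session_in")."""
    try:
        seed = BUILTIN_SCHEDULE_SEEDS[label]
    except KeyError:
        raise KeyError(
            f"unknown schedule label {label!r}; "
            f"expected one of {sorted(BUILTIN_SCHEDULE_SEEDS)}"
        ) from None
    return generate_schedule(
        n_trials=n_trials, n_bandits=n_bandits, seed=seed, instantiation_id=label
    )


def payout_at(schedule: Schedule, bandit: int, trial: int) -> int:
    """Realized payout for 0-based ``bandit`` on 0-based ``trial``."""
    if not 0 <= bandit < schedule.n_bandits:
        raise IndexError(
            f"bandit index {bandit} out of range [0, {schedule.n_bandits})"
        )
    if not 0 <= trial < schedule.n_trials:
        raise IndexError(f"trial index {trial} out of range [0, {schedule.n_trials})")
    return int(schedule.payouts[bandit, trial])


def validate_schedule(schedule: Schedule) -> list[str]:
    """Report (not raise) schedule integrity violations.

    Returns a list of human-readable violation strings; empty when valid.
    """
    violations: list[str] = []
    wp = schedule.walk_params
    expected = (schedule.n_bandits, schedule.n_trials)
    for name in ("means", "payouts"):
        arr = getattr(schedule, name)
        if arr.shape != expected:
            violations.append(
                f"{name} has shape {arr.shape}, expected {expected}"
            )
    if schedule.payouts.shape == expected:
        bad = (schedule.payouts < wp.floor) | (schedule.payouts > wp.ceiling)
        for b, t in zip(*np.nonzero(bad)):
            violations.append(
                f"payout {schedule.payouts[b, t]} at bandit {b + 1}, trial {t + 1} "
                f"outside [{wp.floor}, {wp.ceiling}]"
            )
        if not np.array_equal(schedule.payouts, np.rint(schedule.payouts)):
            violations.append("payouts contain non-integer values")
    return violations


def schedule_to_frame(schedule: Schedule) -> pd.DataFrame:
    """Long-format table with 1-based trial and bandit columns."""
    b, t = np.meshgrid(
        np.arange(schedule.n_bandits), np.arange(schedule.n_trials), indexing="ij"
    )
    return pd.DataFrame(
        {
            "trial": t.ravel() + 1,
            "bandit": b.ravel() + 1,
            "mean": schedule.means.ravel(),
            "payout": schedule.payouts.ravel(),
        }
    ).sort_values(["trial", "bandit"], kind="stable", ignore_index=True)


def schedule_from_frame(
    frame: pd.DataFrame,
    walk_params: WalkParams | None = None,
    seed: int = -1,
    instantiation_id: str = "from_file",
) -> Schedule:
    """Rebuild a :class:`Schedule` from its long-format table."""
    required = {"trial", "bandit", "mean", "payout"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"schedule table missing columns: {sorted(missing)}")
    n_trials = int(frame["trial"].max())
    n_bandits = int(frame["bandit"].max())
    means = np.full((n_bandits, n_trials), np.nan)
    payouts = np.zeros((n_bandits, n_trials), dtype=np.int64)
    means[frame["bandit"] - 1, frame["trial"] - 1] = frame["mean"]
    payouts[frame["bandit"] - 1, frame["trial"] - 1] = frame["payout"]
    if np.isnan(means).any():
        raise ValueError("schedule table does not cover every (trial, bandit) cell")
    return Schedule(
        n_trials=n_trials,
        n_bandits=n_bandits,
        means=means,
        payouts=payouts,
        walk_params=walk_params if walk_params is not None else WalkParams(),
        seed=seed,
        instantiation_id=instantiation_id,
    )
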