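import numpy as np
import pandas as pd
import pytest

from restless_bandit import (
    ModelSpec,
    Params,
    WalkParams,
    builtin_schedule,
    simulate_agent,
)


@pytest.fixture(scope="session")
def walk_params() -> WalkParams:
    return WalkParams()


@pytest.fixture(scope="session")
def schedule():
    return builtin_schedule("session_out")


@pytest.fixture(scope="session")
def bayes_smep() -> ModelSpec:
    return ModelSpec("bayes", "SMEP")


@pytest.fixture(scope="session")
def smep_params() -> Params:
    return Params(beta=0.1, phi=0.8, rho=4.0)


@pytest.fixture(scope="session")
def smep_session(bayes_smep, smep_params, schedule) -> pd.DataFrame:
    """A full 300-trial session from a bayes+SMEP agent, with misses."""
    return simulate_agent(
        bayes_smep, smep_params, schedule, seed=101, missed_rate=0.03
    )


def make_session(choices_1b, outcomes, subject="hand", schedule_id="session_out"):
    """Hand-build a session table; choice None marks a missed trial."""
    rows = []
    for t, (c, o) in enumerate(zip(choices_1b, outcomes)):
        missed = c is None
        rows.append(
            {
                "subject": subject,
                "trial": t + 1,
                "block": t // 50 + 1,
                "choice": np.nan if missed else float(c),
                "outcome": np.nan if missed else float(o),
                "rt_s": np.nan if missed else 0.5,
                "missed": int(missed),
                "schedule_id": schedule_id,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def hand_session():
    return make_session([2, 3, 2, None, 1, 4], [60, 45, 70, None, 52, 38])
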