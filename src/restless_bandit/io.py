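"""Reading/validation of the pipeline's delimited-text files.

File conventions (pinned): UTF-8 CSV with a header row, comma separator,
empty string for missing values, 1-based trial and bandit numbering.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

TRIALS_COLUMNS = [
    "subject", "trial", "block", "choice", "outcome", "rt_s", "missed",
    "schedule_id",
]

__all__ = ["TRIALS_COLUMNS", "read_trials", "write_trials"]


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trials CSV; errors carry 1-based line numbers."""
    trials = pd.read_csv(path)
    missing = [c for c in TRIALS_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    problems = []
    missed = trials["missed"].to_numpy()
    if not np.isin(missed, (0, 1)).all():
        bad = np.nonzero(~np.isin(missed, (0, 1)))[0]
        problems += [f"line {i + 2}: missed must be 0 or 1" for i in bad[:5]]
    choice = trials["choice"].to_numpy(dtype=float)
    valid = missed == 0
    bad_choice = valid & (np.isnan(choice) | (choice < 1) | (choice != np.rint(choice)))
    problems += [
        f"line {i + 2}: non-missed trial needs an integer choice >= 1"
        for i in np.nonzero(bad_choice)[0][:5]
    ]
    bad_outcome = valid & np.isnan(trials["outcome"].to_numpy(dtype=float))
    problems += [
        f"line {i + 2}: non-missed trial lacks an outcome"
        for i in np.nonzero(bad_outcome)[0][:5]
    ]
    bad_extra = (missed == 1) & ~np.isnan(trials["outcome"].to_numpy(dtype=float))
    problems += [
        f"line {i + 2}: missed trial carries an outcome"
        for i in np.nonzero(bad_extra)[0][:5]
    ]
    if problems:
        raise ValueError(f"{path}: malformed trials file:\n  " + "\n  ".join(problems))
    return trials


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
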