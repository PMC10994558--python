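#!/usr/bin/env python
"""Classify every choice and relate behaviour to apathy severity.

Labels each valid trial exploit / directed / random along the Bayesian
learner's belief trace, computes the model-free behavioural metrics
(best-bandit probability, points won, stay probability, choice-type
proportions, per 50-trial block), and correlates them with the LARS
apathy score across the PD groups.

Reads results/cohort/, writes results/behaviour/.
"""

import argparse
from pathlib import Path

import pandas as pd

from restless_bandit.classify import (
    behavioural_summary,
    classify_session,
    correlate_with_score,
)
from restless_bandit.cohort import cohort_from_files

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "behaviour")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = cohort_from_files(args.cohort)
    schedule = cohort.schedules["session_out"]
    spec = cohort.config.spec

    labelled, rows, block_rows = [], [], []
    for sid, sess in cohort.trials.groupby("subject"):
        labels = classify_session(sess, spec, walk_params=schedule.walk_params)
        lab = sess.copy()
        lab["choice_type"] = labels
        labelled.append(lab)
        summary = behavioural_summary(sess, labels, schedule)
        rows.append({"subject": sid, **summary.overall})
        pb = summary.per_block.copy()
        pb.insert(0, "subject", sid)
        block_rows.append(pb)

    pd.concat(labelled, ignore_index=True).to_csv(
        args.out / "trials_labelled.csv", index=False
    )
    pd.concat(block_rows, ignore_index=True).to_csv(
        args.out / "summaries_blocks.csv", index=False
    )
    behaviour = pd.DataFrame(rows).merge(
        cohort.subjects[["subject", "group", "lars"]], on="subject"
    )
    behaviour.to_csv(args.out / "summaries.csv", index=False)

    metrics = ["p_best", "mean_points", "p_exploit", "p_directed", "p_random", "p_stay"]
    print("group means:")
    print(behaviour.groupby("group")[metrics].mean().round(3).to_string())
    pd_subjects = behaviour[behaviour["group"] != "HC"]
    print("\nLARS correlations across the PD groups (Spearman):")
    for metric in metrics:
        res = correlate_with_score(pd_subjects[metric], pd_subjects["lars"])
        print(f"  {metric}: rho = {res.rho:+.2f}, p = {res.p_value:.2g}, n = {res.n}")


if __name__ == "__main__":
    main()
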