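#!/usr/bin/env python
"""Bayesian logistic regression of Allee probability on the scenario design.

Reads results/outcomes.csv (written by 03_classify_outcomes.py), groups
perception neighborhoods of three or more territories, and fits the
Bernoulli-logit cell-means model with Normal(0, 100^2) priors by slice
sampling (3 chains).  Writes results/allee_probability.csv with the
posterior mean and 95% credible interval of the Allee probability per
cell and prints the table ordered as the scenario-probability figure.

Usage: python analysis/04_regress_allee_probability.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from wolfallee.scenario_regression import (
    encode_outcomes,
    sample_logistic,
    summarize_probabilities,
)
from wolfallee.trajectory_classifier import ClassifiedOutcome

ROOT = Path(__file__).resolve().parent.parent
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    src = ROOT / "results" / "outcomes.csv"
    if not src.exists():
        raise SystemExit("run analysis/03_classify_outcomes.py first")
    df = pd.read_csv(src)
    outcomes = [
        ClassifiedOutcome(
            scenario={
                "perception_territories": int(r.perception_territories),
                "dispersal": r.dispersal,
            },
            category=r.category,
        )
        for r in df.itertuples()
    ]
    design, y = encode_outcomes(outcomes, grouping="pn3")
    fit = sample_logistic(design, y, iters=20_000, burnin=5_000, seed=SEED)
    table = summarize_probabilities(fit)
    table.to_csv(ROOT / "results" / "allee_probability.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nconverged: {fit.report.converged} (R-hat_p {fit.report.mpsrf:.3f})")
    worst = table.loc[table.p_mean.idxmax()]
    print(
        f"highest Allee probability: perception {worst.perception}, "
        f"{worst.dispersal} dispersal (p = {worst.p_mean:.2f})"
    )


if __name__ == "__main__":
    main()
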