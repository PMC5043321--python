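#!/usr/bin/env python
"""Fit psychometric functions to every condition's choice data.

Reads the trial tables written by 01_simulate_experiment.py, fits the
logistic psychometric function by maximum likelihood per condition, and
extracts the threshold at the binomially justified criterion (66.7% correct
for 30 trials per level).  Writes one row per condition.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from rnlcolour.psychometrics import (UnattainableCriterionError,
                                     binomial_criterion, fit_psychometric,
                                     read_trial_table, threshold_from_fit)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--experiment", type=Path,
                    default=ROOT / "results" / "experiment")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    trial_dir = args.experiment / "trials"
    if not trial_dir.is_dir():
        ap.error(f"{trial_dir} missing; run 01_simulate_experiment.py first")

    rows = []
    for path in sorted(trial_dir.glob("*.csv")):
        if path.stem == "schedule":
            continue
        data = read_trial_table(path)
        k_min, crit = binomial_criterion(data[0].n_trials)
        fit = fit_psychometric(data)
        try:
            thr = threshold_from_fit(fit, crit)
        except UnattainableCriterionError:
            thr = float("nan")
        rows.append({"condition": path.stem,
                     "criterion_pct": round(100 * crit, 1),
                     "position_a": round(fit.position, 3),
                     "steepness_b": round(fit.steepness, 3),
                     "lapse_rate": round(fit.lapse_rate, 3),
                     "log_likelihood": round(fit.log_likelihood, 2),
                     "converged": fit.converged,
                     "threshold_jnd": round(thr, 3)})

    df = pd.DataFrame(rows)
    df.to_csv(args.out / "psychometric_fits.csv", index=False)
    print(f"fitted {len(df)} conditions at the "
          f"{rows[0]['criterion_pct']}% criterion:")
    print(df.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
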