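#!/usr/bin/env python
"""Model-free behavioural summaries of the simulated cohorts.

For each cohort: accuracy by norm prompt x cue validity (valid cues help,
invalid cues hurt, and the SAME/ONLY prompts amplify/attenuate the effect),
per-subject conformity deltas (change in choosing the cued side vs the
no-norm condition), and total payoffs under the experiment's matrix.
Writes tables under results/behaviour/.
"""

from pathlib import Path

import pandas as pd

from dust_ddm.behavior_metrics import accuracy_table, conformity_delta, payoff_table
from dust_ddm.pipeline import load_trials

out = Path("results/behaviour")
out.mkdir(parents=True, exist_ok=True)

for experiment in ("BO", "HO"):
    data = load_trials(f"results/cohort_{experiment.lower()}/data")
    acc = accuracy_table(data)
    acc.to_csv(out / f"accuracy_{experiment.lower()}.csv", index=False)
    cohort_acc = (
        acc.groupby(["norm", "validity"], observed=True)["accuracy"].mean().unstack()
    )
    print(f"\n{experiment}: accuracy by norm x validity")
    print(cohort_acc.round(3).to_string())

    rows = []
    for subject, sdf in data.groupby("subject"):
        for norm in ("SAME", "ONLY"):
            rows.append((subject, norm, conformity_delta(sdf, norm)))
    conf = pd.DataFrame(rows, columns=["subject", "norm", "delta"])
    conf.to_csv(out / f"conformity_{experiment.lower()}.csv", index=False)
    print(f"{experiment}: mean conformity delta "
          + ", ".join(f"{n}: {g['delta'].mean():+.3f}"
                      for n, g in conf.groupby("norm")))

    pay = payoff_table(data)
    print(f"{experiment}: payoff self {int(pay.points_self.sum())} cents, "
          f"others {int(pay.points_others.sum())} cents")
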