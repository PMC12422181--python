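#!/usr/bin/env python
"""Awakening probability by stimulus intensity and state-transition curves.

Uses the trial table and hypnograms from 01_simulate_cohort.py: computes
the probability of full awakening over NREM trials per intensity, then the
per-second state-probability curves after trial onset and their 5-10 s
wake-transition mean.
"""

import json
from pathlib import Path

import pandas as pd
from scipy import stats

from ne_awake import behavior, io

scratch = Path("scratch/cohort")
results = Path("results")
trials = pd.read_csv(results / "trials.csv")

rows = []
per_mouse_by_db = {}
for db in sorted(trials["intensity_db"].unique()):
    p, per_mouse = behavior.awakening_probability(trials, condition={"intensity_db": db})
    per_mouse_by_db[db] = per_mouse
    rows.append({"intensity_db": db, "p_awakening": p, "n_mice": len(per_mouse)})
    print(f"{db:.0f} dB SPL: awakening probability {p:.3f}")
prob = pd.DataFrame(rows)
prob.to_csv(results / "awakening_probability.csv", index=False)

f, p = stats.f_oneway(*[v.to_numpy() for v in per_mouse_by_db.values()])
print(f"intensity ANOVA on per-mouse probabilities: F={f:.2f}, p={p:.2g}")

curves_all = []
for m in range(7):
    hyp = io.read_hypnogram(scratch / f"hypnogram_m{m}.csv")
    sub = trials[trials["mouse"] == f"m{m}"]
    try:
        curves = behavior.transition_probabilities(
            hyp, sub["onset_s"].to_numpy(), base_state="NREM", horizon_s=60
        )
    except ValueError:
        continue  # this mouse had no NREM-stable trials
    tidy = curves.reset_index().melt("t_s", var_name="state", value_name="probability")
    tidy["mouse"] = f"m{m}"
    curves_all.append(tidy)
    wmean = behavior.window_mean_transition(curves)
    print(f"m{m}: mean wake probability 5-10 s after onset = {wmean:.3f}")

if curves_all:
    pd.concat(curves_all, ignore_index=True).to_csv(
        results / "transition_curves.csv", index=False
    )
with open(results / "behavior_summary.json", "w") as f_:
    json.dump({"anova_F": f, "anova_p": p,
               "p_by_intensity": prob.set_index("intensity_db")["p_awakening"].to_dict()},
              f_, indent=1)
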