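#!/usr/bin/env python
"""ΔF/F preprocessing and response-window detection on the simulated cohort.

Reads the sessions written by 01_simulate_cohort.py, converts each to ΔF/F
against the fitted isosbestic reference, epochs trials, detects the
cohort-level response windows (0.3-s bins over 0-3.9 s, omnibus
Kruskal-Wallis then one-sided many-to-one correction), scores per-trial
window means and post-window drops, and relates them to trial outcome.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ne_awake import io, photometry

scratch = Path("scratch/cohort")
results = Path("results")
if not scratch.exists():
    raise SystemExit("run analysis/01_simulate_cohort.py first")

trials = pd.read_csv(results / "trials.csv")
epochs = []  # awakening trials: the NE response is characterized by outcome
epochs_all = []
for m, sub in trials.groupby(trials["mouse"].str.slice(1).astype(int)):
    sess = io.read_session(scratch / f"session_m{m}.h5")["photometry"]
    fit = photometry.fit_isosbestic(sess)
    dff = photometry.compute_dff(sess, fit)
    awake = sub.loc[sub["outcome"] == "awakening", "onset_s"].to_numpy()
    epochs.append(photometry.epoch_trials(dff, awake))
    epochs_all.append(photometry.epoch_trials(dff, sub["onset_s"].to_numpy()))

det = photometry.detect_response_windows(epochs, seed=0)
print(f"omnibus Kruskal-Wallis: H={det.kw_stat:.1f}, p={det.kw_p:.2g}")
for w in det.windows:
    print(f"  response window {w.start_s:.1f}-{w.end_s:.1f} s, "
          f"per-bin corrected p: {np.round(w.per_bin_p, 4).tolist()}")

with open(results / "response_windows.json", "w") as f:
    json.dump(
        {"kw_stat": det.kw_stat, "kw_p": det.kw_p,
         "windows": [{"start_s": w.start_s, "end_s": w.end_s,
                      "per_bin_p": list(map(float, w.per_bin_p))} for w in det.windows]},
        f, indent=1)

if det.windows:
    win = det.windows[0]
    scored = []  # scored on all trials so outcomes can be contrasted
    for m, (ep, (_, sub)) in enumerate(
        zip(epochs_all, trials.groupby(trials["mouse"].str.slice(1).astype(int)))
    ):
        s = photometry.score_elements(
            ep, win, outcomes=sub["outcome"].to_numpy()[ep.trial_ids]
        )
        s["mouse"] = f"m{m}"
        scored.append(s)
    scored = pd.concat(scored, ignore_index=True)
    scored.to_csv(results / "element_scores.csv", index=False)

    paired = photometry.compare_outcomes(scored)
    print(f"awakening vs maintained window score: t({paired.df})={paired.t:.2f}, "
          f"p={paired.p:.3g} over {paired.n} mice")
    r, p = photometry.peak_drop_correlation(scored)
    print(f"peak-drop correlation: r={r:.2f}, p={p:.2g}")

    model = photometry.fit_outcome_model(
        scored[["score"]].rename(columns={"score": "window_score"}),
        scored["outcome"].to_numpy(),
    )
    print(f"outcome model LRT: chi2({model.df})={model.chi2:.2f}, p={model.p_lrt:.2g}")
    with open(results / "outcome_model.json", "w") as f:
        json.dump({"chi2": model.chi2, "df": model.df, "p": model.p_lrt,
                   "paired_t": paired.t, "paired_df": paired.df, "paired_p": paired.p,
                   "peak_drop_r": r}, f, indent=1)
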