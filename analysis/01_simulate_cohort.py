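#!/usr/bin/env python
"""Generate the synthetic study cohort used by the downstream analyses.

Seven mice, each with a 15-minute two-channel photometry session, sound
trials every 60 s (±0.5 s) at 73/80/88 dB, a hypnogram and EEG/EMG traces.
Ground truth (injected response windows, per-trial outcomes) is saved as
YAML.  Heavy time-series go to scratch/ (HDF5); tables to results/.
"""

from pathlib import Path

from ne_awake import io, synth

SEED = 1
N_MICE = 7
DURATION_S = 900.0

scratch = Path("scratch/cohort")
results = Path("results")
scratch.mkdir(parents=True, exist_ok=True)
results.mkdir(exist_ok=True)

all_trials = []
for m in range(N_MICE):
    cfg = synth.SimulationConfig(seed=SEED * 1000 + m, duration_s=DURATION_S)
    trials = synth.generate_trial_schedule(cfg)
    session, truth = synth.generate_photometry_session(cfg, trials)
    hyp, eeg_tr, emg_tr = synth.generate_sleep_records(cfg)
    io.write_session(scratch / f"session_m{m}.h5", session, eeg=eeg_tr, emg=emg_tr,
                     attrs={"seed": cfg.seed})
    trials["mouse"] = f"m{m}"
    trials["baseline_state"] = "NREM"
    trials["outcome"] = truth.trial_outcomes
    all_trials.append(trials)
    io.write_table(scratch / f"hypnogram_m{m}.csv", hyp)
    io.write_yaml(
        scratch / f"truth_m{m}.yaml",
        {"true_windows": [list(w) for w in truth.true_windows],
         "trial_outcomes": truth.trial_outcomes},
    )

import pandas as pd  # noqa: E402

trials = pd.concat(all_trials, ignore_index=True)
io.write_table(results / "trials.csv", trials)

n_awake = (trials["outcome"] == "awakening").sum()
print(f"simulated {N_MICE} mice, {len(trials)} trials "
      f"({n_awake} awakenings, {n_awake / len(trials):.2f} of trials)")
print(f"sessions under {scratch}/, trial table at {results/'trials.csv'}")
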