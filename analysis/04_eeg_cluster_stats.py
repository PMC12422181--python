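#!/usr/bin/env python
"""Spectral effect of synaptic silencing: ERSP maps and cluster statistics.

Simulates, per mouse, EEG around "laser" and "sham" events where the laser
condition multiplies sigma-band (10-16 Hz) amplitude during stimulation —
the signature of reduced norepinephrine tone.  Computes per-mouse ERSPs,
runs the paired cluster-corrected permutation test against sham, and
summarizes mean power in the significant cluster.
"""

import json
from pathlib import Path

import numpy as np
from scipy import signal as sps

from ne_awake import eeg
from ne_awake.types import Trace

results = Path("results")
results.mkdir(exist_ok=True)

FS = 128.0
N_MICE = 6
SIGMA_GAIN = 1.8  # amplitude gain in 10-16 Hz during the 10-s stimulation
rng = np.random.default_rng(12)


def band_noise(n, lo, hi):
    b, a = sps.butter(2, [lo / (FS / 2), hi / (FS / 2)], btype="band")
    x = sps.filtfilt(b, a, rng.normal(size=n))
    return x / x.std()


def make_condition(sigma_gain):
    onsets = 40.0 + 95.0 * np.arange(8)
    n = int((onsets[-1] + 70) * FS)
    t = np.arange(n) / FS
    x = band_noise(n, 1, 45) + 1.5 * band_noise(n, 1, 4)
    sigma = band_noise(n, 10, 16)
    gain = np.ones(n)
    for on in onsets:
        gain[(t >= on) & (t < on + 10)] = sigma_gain
    return Trace(x + gain * sigma, FS), onsets


cond_maps, sham_maps = [], []
for m in range(N_MICE):
    tr, onsets = make_condition(SIGMA_GAIN)
    cond_maps.append(eeg.compute_ersp(tr, onsets).ersp)
    tr, onsets = make_condition(1.0)
    res = eeg.compute_ersp(tr, onsets)
    sham_maps.append(res.ersp)
freqs, times = res.freqs, res.times

cond_maps, sham_maps = np.asarray(cond_maps), np.asarray(sham_maps)
test = eeg.cluster_permutation_test(cond_maps, sham_maps, n_perm=1000, seed=0)
print(f"{len(test.clusters)} supra-threshold cluster(s)")
for c in test.clusters[:3]:
    fsel = freqs[c["mask"].any(axis=1)]
    tsel = times[c["mask"].any(axis=0)]
    print(f"  mass={c['mass']:.0f}, p={c['p']:.3f}, "
          f"{fsel.min():.1f}-{fsel.max():.1f} Hz, {tsel.min():.0f}-{tsel.max():.0f} s")

out = {"clusters": [{"mass": c["mass"], "p": c["p"]} for c in test.clusters]}
if test.clusters and test.clusters[0]["p"] <= 0.05:
    summary = eeg.cluster_mean_power(
        {"sham": sham_maps, "laser": cond_maps}, test.clusters[0]["mask"]
    )
    means = summary["per_mouse_means"]
    print(f"mean dB in cluster: laser {np.mean(means['laser']):.2f}, "
          f"sham {np.mean(means['sham']):.2f}; ANOVA p={summary['anova']['p']:.2g}")
    out["cluster_mean_power"] = summary["per_mouse_means"]
    out["anova"] = summary["anova"]
with open(results / "eeg_cluster_stats.json", "w") as f:
    json.dump(out, f, indent=1)
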