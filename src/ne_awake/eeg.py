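"""Event-related spectral perturbation, band power, EMG tone, cluster stats.

The ERSP is a Hanning-tapered short-time log-power map per trial, averaged
over trials and normalized per frequency by the pre-event baseline, in dB
(10·log10).  Group inference on condition-vs-sham contrasts uses a paired
t-map thresholded at a parametric one-sided critical value, with
4-connected supra-threshold clusters scored by summed t (mass) against a
sign-flip permutation null of the maximum cluster mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps, stats

from .types import ClusterStatResult, SpectrogramResult, Trace

log = logging.getLogger(__name__)

__all__ = [
    "compute_ersp",
    "band_power",
    "emg_rms",
    "cluster_permutation_test",
    "cluster_mean_power",
]

_EPS = 1e-20


def compute_ersp(
    eeg: Trace,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = (-30.0, 60.0),
    freq_range_hz: tuple[float, float] = (1.0, 50.0),
    taper_s: float = 2.0,
    max_win_s: float = 10.0,
    overlap: float = 0.5,
    baseline_window_s: tuple[float, float] | None = None,
) -> SpectrogramResult:
    """Trial-averaged, baseline-normalized log spectrogram around events.

    Per trial a Hanning-tapered short-time FFT (taper length ``taper_s``,
    capped at ``max_win_s``) yields log power per (frequency, time); the
    log-power maps are averaged over trials — no single-trial normalization
    — and the per-frequency mean over the baseline window (the pre-onset
    part of the window by default) is subtracted, giving dB change.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    fs = eeg.fs
    if baseline_window_s is None:
        baseline_window_s = (window_s[0], 0.0)
    nper = int(round(min(taper_s, max_win_s) * fs))
    if nper < 8:
        raise ValueError("taper too short for the sampling rate")
    nover = int(nper * overlap)
    i0_rel = int(round(window_s[0] * fs))
    i1_rel = int(round(window_s[1] * fs))
    maps = []
    for onset in onsets_s:
        i0 = int(round(onset * fs)) + i0_rel
        i1 = int(round(onset * fs)) + i1_rel
        if i0 < 0 or i1 > eeg.samples.size:
            log.info("ersp: trial at %.1f s outside trace; dropped", onset)
            continue
        f, tt, sxx = sps.spectrogram(
            eeg.samples[i0:i1], fs=fs, window="hann", nperseg=nper, noverlap=nover
        )
        maps.append(10.0 * np.log10(sxx + _EPS))
    if not maps:
        raise ValueError("no complete trial window inside the trace")
    f_sel = (f >= freq_range_hz[0]) & (f <= freq_range_hz[1])
    mean_log = np.mean(maps, axis=0)[f_sel]
    times = tt + window_s[0]
    base = (times >= baseline_window_s[0]) & (times < baseline_window_s[1])
    if not base.any():
        raise ValueError("baseline window contains no spectrogram frames")
    ersp = mean_log - mean_log[:, base].mean(axis=1, keepdims=True)
    return SpectrogramResult(
        ersp=ersp,
        freqs=f[f_sel],
        times=times,
        baseline_window_s=baseline_window_s,
        n_trials=len(maps),
    )


def band_power(
    eeg: Trace, window_s: tuple[float, float], band_hz: tuple[float, float]
) -> float:
    """Mean periodogram power within a frequency band over a time window."""
    lo, hi = band_hz
    if hi > eeg.fs / 2:
        raise ValueError(f"band {band_hz} exceeds Nyquist ({eeg.fs / 2:.1f} Hz)")
    i0, i1 = int(round(window_s[0] * eeg.fs)), int(round(window_s[1] * eeg.fs))
    seg = eeg.samples[max(i0, 0) : i1]
    if seg.size < 2 * eeg.fs / lo:
        raise ValueError("window shorter than two cycles of the lowest band frequency")
    f, pxx = sps.periodogram(seg, fs=eeg.fs)
    sel = (f >= lo) & (f <= hi)
    return float(pxx[sel].mean())


def emg_rms(
    emg: Trace,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = (-5.0, 15.0),
    bin_s: float = 0.1,
    avg_span_s: tuple[float, float] = (0.0, 4.0),
    baseline_subtract: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned EMG root-mean-square per trial with per-trial baselining.

    The trial segment is cut into ``bin_s`` bins and each bin's RMS
    computed; with ``baseline_subtract`` the mean of the pre-onset bins is
    removed per trial.  Returns ``(per_trial_mean, binned, bin_times)``
    where ``per_trial_mean`` averages the bins inside ``avg_span_s``.
    """
    fs = emg.fs
    nbin = int(round(bin_s * fs))
    i0_rel = int(round(window_s[0] * fs))
    n_bins = int(np.floor((window_s[1] - window_s[0]) / bin_s + 1e-9))
    bin_t = window_s[0] + bin_s * (np.arange(n_bins) + 0.5)
    rows = []
    for onset in np.asarray(onsets_s, dtype=float):
        i0 = int(round(onset * fs)) + i0_rel
        i1 = i0 + n_bins * nbin
        if i0 < 0 or i1 > emg.samples.size:
            raise ValueError(f"trial at {onset:.1f} s leaves the trace")
        seg = emg.samples[i0:i1].reshape(n_bins, nbin)
        rows.append(np.sqrt((seg**2).mean(axis=1)))
    binned = np.asarray(rows)
    if baseline_subtract:
        pre = bin_t < 0
        binned = binned - binned[:, pre].mean(axis=1, keepdims=True)
    span = (bin_t >= avg_span_s[0]) & (bin_t < avg_span_s[1])
    return binned[:, span].mean(axis=1), binned, bin_t


def _paired_tmap(diffs: np.ndarray) -> np.ndarray:
    """t-map across the first axis (mice) of per-mouse difference maps."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _cluster_masses(t_map: np.ndarray, thresh: float) -> tuple[np.ndarray, list[float], list[np.ndarray]]:
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    lab, n = ndimage.label(t_map > thresh, structure=structure)
    masses, masks = [], []
    for i in range(1, n + 1):
        m = lab == i
        masses.append(float(t_map[m].sum()))
        masks.append(m)
    return lab, masses, masks


def cluster_permutation_test(
    cond_maps: np.ndarray,
    sham_maps: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.1,
    tail: str = "greater",
    seed: int | None = 0,
) -> ClusterStatResult:
    """Paired cluster-corrected permutation test of condition vs sham maps.

    ``cond_maps`` and ``sham_maps`` are (n_mice, n_freqs, n_times) arrays of
    per-mouse ERSPs.  The paired t-map is thresholded at the one-sided
    parametric critical value for ``alpha_cluster``; supra-threshold
    4-connected clusters are scored by summed t and compared against the
    sign-flip permutation null of the maximum cluster mass.
    Cluster p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    cond_maps = np.asarray(cond_maps, dtype=float)
    sham_maps = np.asarray(sham_maps, dtype=float)
    if cond_maps.shape != sham_maps.shape:
        raise ValueError("condition and sham map stacks must share a shape")
    n_mice = cond_maps.shape[0]
    if n_mice < 3:
        raise ValueError("need at least three mice for the paired test")
    if n_perm < 100:
        log.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    if tail != "greater":
        raise ValueError("only the one-sided 'greater' tail is implemented")
    diffs = cond_maps - sham_maps
    df = n_mice - 1
    thresh = stats.t.ppf(1.0 - alpha_cluster, df)
    t_map = _paired_tmap(diffs)
    _, masses, masks = _cluster_masses(t_map, thresh)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_mice)
        t_perm = _paired_tmap(diffs * signs[:, None, None])
        _, perm_masses, _ = _cluster_masses(t_perm, thresh)
        null_max[i] = max(perm_masses) if perm_masses else 0.0

    clusters = []
    for mass, mask in zip(masses, masks):
        p = (1.0 + float((null_max >= mass).sum())) / (n_perm + 1.0)
        clusters.append({"mask": mask, "mass": mass, "p": p})
    clusters.sort(key=lambda c: c["p"])
    return ClusterStatResult(
        t_map=t_map,
        clusters=clusters,
        n_permutations=n_perm,
        alpha_cluster=alpha_cluster,
        tail=tail,
    )


def cluster_mean_power(
    maps_by_condition: dict[str, np.ndarray],
    mask: np.ndarray,
    sham: str = "sham",
) -> dict:
    """Per-mouse mean dB within a cluster mask, compared across conditions.

    Returns per-condition per-mouse means, a one-way ANOVA across
    conditions and, when a sham condition is present, many-to-one post hoc
    comparisons of every other condition against sham (Dunnett).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cluster mask is empty")
    means = {
        cond: np.asarray([m[mask].mean() for m in maps]) for cond, maps in maps_by_condition.items()
    }
    out: dict = {"per_mouse_means": {k: v.tolist() for k, v in means.items()}}
    if len(means) >= 2 and all(v.size >= 2 for v in means.values()):
        f, p = stats.f_oneway(*means.values())
        out["anova"] = {"F": float(f), "p": float(p)}
        if sham in means and len(means) >= 3:
            others = [k for k in means if k != sham]
            res = stats.dunnett(*[means[k] for k in others], control=means[sham])
            out["vs_sham"] = {
                k: {"stat": float(s), "p": float(pv)}
                for k, s, pv in zip(others, res.statistic, res.pvalue)
            }
    return out
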