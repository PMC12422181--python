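"""Seeded synthetic data: photometry sessions, sleep records, anatomy tables.

Every generator in this module carries known ground truth so the downstream
stages (ΔF/F preprocessing, response-window detection, outcome scoring,
spectral statistics, anatomical permutation tests) can be exercised and
calibrated without any recorded data.

Randomness discipline: all generators draw from ``numpy`` Generators built
by :func:`stream_rng`, which derives independent child streams from one
session seed via ``SeedSequence(seed, spawn_key=(stream_id,))``.  Fixed seed
implies bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import EpochMatrix, PhotometrySession, Trace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "stream_rng",
    "generate_trial_schedule",
    "generate_photometry_session",
    "generate_sleep_records",
    "generate_cell_counts",
    "generate_colocalization",
    "generate_epoch_cohort",
]

# Named sub-streams of the session seed.  Adding a stream appends a name;
# existing ids never change, so outputs stay reproducible across versions.
_STREAMS = {
    "schedule": 0,
    "photometry": 1,
    "sleep": 2,
    "cell_counts": 3,
    "colocalization": 4,
    "epoch_cohort": 5,
    "outcomes": 6,
}

STATES = ("wake", "NREM", "REM")


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Child Generator for a named stream of the session seed."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic session generators.

    Defaults follow the recorded experiment: two-channel photometry sampled
    at 1017.25 Hz and low-pass shaped at 6 Hz, broadband-noise trials every
    60 s with ±0.5 s jitter at 73/80/88 dB SPL, an early norepinephrine
    surge 0.3-0.6 s after sound onset and a slower rise at 1.8-3 s.
    Response amplitudes are in ΔF/F percent.
    """

    seed: int = 0
    duration_s: float = 600.0
    fs: float = 1017.25
    bleach_tau_s: float = 3600.0
    noise_sd: float = 1.0  # ΔF/F % per sample, after 6-Hz low-pass shaping
    surge_window_s: tuple[float, float] = (0.3, 0.6)
    surge_amp: float = 1.0  # ΔF/F %
    rise_window_s: tuple[float, float] = (1.8, 3.0)
    rise_amp: float = 1.0  # ΔF/F %
    trial_spacing_s: tuple[float, float] = (60.0, 0.5)  # mean, jitter
    intensities_db: tuple[float, ...] = (73.0, 80.0, 88.0)
    state_dwell_s: dict[str, float] = field(
        default_factory=lambda: {"wake": 120.0, "NREM": 180.0, "REM": 60.0}
    )
    # per-trial full-awakening probability; either one number or a mapping
    # from stimulus intensity (dB SPL) to probability.  Defaults follow the
    # measured awakening rates at 73/80/88 dB.
    awakening_prob: float | dict[float, float] = field(
        default_factory=lambda: {73.0: 0.2794, 80.0: 0.3444, 88.0: 0.3816}
    )
    led_cycle_s: tuple[float, float] | None = None  # (on_s, off_s); None = always on

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        mean, jitter = self.trial_spacing_s
        if not 0 <= jitter < mean:
            raise ValueError("trial jitter must be non-negative and below the mean spacing")
        for name, (a, b) in (
            ("surge_window_s", self.surge_window_s),
            ("rise_window_s", self.rise_window_s),
        ):
            if not a < b:
                raise ValueError(f"{name} must have start < end")
        if self.surge_amp < 0 or self.rise_amp < 0:
            raise ValueError("response amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.intensities_db:
            raise ValueError("intensities_db must be non-empty")
        for s, d in self.state_dwell_s.items():
            if s not in STATES:
                raise ValueError(f"unknown state {s!r}")
            if d <= 0:
                raise ValueError("state dwell times must be positive")
        probs = (
            self.awakening_prob.values()
            if isinstance(self.awakening_prob, dict)
            else (self.awakening_prob,)
        )
        if not all(0 <= p <= 1 for p in probs):
            raise ValueError("awakening_prob must be a probability")


@dataclass
class GroundTruth:
    """Injected truth paired with a generated session.

    ``true_windows`` lists (region_label, start_s, end_s, amplitude) of the
    stimulus-locked components added to the signal channel; ``trial_outcomes``
    is the per-trial behavioral label the generator committed to;
    ``state_sequence`` the per-second hypnogram; ``gradient_params`` the
    per-group anatomical distribution parameters.
    """

    true_windows: list[tuple[str, float, float, float]] = field(default_factory=list)
    trial_outcomes: list[str] = field(default_factory=list)
    state_sequence: list[str] = field(default_factory=list)
    gradient_params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trial schedule


def generate_trial_schedule(cfg: SimulationConfig) -> pd.DataFrame:
    """Trial onsets with jittered spacing and randomized intensities.

    Returns a DataFrame with columns ``trial_id, onset_s, intensity_db,
    laser``.  Consecutive onsets are spaced ``mean + U(-jitter, +jitter)``
    seconds apart, so every gap lies in [mean - jitter, mean + jitter].
    """
    rng = stream_rng(cfg.seed, "schedule")
    mean, jitter = cfg.trial_spacing_s
    # leave room for a pre-trial baseline and the 60-s post-trial horizon
    first = min(30.0, mean / 2)
    onsets = []
    t = first
    while t + 5.0 <= cfg.duration_s:
        onsets.append(t)
        t = t + mean + rng.uniform(-jitter, jitter)
    if not onsets:
        raise ValueError(
            f"duration_s={cfg.duration_s} too short for a single trial "
            f"(first onset would be at {first:.1f} s)"
        )
    onsets = np.asarray(onsets)
    intensities = rng.choice(np.asarray(cfg.intensities_db, dtype=float), size=onsets.size)
    return pd.DataFrame(
        {
            "trial_id": np.arange(onsets.size),
            "onset_s": onsets,
            "intensity_db": intensities,
            "laser": np.repeat("none", onsets.size),
        }
    )


def assign_outcomes(cfg: SimulationConfig, trials: pd.DataFrame) -> list[str]:
    """Per-trial awakening/maintained labels at the configured rates.

    With a per-intensity mapping, each trial's probability follows its
    stimulus level (intensities absent from the mapping use the mean rate).
    """
    rng = stream_rng(cfg.seed, "outcomes")
    if isinstance(cfg.awakening_prob, dict):
        fallback = float(np.mean(list(cfg.awakening_prob.values())))
        if "intensity_db" in trials.columns:
            p = trials["intensity_db"].map(
                lambda db: cfg.awakening_prob.get(float(db), fallback)
            ).to_numpy()
        else:
            p = np.full(len(trials), fallback)
    else:
        p = np.full(len(trials), cfg.awakening_prob)
    draws = rng.uniform(size=len(trials))
    return ["awakening" if u < pi else "maintained" for u, pi in zip(draws, p)]


# ---------------------------------------------------------------------------
# photometry


def _shaped_noise(rng: np.random.Generator, n: int, sd: float, fs: float) -> np.ndarray:
    """iid Gaussian noise low-pass shaped at 6 Hz (the acquisition corner).

    The filter gain rescales the variance, so the output is re-standardized
    to ``sd`` to keep the configured per-sample amplitude meaningful.
    """
    x = rng.normal(0.0, 1.0, n)
    if sd == 0 or n < 30:
        return sd * x
    nyq = fs / 2
    if 6.0 < nyq:
        b, a = sps.butter(2, 6.0 / nyq)
        x = sps.filtfilt(b, a, x)
        s = x.std()
        if s > 0:
            x = x / s
    return sd * x


def _led_epochs(cfg: SimulationConfig) -> list[tuple[float, float]] | None:
    if cfg.led_cycle_s is None:
        return None
    on, off = cfg.led_cycle_s
    epochs = []
    t = 0.0
    while t < cfg.duration_s:
        epochs.append((t, min(t + on, cfg.duration_s)))
        t += on + off
    return epochs


def generate_photometry_session(
    cfg: SimulationConfig,
    trials: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> tuple[PhotometrySession, GroundTruth]:
    """Two-channel photometry with shared bleaching and injected responses.

    Both channels decay with the same slow exponential bleach (toward a
    70% plateau).  On trials whose ground-truth outcome is ``awakening``
    the signal channel additionally receives a rectangular surge over
    ``surge_window_s`` and a half-sine rise over ``rise_window_s``, scaled
    so the surge contributes exactly ``surge_amp`` ΔF/F percent relative to
    the local reference.  If ``truth`` is None, outcomes are drawn first.
    """
    rng = stream_rng(cfg.seed, "photometry")
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    if truth is None:
        truth = GroundTruth()
    if not truth.trial_outcomes:
        truth.trial_outcomes = assign_outcomes(cfg, trials)

    bleach = 0.7 + 0.3 * np.exp(-t / cfg.bleach_tau_s)
    f_sig, f_iso = 100.0, 70.0
    sig = f_sig * bleach
    iso = f_iso * bleach

    # stimulus-locked components on awakening trials only, signal channel only
    w0, w1 = cfg.surge_window_s
    r0, r1 = cfg.rise_window_s
    component = np.zeros(n)
    for onset, outcome in zip(trials["onset_s"].to_numpy(), truth.trial_outcomes):
        if outcome != "awakening":
            continue
        if cfg.surge_amp > 0:
            i0, i1 = int(round((onset + w0) * cfg.fs)), int(round((onset + w1) * cfg.fs))
            component[i0:i1] += cfg.surge_amp / 100.0
        if cfg.rise_amp > 0:
            i0, i1 = int(round((onset + r0) * cfg.fs)), int(round((onset + r1) * cfg.fs))
            if i1 > i0:
                phase = np.linspace(0, np.pi, i1 - i0)
                component[i0:i1] += cfg.rise_amp / 100.0 * np.sin(phase)
    sig = sig + component * f_sig * bleach

    noise_scale = cfg.noise_sd / 100.0
    sig = sig + _shaped_noise(rng, n, noise_scale * f_sig, cfg.fs) * bleach
    iso = iso + _shaped_noise(rng, n, noise_scale * f_iso, cfg.fs) * bleach

    truth.true_windows = []
    if cfg.surge_amp > 0:
        truth.true_windows.append(("surge", w0, w1, cfg.surge_amp))
    if cfg.rise_amp > 0:
        truth.true_windows.append(("rise", r0, r1, cfg.rise_amp))

    session = PhotometrySession(
        signal=sig, isosbestic=iso, fs=cfg.fs, led_epochs=_led_epochs(cfg)
    )
    return session, truth


# ---------------------------------------------------------------------------
# sleep records


def _sample_state_sequence(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Per-second hypnogram from a semi-Markov chain with exponential dwells.

    Transition structure: wake -> NREM; NREM -> REM with probability 0.25,
    otherwise wake; REM -> wake, mirroring rodent sleep architecture where
    REM is entered from NREM only.
    """
    n_sec = int(round(cfg.duration_s))
    seq: list[str] = []
    state = "wake"
    while len(seq) < n_sec:
        dwell = max(1, int(round(rng.exponential(cfg.state_dwell_s[state]))))
        seq.extend([state] * dwell)
        if state == "wake":
            state = "NREM"
        elif state == "NREM":
            state = "REM" if rng.uniform() < 0.25 else "wake"
        else:
            state = "wake"
    return seq[:n_sec]


def _band_noise(rng, n, fs, lo, hi):
    x = rng.normal(size=n)
    nyq = fs / 2
    hi = min(hi, 0.99 * nyq)
    if hi <= lo:
        return np.zeros(n)
    b, a = sps.butter(2, [lo / nyq, hi / nyq], btype="band")
    y = sps.filtfilt(b, a, x)
    s = y.std()
    return y / s if s > 0 else y


def generate_sleep_records(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, Trace, Trace]:
    """Hypnogram plus EEG/EMG traces with state-dependent spectral content.

    EEG is a sum of band-limited noise components gated per second by state:
    strong delta (1-4 Hz) and sigma (10-16 Hz) in NREM, theta (5-9 Hz) in
    REM, broadband desynchronized activity in wake.  EMG is white noise with
    muscle tone (RMS) highest in wake and lowest in REM.

    Returns ``(hypnogram, eeg, emg)``; the hypnogram is a DataFrame with
    columns ``epoch_start_s, state`` at 1-s resolution.
    """
    rng = stream_rng(cfg.seed, "sleep")
    seq = _sample_state_sequence(cfg, rng)
    n_sec = len(seq)
    n = int(round(n_sec * cfg.fs))

    # per-second gain envelopes, expanded to the sample grid
    gains = {
        #            wake NREM REM
        "delta": {"wake": 0.5, "NREM": 2.5, "REM": 0.5},
        "sigma": {"wake": 0.4, "NREM": 1.5, "REM": 0.4},
        "theta": {"wake": 0.8, "NREM": 0.5, "REM": 2.0},
        "broad": {"wake": 1.0, "NREM": 0.4, "REM": 0.6},
    }
    bands = {"delta": (1, 4), "sigma": (10, 16), "theta": (5, 9), "broad": (1, 45)}

    sec_idx = np.minimum((np.arange(n) / cfg.fs).astype(int), n_sec - 1)
    eeg = np.zeros(n)
    for name, (lo, hi) in bands.items():
        env = np.asarray([gains[name][s] for s in seq])[sec_idx]
        eeg += env * _band_noise(rng, n, cfg.fs, lo, hi)

    emg_gain = {"wake": 3.0, "NREM": 1.0, "REM": 0.5}
    emg_env = np.asarray([emg_gain[s] for s in seq])[sec_idx]
    emg = emg_env * rng.normal(size=n)

    hyp = pd.DataFrame({"epoch_start_s": np.arange(n_sec, dtype=float), "state": seq})
    return hyp, Trace(eeg, cfg.fs), Trace(emg, cfg.fs)


# ---------------------------------------------------------------------------
# anatomy

DV_STRIPS_MM = tuple(np.round(-3.3 - 0.1 * np.arange(9), 2))  # strip lower edges
AP_SLICES_MM = (-5.34, -5.46, -5.58, -5.70, -5.80)


def _gradient_pmf(params: dict, ap: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Separable Gaussian mass over the (AP, DV) grid, normalized to 1."""
    dvc = params.get("dv_mean", -3.7)
    dvs = params.get("dv_sd", 0.3)
    apc = params.get("ap_mean", -5.55)
    aps = params.get("ap_sd", 0.2)
    w_dv = np.exp(-0.5 * ((dv - dvc) / dvs) ** 2)
    w_ap = np.exp(-0.5 * ((ap - apc) / aps) ** 2)
    pmf = np.outer(w_ap, w_dv)
    return pmf / pmf.sum()


def generate_cell_counts(
    n_per_group: dict[str, int],
    gradient: dict[str, dict] | None = None,
    yield_scale: float = 1.0,
    missing_slice_prob: float = 0.0,
    seed: int = 0,
    total_cells: float = 300.0,
    dispersion: float = 5.0,
    yield_sd: float = 0.4,
    ap_slices: tuple[float, ...] = AP_SLICES_MM,
    dv_strips: tuple[float, ...] = DV_STRIPS_MM,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-animal labeled-cell counts over the (AP slice x DV strip) grid.

    Counts are negative binomial (overdispersed Poisson) around
    ``yield_a * total_cells * pmf(ap, dv)`` where the per-animal yield
    ``yield_a`` is log-normal with spread ``yield_sd`` around ``yield_scale``,
    emulating tracer-uptake variability.  Whole AP slices go missing per
    animal with probability ``missing_slice_prob`` (at least one slice is
    always kept), reproducing unequal histological slice availability.
    Missing slices are absent rows, never zero counts.

    Returns a tidy table with columns
    ``animal_id, group, ap_mm, dv_strip_mm, count``.
    """
    if not ap_slices or not dv_strips:
        raise ValueError("AP/DV grid must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STREAMS["cell_counts"],)))
    if gradient is None:
        gradient = {g: {} for g in n_per_group}
    ap = np.asarray(ap_slices)
    dv = np.asarray(dv_strips)
    rows = []
    for group, n_animals in n_per_group.items():
        pmf = _gradient_pmf(gradient.get(group, {}), ap, dv)
        for k in range(n_animals):
            animal = f"{group}_{k}"
            y = yield_scale * rng.lognormal(mean=0.0, sigma=yield_sd)
            keep = rng.uniform(size=ap.size) >= missing_slice_prob
            if not keep.any():
                keep[rng.integers(ap.size)] = True
            for i, a in enumerate(ap):
                if not keep[i]:
                    continue
                for j, d in enumerate(dv):
                    mu = max(y * total_cells * pmf[i, j], 1e-9)
                    # negative binomial with mean mu, size (dispersion) r
                    r = dispersion
                    p = r / (r + mu)
                    rows.append(
                        {
                            "animal_id": animal,
                            "group": group,
                            "ap_mm": a,
                            "dv_strip_mm": d,
                            "count": int(rng.negative_binomial(r, p)),
                        }
                    )
    truth = GroundTruth(gradient_params={g: dict(gradient.get(g, {})) for g in n_per_group})
    return pd.DataFrame(rows), truth


def generate_colocalization(
    n_mice: int,
    p_categories: tuple[float, float, float, float],
    cells_per_slice: float = 60.0,
    slices_per_mouse: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Dual-retrograde-tracer counts per slice from category probabilities.

    ``p_categories`` gives probabilities over cell categories
    (PRN-only, BF-only, both, none).  Per slice, a Poisson number of cells
    is drawn and split multinomially; red cells are BF-tagged
    (BF-only + both), green cells PRN-tagged (PRN-only + both).

    Returns columns ``mouse_id, slice_id, n_red, n_green, n_coloc, n_total``.
    """
    p = np.asarray(p_categories, dtype=float)
    if p.size != 4 or (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("p_categories must be 4 non-negative probabilities summing to 1")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STREAMS["colocalization"],)))
    rows = []
    for m in range(n_mice):
        for s in range(slices_per_mouse):
            n_cells = rng.poisson(cells_per_slice)
            prn_only, bf_only, both, none = rng.multinomial(n_cells, p)
            rows.append(
                {
                    "mouse_id": f"m{m}",
                    "slice_id": s,
                    "n_red": int(bf_only + both),
                    "n_green": int(prn_only + both),
                    "n_coloc": int(both),
                    "n_total": int(n_cells),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# epoch-level cohort generator (drives detection calibration at scale)


def generate_epoch_cohort(
    n_mice: int = 7,
    n_trials: int = 40,
    fs: float = 101.725,
    window_s: tuple[float, float] = (-5.0, 4.0),
    noise_sd: float = 1.0,
    bump_window_s: tuple[float, float] | None = None,
    bump_amp: float = 0.0,
    seed: int = 0,
    baseline_window_s: tuple[float, float] = (-5.0, 0.0),
) -> list[EpochMatrix]:
    """One epoched ΔF/F cohort (one EpochMatrix per mouse), noise + optional bump.

    Trial noise is iid Gaussian with ``noise_sd`` ΔF/F percent per sample on
    the decimated analysis grid; a rectangular bump of ``bump_amp`` percent
    over ``bump_window_s`` is added to every trial when requested.  Epochs
    are baseline-subtracted over ``baseline_window_s`` exactly as the
    preprocessing stage would do, so the cohort feeds straight into
    response-window detection.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STREAMS["epoch_cohort"],)))
    t = np.arange(window_s[0] * fs, window_s[1] * fs) / fs
    base_mask = (t >= baseline_window_s[0]) & (t < baseline_window_s[1])
    cohort = []
    for m in range(n_mice):
        data = rng.normal(0.0, noise_sd, size=(n_trials, t.size))
        if bump_window_s is not None and bump_amp != 0:
            in_bump = (t >= bump_window_s[0]) & (t < bump_window_s[1])
            data[:, in_bump] += bump_amp
        data = data - data[:, base_mask].mean(axis=1, keepdims=True)
        cohort.append(
            EpochMatrix(
                data=data,
                t=t,
                fs=fs,
                baseline_window_s=baseline_window_s,
                trial_ids=np.arange(n_trials),
            )
        )
    return cohort
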