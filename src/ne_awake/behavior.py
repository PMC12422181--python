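"""Trial-outcome classification and sleep-state transition analysis.

Outcome scoring mirrors the manual rules used for sound-evoked arousal
trials: the baseline state is read at the 5 s preceding trial onset (trials
with unstable baselines are discarded), and the behavioral response is
judged over the 3 s following onset on three channels — EEG activation,
EMG activation and movement on video.  Full awakening requires all three to
persist for at least 3 s; the same conjunction for less than 3 s is a short
awakening; single-channel responses are tagged by the activated channel;
no visible change on any channel is maintained sleep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TrialEvidence",
    "OUTCOME_LABELS",
    "classify_trial",
    "awakening_probability",
    "transition_probabilities",
    "window_mean_transition",
]

OUTCOME_LABELS = (
    "maintained",
    "awakening",
    "short_awakening",
    "eeg_activation",
    "emg_activation",
    "discarded",
)

Interval = tuple[float, float]


@dataclass(frozen=True)
class TrialEvidence:
    """Channel-activation evidence for one trial.

    Intervals are (start_s, end_s) relative to trial onset, confined to the
    response window; ``None`` means no activation on that channel.
    """

    baseline_stable: bool
    baseline_state: str
    eeg_activation: Interval | None = None
    emg_activation: Interval | None = None
    movement: Interval | None = None

    def __post_init__(self) -> None:
        for name in ("eeg_activation", "emg_activation", "movement"):
            iv = getattr(self, name)
            if iv is not None and not iv[0] < iv[1]:
                raise ValueError(f"{name} interval must have start < end")


def classify_trial(
    ev: TrialEvidence,
    min_duration_s: float = 3.0,
    response_window_s: float = 3.0,
    two_of_three: str = "precedence",
) -> str:
    """Apply the five-way outcome rule to one trial's evidence.

    * unstable baseline -> ``discarded``
    * EEG + EMG + movement all active and jointly persisting from their
      common onset to at least ``min_duration_s`` after trial onset ->
      ``awakening``; same conjunction for less -> ``short_awakening``
    * no activation anywhere -> ``maintained``
    * a single active channel -> ``eeg_activation`` / ``emg_activation``

    The source rules do not cover two active channels; by default
    (``two_of_three='precedence'``) such trials are tagged by the activated
    channel of highest precedence (EEG over EMG) with a warning.  A
    movement-only trial is neither maintained (a change was visible) nor an
    EEG/EMG activation, so it is discarded.
    """
    if not ev.baseline_stable:
        return "discarded"
    present = {
        "eeg": ev.eeg_activation,
        "emg": ev.emg_activation,
        "movement": ev.movement,
    }
    active = [k for k, v in present.items() if v is not None]
    if len(active) == 3:
        # joint activation must persist to min_duration_s after trial onset
        persists = min(iv[1] for iv in present.values()) >= min(
            min_duration_s, response_window_s
        )
        return "awakening" if persists else "short_awakening"
    if len(active) == 0:
        return "maintained"
    if len(active) == 1:
        only = active[0]
        if only == "eeg":
            return "eeg_activation"
        if only == "emg":
            return "emg_activation"
        log.warning("movement-only trial has no rule-defined label; discarding")
        return "discarded"
    # two of three
    if two_of_three != "precedence":
        raise ValueError(f"unknown two_of_three policy {two_of_three!r}")
    log.warning("two-channel activation %s not covered by the rules; using EEG>EMG precedence", active)
    if "eeg" in active:
        return "eeg_activation"
    return "emg_activation"


def awakening_probability(
    trials: pd.DataFrame,
    condition: dict | None = None,
    mouse: str = "mouse",
    baseline_state: str = "NREM",
) -> tuple[float, pd.Series]:
    """Probability of full awakening over NREM-baseline trials in a condition.

    ``trials`` needs columns ``outcome``, ``baseline_state`` and a mouse-id
    column; ``condition`` filters on equality per column.  Returns the
    pooled probability and the per-mouse probabilities for group statistics.
    """
    sub = trials[trials["baseline_state"] == baseline_state]
    if condition:
        for col, val in condition.items():
            sub = sub[sub[col] == val]
    if len(sub) == 0:
        raise ValueError(f"no {baseline_state}-baseline trials under condition {condition!r}")
    hit = (sub["outcome"] == "awakening").astype(float)
    per_mouse = hit.groupby(sub[mouse], observed=True).mean()
    return float(hit.mean()), per_mouse


def transition_probabilities(
    hypnogram: pd.DataFrame,
    onsets_s: np.ndarray,
    base_state: str = "NREM",
    horizon_s: int = 60,
    lookback_s: float = 5.0,
) -> pd.DataFrame:
    """Per-second state-probability curves after trial onset.

    For each second 0..``horizon_s`` the curve gives, over trials whose
    state ``lookback_s`` before onset equals ``base_state``, the fraction of
    trials in each state.  The hypnogram is a DataFrame with columns
    ``epoch_start_s, state`` at 1-s resolution.  Rows sum to 1.
    """
    states = hypnogram["state"].to_numpy()
    t0 = float(hypnogram["epoch_start_s"].iloc[0])
    n_sec = states.size
    labels = sorted(set(states) | {base_state})
    counts = np.zeros((horizon_s + 1, len(labels)))
    n_used = 0
    for onset in np.asarray(onsets_s, dtype=float):
        i_base = int(np.floor(onset - lookback_s - t0))
        i_on = int(np.floor(onset - t0))
        if i_base < 0 or i_on + horizon_s >= n_sec:
            continue
        if states[i_base] != base_state:
            continue
        for dt in range(horizon_s + 1):
            counts[dt, labels.index(states[i_on + dt])] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no qualifying trials with base state {base_state!r}")
    curves = pd.DataFrame(counts / n_used, columns=labels)
    curves.index.name = "t_s"
    return curves


def window_mean_transition(
    curves: pd.DataFrame,
    window_s: tuple[float, float] = (5.0, 10.0),
    target_state: str = "wake",
) -> float:
    """Mean target-state probability over a window (inclusive endpoints)."""
    if window_s[1] > curves.index.max():
        raise ValueError("window exceeds curve horizon")
    sel = (curves.index >= window_s[0]) & (curves.index <= window_s[1])
    if target_state not in curves.columns:
        return 0.0
    return float(curves.loc[sel, target_state].mean())
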