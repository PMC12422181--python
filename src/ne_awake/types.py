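"""Shared containers for signals, epoched data and statistical results.

Tabular data (trial tables, cell counts, colocalization counts, hypnograms)
are plain :class:`pandas.DataFrame` objects with documented column contracts
(see :mod:`ne_awake.io`); only containers that carry coupled metadata
(sampling rate, time axes, masks) get a dataclass here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trace",
    "PhotometrySession",
    "DffTrace",
    "EpochMatrix",
    "ResponseWindow",
    "SpectrogramResult",
    "ClusterStatResult",
]


@dataclass
class Trace:
    """A uniformly sampled single-channel recording."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class PhotometrySession:
    """Two-channel fluorescence recording with LED-on epochs.

    ``signal`` is the ligand-sensitive channel (465-nm excitation),
    ``isosbestic`` the ligand-insensitive 405-nm reference used to model
    motion and photobleaching.  ``led_epochs`` lists (start_s, end_s)
    intervals during which the excitation LEDs were on; ``None`` means the
    LEDs were on for the whole recording.
    """

    signal: np.ndarray
    isosbestic: np.ndarray
    fs: float
    led_epochs: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.isosbestic = np.asarray(self.isosbestic, dtype=float)
        if self.signal.shape != self.isosbestic.shape:
            raise ValueError("signal and isosbestic must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.led_epochs is not None:
            eps = sorted((float(a), float(b)) for a, b in self.led_epochs)
            for (a0, b0), (a1, _) in zip(eps, eps[1:]):
                if a1 < b0:
                    raise ValueError("led_epochs must be non-overlapping")
            for a, b in eps:
                if b <= a:
                    raise ValueError("led epoch must have start < end")
            self.led_epochs = eps

    @property
    def n_samples(self) -> int:
        return self.signal.size

    def valid_mask(self) -> np.ndarray:
        """Boolean per-sample mask, True where the LEDs were on."""
        if self.led_epochs is None:
            return np.ones(self.n_samples, dtype=bool)
        mask = np.zeros(self.n_samples, dtype=bool)
        for a, b in self.led_epochs:
            i0 = max(0, int(np.ceil(a * self.fs)))
            i1 = min(self.n_samples, int(np.floor(b * self.fs)) + 1)
            mask[i0:i1] = True
        return mask


@dataclass
class DffTrace:
    """Fractional fluorescence change in percent, masked to LED-on samples.

    ``values`` holds ΔF/F (%) where ``valid_mask`` is True and NaN elsewhere.
    """

    values: np.ndarray
    fs: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must align")


@dataclass
class EpochMatrix:
    """Trials x samples matrix of baseline-subtracted responses.

    ``t`` is seconds relative to event onset.  Each row's mean over
    ``baseline_window_s`` is zero (up to numerical tolerance) after
    baselining.
    """

    data: np.ndarray
    t: np.ndarray
    fs: float
    baseline_window_s: tuple[float, float]
    trial_ids: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.t = np.asarray(self.t, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.shape[1] != self.t.size:
            raise ValueError("data columns must match time axis")
        if self.data.shape[0] != self.trial_ids.size:
            raise ValueError("data rows must match trial_ids")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def mean_trace(self) -> np.ndarray:
        """Trial-averaged response (one trace per session/mouse)."""
        return self.data.mean(axis=0)


@dataclass
class ResponseWindow:
    """A run of contiguous post-stimulus bins significantly above zero."""

    region_label: str
    start_s: float
    end_s: float
    per_bin_p: np.ndarray = field(default_factory=lambda: np.array([]))
    direction: str = "above"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("window must have start < end")
        self.per_bin_p = np.asarray(self.per_bin_p, dtype=float)


@dataclass
class SpectrogramResult:
    """Baseline-normalized event-related spectral perturbation (dB)."""

    ersp: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray  # seconds relative to event onset
    baseline_window_s: tuple[float, float]
    n_trials: int

    def __post_init__(self) -> None:
        self.ersp = np.asarray(self.ersp, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.ersp.shape != (self.freqs.size, self.times.size):
            raise ValueError("ersp shape must be (n_freqs, n_times)")


@dataclass
class ClusterStatResult:
    """Cluster-corrected permutation test result on a time-frequency map."""

    t_map: np.ndarray
    clusters: list[dict]  # each: {"mask": bool array, "mass": float, "p": float}
    n_permutations: int
    alpha_cluster: float
    tail: str

    def min_p(self) -> float:
        if not self.clusters:
            return 1.0
        return min(c["p"] for c in self.clusters)
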