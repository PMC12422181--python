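"""ΔF/F preprocessing, epoching, response-window detection and quantification.

Pipeline:  raw two-channel session -> isosbestic fit (f0 reference) ->
ΔF/F percent -> per-trial epochs with baseline subtraction -> cohort-level
response-window detection (Kruskal-Wallis omnibus over 0.3-s bins, then
one-sided many-to-one correction against zero, consecutive significant bins
grouped into windows) -> per-trial element scores and their relation to
behavioral outcome and other physiology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _dunnett
from .types import DffTrace, EpochMatrix, PhotometrySession, ResponseWindow

__all__ = [
    "IsosbesticFit",
    "fit_isosbestic",
    "compute_dff",
    "epoch_trials",
    "WindowDetectionResult",
    "detect_response_windows",
    "score_elements",
    "compare_outcomes",
    "correlate_with_physiology",
    "peak_drop_correlation",
    "fit_outcome_model",
    "cross_correlate",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ΔF/F


@dataclass
class IsosbesticFit:
    """Least-squares scaling of the isosbestic channel onto the signal."""

    fitted: np.ndarray  # a*iso + b per sample; NaN where LED off
    coefficients: list[tuple[float, float]]  # (a, b) per fitted block
    per_block: bool


def _led_blocks(session: PhotometrySession) -> list[np.ndarray]:
    """Index arrays of contiguous LED-on runs."""
    mask = session.valid_mask()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, splits)


def fit_isosbestic(session: PhotometrySession, per_block: bool = True) -> IsosbesticFit:
    """Fit ``a * isosbestic + b`` to the signal over LED-on samples.

    ``per_block=True`` (default) fits each contiguous LED-on block
    separately, tracking bleaching that differs across hour-long blocks;
    ``per_block=False`` fits the whole session at once.
    """
    blocks = _led_blocks(session)
    if sum(b.size for b in blocks) < 2:
        raise ValueError("need at least two LED-on samples to fit the reference")
    if not per_block:
        blocks = [np.concatenate(blocks)]
    fitted = np.full(session.n_samples, np.nan)
    coeffs = []
    for b in blocks:
        iso = session.isosbestic[b]
        if np.ptp(iso) == 0:
            raise ValueError(
                f"isosbestic channel constant over samples {b[0]}..{b[-1]}; fit is degenerate"
            )
        a, c = np.polyfit(iso, session.signal[b], 1)
        fitted[b] = a * iso + c
        coeffs.append((float(a), float(c)))
    return IsosbesticFit(fitted=fitted, coefficients=coeffs, per_block=per_block)


def compute_dff(session: PhotometrySession, fit: IsosbesticFit) -> DffTrace:
    """ΔF/F = (signal - f0) / f0 * 100 with the fitted reference as f0."""
    valid = session.valid_mask() & np.isfinite(fit.fitted)
    ref = fit.fitted
    bad = valid & (ref <= 0)
    if bad.any():
        lo, hi = np.flatnonzero(bad)[[0, -1]]
        raise ValueError(
            f"fitted reference non-positive on valid samples {lo}..{hi}; cannot form ΔF/F"
        )
    values = np.full(session.n_samples, np.nan)
    values[valid] = (session.signal[valid] - ref[valid]) / ref[valid] * 100.0
    return DffTrace(values=values, fs=session.fs, valid_mask=valid)


# ---------------------------------------------------------------------------
# epoching


def epoch_trials(
    dff: DffTrace,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = (-5.0, 4.0),
    baseline_window_s: tuple[float, float] = (-5.0, 0.0),
    decimate: int = 10,
) -> EpochMatrix:
    """Cut per-trial windows, decimate, and subtract the per-trial baseline.

    Decimation averages consecutive ``decimate``-sample groups (the raw
    trace is already low-pass shaped well below the decimated Nyquist, so
    plain block averaging is alias-safe); ``decimate=1`` keeps the raw rate.
    Trials whose window leaves the recording or touches LED-off samples are
    dropped and counted in ``n_dropped``.
    """
    if not window_s[0] < window_s[1]:
        raise ValueError("window must have start < end")
    onsets_s = np.asarray(onsets_s, dtype=float)
    fs = dff.fs
    n0 = int(round(window_s[0] * fs))
    n1 = int(round(window_s[1] * fs))
    length = n1 - n0
    length -= length % decimate  # full decimation blocks only
    rows, ids = [], []
    n_dropped = 0
    for tid, onset in enumerate(onsets_s):
        i0 = int(round(onset * fs)) + n0
        i1 = i0 + length
        if i0 < 0 or i1 > dff.values.size or not dff.valid_mask[i0:i1].all():
            n_dropped += 1
            continue
        seg = dff.values[i0:i1]
        if decimate > 1:
            seg = seg.reshape(-1, decimate).mean(axis=1)
        rows.append(seg)
        ids.append(tid)
    if not rows:
        raise ValueError("every trial was dropped (windows outside valid samples)")
    if n_dropped:
        log.info("epoch_trials: dropped %d/%d trials", n_dropped, onsets_s.size)
    fs_out = fs / decimate
    t = (np.arange(length // decimate) + 0.5) * decimate / fs + n0 / fs
    data = np.asarray(rows)
    base = (t >= baseline_window_s[0]) & (t < baseline_window_s[1])
    if not base.any():
        raise ValueError("baseline window contains no samples")
    data = data - data[:, base].mean(axis=1, keepdims=True)
    return EpochMatrix(
        data=data,
        t=t,
        fs=fs_out,
        baseline_window_s=baseline_window_s,
        trial_ids=np.asarray(ids),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# response-window detection


@dataclass
class WindowDetectionResult:
    windows: list[ResponseWindow]
    bin_edges_s: np.ndarray
    bin_means: np.ndarray  # (n_mice, n_bins)
    kw_stat: float
    kw_p: float
    corrected_p: np.ndarray  # per bin; NaN if omnibus not significant
    rho: float = 0.0
    df: int = 0


def bin_epoch_means(
    epochs: EpochMatrix, bin_s: float, span_s: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged mean per analysis bin; partial trailing bin dropped."""
    n_bins = int(np.floor((span_s[1] - span_s[0]) / bin_s + 1e-9))
    leftover = (span_s[1] - span_s[0]) - n_bins * bin_s
    if leftover > 1e-9:
        log.info("analysis span not divisible by bin; dropping trailing %.3f s", leftover)
    edges = span_s[0] + bin_s * np.arange(n_bins + 1)
    trace = epochs.mean_trace()
    means = np.empty(n_bins)
    for k in range(n_bins):
        sel = (epochs.t >= edges[k]) & (epochs.t < edges[k + 1])
        if not sel.any():
            raise ValueError(f"bin {k} ({edges[k]:.2f}-{edges[k+1]:.2f} s) contains no samples")
        means[k] = trace[sel].mean()
    return means, edges


def detect_response_windows(
    epochs_per_mouse: list[EpochMatrix],
    bin_s: float = 0.3,
    analysis_span_s: tuple[float, float] = (0.0, 3.9),
    alpha: float = 0.05,
    method: str = "mvt",
    n_mc: int = 100_000,
    seed: int | None = 0,
    region_label: str = "",
) -> WindowDetectionResult:
    """Cohort-level detection of post-stimulus bins significantly above zero.

    Stage 1: omnibus Kruskal-Wallis (tie-corrected midranks) across the
    analysis bins of per-mouse bin means; if not significant at ``alpha``
    no windows are returned.  Stage 2: one-sided many-to-one comparison of
    each bin against zero with family correction over all bins
    (``method='mvt'`` multivariate-t CDF, ``'mc'`` max-statistic simulation).
    Stage 3: maximal runs of consecutive significant bins become
    :class:`ResponseWindow` objects carrying per-bin corrected p-values.
    """
    if len(epochs_per_mouse) < 2:
        raise ValueError("need at least two mice")
    per_mouse = []
    edges = None
    for ep in epochs_per_mouse:
        m, edges = bin_epoch_means(ep, bin_s, analysis_span_s)
        per_mouse.append(m)
    M = np.asarray(per_mouse)  # (n_mice, n_bins)
    n_bins = M.shape[1]

    kw_stat, kw_p = stats.kruskal(*[M[:, k] for k in range(n_bins)])
    if kw_p >= alpha:
        return WindowDetectionResult(
            windows=[],
            bin_edges_s=edges,
            bin_means=M,
            kw_stat=float(kw_stat),
            kw_p=float(kw_p),
            corrected_p=np.full(n_bins, np.nan),
        )

    tstats, df = _dunnett.one_sample_tstats(M)
    rho = _dunnett.equicorrelation(M)
    if method == "mvt":
        p_corr = _dunnett.corrected_pvalues_mvt(tstats, rho, df, seed=seed)
    elif method == "mc":
        p_corr = _dunnett.corrected_pvalues_mc(tstats, rho, df, n_draws=n_mc, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")

    sig = p_corr <= alpha
    windows: list[ResponseWindow] = []
    k = 0
    while k < n_bins:
        if sig[k]:
            j = k
            while j + 1 < n_bins and sig[j + 1]:
                j += 1
            windows.append(
                ResponseWindow(
                    region_label=region_label,
                    start_s=float(edges[k]),
                    end_s=float(edges[j + 1]),
                    per_bin_p=p_corr[k : j + 1],
                )
            )
            k = j + 1
        else:
            k += 1
    return WindowDetectionResult(
        windows=windows,
        bin_edges_s=edges,
        bin_means=M,
        kw_stat=float(kw_stat),
        kw_p=float(kw_p),
        corrected_p=p_corr,
        rho=rho,
        df=df,
    )


# ---------------------------------------------------------------------------
# element scores and their relations


def score_elements(
    epochs: EpochMatrix,
    window: ResponseWindow,
    outcomes: np.ndarray | None = None,
    drop_span_s: float = 2.0,
) -> pd.DataFrame:
    """Per-trial window mean and post-window minimum (the signal drop).

    The drop score is the trial's minimum ΔF/F within ``drop_span_s``
    seconds after the window end.  Returns columns
    ``trial_id, score, drop[, outcome]``.
    """
    if window.start_s < epochs.t[0] or window.end_s > epochs.t[-1] + 1.0 / epochs.fs:
        raise ValueError("response window outside epoch span")
    in_win = (epochs.t >= window.start_s) & (epochs.t < window.end_s)
    post = (epochs.t >= window.end_s) & (epochs.t <= window.end_s + drop_span_s)
    score = epochs.data[:, in_win].mean(axis=1)
    drop = epochs.data[:, post].min(axis=1) if post.any() else np.full(epochs.n_trials, np.nan)
    out = pd.DataFrame({"trial_id": epochs.trial_ids, "score": score, "drop": drop})
    if outcomes is not None:
        out["outcome"] = np.asarray(outcomes)
    return out


@dataclass
class PairedResult:
    t: float
    df: int
    p: float
    n: int
    per_mouse_means: pd.DataFrame = field(default_factory=pd.DataFrame)


def compare_outcomes(
    scores: pd.DataFrame,
    mouse: str = "mouse",
    outcome_pair: tuple[str, str] = ("awakening", "maintained"),
) -> PairedResult:
    """Paired t test of per-mouse mean scores between two trial outcomes.

    ``scores`` needs columns ``score``, ``outcome`` and a mouse-id column.
    Mice lacking trials in either outcome are excluded (logged).  The t
    statistic is for (first - second) outcome with df = n_mice - 1.
    """
    a, b = outcome_pair
    sub = scores[scores["outcome"].isin(outcome_pair)]
    means = sub.groupby([mouse, "outcome"], observed=True)["score"].mean().unstack("outcome")
    usable = means.dropna(subset=[c for c in outcome_pair if c in means.columns], how="any")
    if a not in means.columns or b not in means.columns:
        usable = means.iloc[0:0]
    excluded = set(means.index) - set(usable.index)
    if excluded:
        log.info("compare_outcomes: excluding mice without both outcomes: %s", sorted(excluded))
    if len(usable) < 2:
        raise ValueError("need at least two mice with trials in both outcomes")
    d = (usable[a] - usable[b]).to_numpy()
    if np.allclose(d, 0.0):
        t, p = 0.0, 1.0  # identical per-mouse means: no effect, not undefined
    else:
        t, p = stats.ttest_rel(usable[a], usable[b])
    return PairedResult(t=float(t), df=len(usable) - 1, p=float(p), n=len(usable), per_mouse_means=usable)


def per_mouse_correlations(
    trials: pd.DataFrame, score_col: str, covariate_col: str, mouse: str = "mouse"
) -> pd.Series:
    """Per-mouse Pearson r between a response element and a covariate.

    Mice with fewer than 3 trials or zero variance on either variable are
    excluded with a log entry.
    """
    rs = {}
    for mid, g in trials.groupby(mouse, observed=True):
        if len(g) < 3:
            log.info("correlations: mouse %s has <3 trials; excluded", mid)
            continue
        x, y = g[score_col].to_numpy(float), g[covariate_col].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            log.info("correlations: mouse %s has zero-variance data; excluded", mid)
            continue
        rs[mid] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(rs, name="r")


def correlate_with_physiology(per_element_r: dict[str, pd.Series]) -> dict:
    """Group tests over per-mouse correlation coefficients by element type.

    One-way ANOVA across element types plus, per element, a one-sample t of
    the mean r against zero.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in per_element_r.items() if len(v) > 1}
    out: dict = {"per_element": {}}
    if len(groups) >= 2:
        f, p = stats.f_oneway(*groups.values())
        out["anova"] = {"F": float(f), "p": float(p)}
    for name, r in groups.items():
        t, p = stats.ttest_1samp(r, 0.0)
        out["per_element"][name] = {"mean_r": float(np.mean(r)), "t": float(t), "p": float(p)}
    return out


def peak_drop_correlation(scores: pd.DataFrame) -> tuple[float, float]:
    """Pooled Pearson correlation between window score and post-window drop."""
    x = scores["score"].to_numpy(float)
    y = scores["drop"].to_numpy(float)
    if x.size < 3:
        raise ValueError("need at least 3 trials")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class OutcomeModelResult:
    params: pd.DataFrame
    wald_z: pd.DataFrame
    wald_p: pd.DataFrame
    chi2: float
    df: int
    p_lrt: float
    separation: bool = False


def fit_outcome_model(features: pd.DataFrame, outcomes: np.ndarray) -> OutcomeModelResult:
    """Multinomial logistic regression of trial outcome on response elements.

    Fits outcome ~ features by maximum likelihood (binomial when two
    classes) and reports coefficients, per-feature Wald statistics and the
    likelihood-ratio χ² against the intercept-only model with
    df = n_features x (K - 1).  Complete separation is flagged and the fit
    falls back to a small L2 penalty.
    """
    import statsmodels.api as sm

    y = pd.Series(outcomes).astype("category")
    if len(y.cat.categories) < 2:
        raise ValueError("need at least two outcome classes")
    X = sm.add_constant(features.astype(float), has_constant="add")
    codes = y.cat.codes.to_numpy()
    model = sm.MNLogit(codes, X)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200)
            if not np.isfinite(fit.params.to_numpy()).all() or not fit.mle_retvals.get(
                "converged", True
            ):
                raise RuntimeError("non-finite or unconverged ML fit")
        except Exception:
            separation = True
            fit = model.fit_regularized(disp=0, alpha=1e-4, maxiter=500)
    k = len(y.cat.categories)
    n_features = features.shape[1]
    llf = float(fit.llf)
    null_model = sm.MNLogit(codes, np.ones((len(codes), 1)))
    llnull = float(null_model.fit(disp=0).llf)
    chi2 = max(0.0, 2.0 * (llf - llnull))
    df = n_features * (k - 1)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            z = fit.tvalues
            pz = fit.pvalues
        except Exception:
            z = pd.DataFrame(np.nan, index=fit.params.index, columns=fit.params.columns)
            pz = z.copy()
    return OutcomeModelResult(
        params=pd.DataFrame(fit.params),
        wald_z=pd.DataFrame(z),
        wald_p=pd.DataFrame(pz),
        chi2=chi2,
        df=df,
        p_lrt=p,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# cross-correlation


def cross_correlate(
    a: np.ndarray, b: np.ndarray, fs: float, max_lag_s: float
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalized cross-correlation of two traces over ±``max_lag_s``.

    Sign convention: a peak at **positive** lag means ``b`` lags (is a
    delayed copy of) ``a``.  Returns ``(lags_s, cc, peak_lag_s, peak_value)``
    where the peak is the maximum of the correlation.  Normalization is
    biased (divided by the full length n), which keeps edge lags from
    blowing up; with z-scored inputs ``cc`` is 1 at lag 0 for identical
    traces.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = min(a.size, b.size)
    max_lag = int(round(max_lag_s * fs))
    if n <= max_lag:
        raise ValueError("traces shorter than the requested maximum lag")
    a, b = a[:n], b[:n]
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    full = np.correlate(bz, az, mode="full") / n
    lags = (np.arange(full.size) - (n - 1)) / fs
    sel = (lags >= -max_lag_s - 1e-12) & (lags <= max_lag_s + 1e-12)
    lags, cc = lags[sel], full[sel]
    i = int(np.argmax(cc))
    return lags, cc, float(lags[i]), float(cc[i])
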