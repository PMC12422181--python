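"""Many-to-one (Dunnett-style) one-sided comparisons against a zero reference.

The use case: K per-stimulus time bins, each summarized by one value per
mouse, tested one-sided for mean > 0 with family-wise control over the K
comparisons.  Because the same mice contribute every bin, the K t statistics
are correlated; the correction models them as an equicorrelated multivariate
t with df = n_mice - 1 and correlation estimated from the data (the mean
off-diagonal bin correlation).  Corrected p for bin k is
P(max_j T_j >= t_k) under that null.

Two evaluation routes are provided: ``mvt`` integrates the multivariate-t
CDF (quasi-Monte Carlo, seeded); ``mc`` simulates the max-statistic null
directly and serves as the independent oracle in tests.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "one_sample_tstats",
    "equicorrelation",
    "corrected_pvalues_mvt",
    "corrected_pvalues_mc",
]


def one_sample_tstats(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-column one-sample t statistics vs 0 for an (n, K) matrix."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two observations per bin")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t, n - 1


def equicorrelation(values: np.ndarray) -> float:
    """Mean off-diagonal correlation across columns, clipped to [0, 0.95].

    With few subjects the full K x K sample correlation matrix is singular;
    collapsing to its mean off-diagonal element gives a stable exchangeable
    approximation.  Negative estimates are clipped to 0 (conservative: less
    correlation means a stricter max-statistic threshold).
    """
    values = np.asarray(values, dtype=float)
    k = values.shape[1]
    if k < 2 or values.shape[0] < 3:
        return 0.0
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(values, rowvar=False)
    off = c[~np.eye(k, dtype=bool)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        return 0.0
    return float(np.clip(off.mean(), 0.0, 0.95))


def corrected_pvalues_mvt(
    tstats: np.ndarray, rho: float, df: int, seed: int | None = None
) -> np.ndarray:
    """Family-corrected one-sided p via the equicorrelated multivariate-t CDF."""
    tstats = np.asarray(tstats, dtype=float)
    k = tstats.size
    shape = (1.0 - rho) * np.eye(k) + rho * np.ones((k, k))
    rs = np.random.default_rng(seed if seed is not None else 0)
    out = np.empty(k)
    for i, t in enumerate(tstats):
        cdf = stats.multivariate_t.cdf(
            np.full(k, t), loc=np.zeros(k), shape=shape, df=df, random_state=rs
        )
        out[i] = 1.0 - float(np.clip(cdf, 0.0, 1.0))
    # P(max >= t) can never be below the single-comparison p; enforcing the
    # bound also guards against QMC round-off when the CDF is near 1
    single = stats.t.sf(tstats, df)
    return np.clip(np.maximum(out, single), 0.0, 1.0)


def corrected_pvalues_mc(
    tstats: np.ndarray,
    rho: float,
    df: int,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> np.ndarray:
    """Same correction via direct simulation of the max-t null distribution.

    Draws equicorrelated normal vectors Z = sqrt(rho) * g + sqrt(1-rho) * e
    and one chi-square scale per draw, forming multivariate-t samples whose
    maximum gives the null of the max statistic.
    """
    tstats = np.asarray(tstats, dtype=float)
    k = tstats.size
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(n_draws, 1))
    e = rng.normal(size=(n_draws, k))
    z = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e
    s = np.sqrt(rng.chisquare(df, size=(n_draws, 1)) / df)
    max_t = (z / s).max(axis=1)
    return np.asarray([(max_t >= t).mean() for t in tstats])
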