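"""Yield-normalized spatial comparison of projection-defined cell counts.

Projection-defined locus-coeruleus subpopulations are compared on an
(AP slice x DV strip) grid of manually counted labeled neurons.  Because
animals differ both in tracer yield and in which coronal slices were
recoverable, raw counts are normalized by a chain of yield corrections:

* expected yield  E(loc)  = mean count across animals with data at loc
* animal yield    A(a)    = total count of animal a over its available strips
* normal yield    N(a)    = sum of E over the locations available in a
* normalized gradient     = count / (E(loc) * A(a) / N(a))
* average distribution    = E / sum(E)

A group's distribution map is the group mean of normalized gradients times
the average distribution, renormalized to unit mass.  Groups are compared
by the square root of the (validity-weighted) mean squared difference
between their maps, with inference from a Monte Carlo permutation test that
reassigns animals to groups at fixed group sizes; axis-specific location
tests compare distribution-weighted mean DV (or AP) positions two-tailed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedCounts",
    "normalize_counts",
    "group_distribution",
    "diff_statistic",
    "PermutationResult",
    "permutation_test",
    "colocalization_summary",
    "subpopulation_test",
]


@dataclass
class NormalizedCounts:
    """Normalized gradients plus the shared references of the cohort.

    ``norm`` is animals x locations (MultiIndex (ap_mm, dv_strip_mm));
    NaN marks locations missing for that animal.  ``avg_dist`` is the
    cohort-average distribution (expected yield, renormalized), and
    ``valid_frac`` the per-location fraction of animals contributing
    numeric data (the permutation weights).
    """

    norm: pd.DataFrame
    avg_dist: pd.Series
    valid_frac: pd.Series
    expected_yield: pd.Series
    groups: pd.Series  # animal -> group label

    def animal_distribution(self, animal: str) -> pd.Series:
        """One animal's distribution map: gradient x avg_dist, unit mass.

        Algebraically this equals the animal's own count distribution over
        its available locations, so it is exactly invariant to scaling all
        of the animal's counts.
        """
        m = self.norm.loc[animal] * self.avg_dist
        return m / m.sum()


def normalize_counts(table: pd.DataFrame) -> NormalizedCounts:
    """Run the yield-normalization chain on a tidy cell-count table.

    ``table`` needs columns ``animal_id, group, ap_mm, dv_strip_mm, count``;
    missing slices are absent rows (never zero counts).  Animals with no
    numeric counts are excluded with a log entry.
    """
    required = {"animal_id", "group", "ap_mm", "dv_strip_mm", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cell-count table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("cell-count table is empty")
    wide = table.pivot_table(
        index="animal_id", columns=["ap_mm", "dv_strip_mm"], values="count", aggfunc="sum"
    )
    all_missing = wide.isna().all(axis=1)
    if all_missing.any():
        log.info("excluding animals with no numeric data: %s", list(wide.index[all_missing]))
        wide = wide.loc[~all_missing]
    if len(wide) == 0:
        raise ValueError("no animal has numeric counts")
    expected = wide.mean(axis=0, skipna=True)  # E(loc)
    animal_yield = wide.sum(axis=1, skipna=True)  # A(a)
    avail = wide.notna()
    normal_yield = avail.mul(expected, axis=1).sum(axis=1)  # N(a)
    denom = pd.DataFrame(
        np.outer(animal_yield / normal_yield, expected),
        index=wide.index,
        columns=wide.columns,
    )
    norm = wide / denom
    avg_dist = expected / expected.sum()
    valid_frac = avail.mean(axis=0)
    groups = table.drop_duplicates("animal_id").set_index("animal_id")["group"]
    return NormalizedCounts(
        norm=norm,
        avg_dist=avg_dist,
        valid_frac=valid_frac,
        expected_yield=expected,
        groups=groups.loc[norm.index],
    )


def group_distribution(nc: NormalizedCounts, group: str) -> pd.Series:
    """Group distribution map: mean normalized gradient x avg_dist, unit mass."""
    members = nc.groups.index[nc.groups == group]
    if len(members) == 0:
        raise ValueError(f"no animals in group {group!r}")
    mean_grad = nc.norm.loc[members].mean(axis=0, skipna=True)
    m = mean_grad * nc.avg_dist
    total = m.sum(skipna=True)
    if not total > 0:
        raise ValueError(f"group {group!r} has no mass")
    return m / total


def diff_statistic(
    map_a: pd.Series | np.ndarray,
    map_b: pd.Series | np.ndarray,
    weights: pd.Series | np.ndarray | None = None,
) -> float:
    """sqrt of the weighted mean squared difference between two maps.

    Locations where either map is undefined (NaN) are excluded; ``weights``
    default to 1 (unweighted).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("maps share no defined locations")
    d2 = (a[ok] - b[ok]) ** 2
    return float(np.sqrt((w[ok] * d2).sum() / w[ok].sum()))


# ---------------------------------------------------------------------------
# permutation inference


def _assignment_statistics(
    X: np.ndarray,  # (n_animals, n_locs) normalized gradients, NaN = missing
    d: np.ndarray,  # avg_dist per loc
    w: np.ndarray,  # validity weights per loc
    coord: np.ndarray | None,  # per-loc coordinate for location statistics
    g1: np.ndarray,  # (n_assign, n_animals) boolean group-1 membership
    statistic: str,
) -> np.ndarray:
    """Vectorized statistic over many group assignments at once."""
    V = np.isfinite(X)
    X0 = np.where(V, X, 0.0)
    g2 = ~g1

    def group_maps(g):
        cnt = g.astype(float) @ V
        s = g.astype(float) @ X0
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
        m = mean * d
        tot = np.nansum(m, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return m / tot

    p1, p2 = group_maps(g1), group_maps(g2)
    if statistic == "overall":
        ok = np.isfinite(p1) & np.isfinite(p2)
        d2 = np.where(ok, (np.nan_to_num(p1) - np.nan_to_num(p2)) ** 2, 0.0)
        wsum = (w * ok).sum(axis=1)
        return np.sqrt((w * d2).sum(axis=1) / wsum)
    if coord is None:
        raise ValueError("coordinate vector required for location statistics")
    loc1 = np.nansum(p1 * coord, axis=1)
    loc2 = np.nansum(p2 * coord, axis=1)
    return loc1 - loc2


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    p_value: float
    n_perm: int
    exact: bool
    null_mean: float
    null_sd: float
    tail: str


def permutation_test(
    table: pd.DataFrame,
    statistic: str = "overall",
    n_perm: int = 100_000,
    seed: int | None = 0,
    weighted: bool = True,
    exact_threshold: int = 10_000,
) -> PermutationResult:
    """Monte Carlo permutation test on the group-distribution difference.

    ``statistic='overall'`` uses the weighted root-mean-square map
    difference, one-tailed (reject for large values).  ``'dv_location'`` /
    ``'ap_location'`` use the difference of distribution-weighted mean
    strip/slice coordinates, two-tailed on the absolute difference.
    Group sizes are held fixed while animal-to-group assignment is
    randomized; when the number of distinct assignments is at most
    ``exact_threshold`` the null is enumerated exactly instead of sampled.
    Monte Carlo p = (1 + #{null >= observed}) / (n_perm + 1), ties counted
    as exceeding (conservative).
    """
    if statistic not in ("overall", "dv_location", "ap_location"):
        raise ValueError(f"unknown statistic {statistic!r}")
    nc = normalize_counts(table)
    group_names = sorted(nc.groups.unique())
    if len(group_names) != 2:
        raise ValueError("exactly two groups are required")
    sizes = nc.groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs at least two animals")
    g_obs = (nc.groups == group_names[0]).to_numpy()
    n_animals = g_obs.size
    n1 = int(g_obs.sum())

    X = nc.norm.to_numpy()
    d = nc.avg_dist.to_numpy()
    w = nc.valid_frac.to_numpy() if weighted else np.ones_like(d)
    if statistic == "dv_location":
        coord = nc.norm.columns.get_level_values("dv_strip_mm").to_numpy(dtype=float)
    elif statistic == "ap_location":
        coord = nc.norm.columns.get_level_values("ap_mm").to_numpy(dtype=float)
    else:
        coord = None

    obs = float(
        _assignment_statistics(X, d, w, coord, g_obs[None, :], statistic)[0]
    )
    two_tailed = statistic != "overall"

    n_total = math.comb(n_animals, n1)
    exact = n_total <= exact_threshold
    if exact:
        G = np.zeros((n_total, n_animals), dtype=bool)
        for i, combo in enumerate(combinations(range(n_animals), n1)):
            G[i, list(combo)] = True
        null = _assignment_statistics(X, d, w, coord, G, statistic)
        vals = np.abs(null) if two_tailed else null
        ref = abs(obs) if two_tailed else obs
        p = float((vals >= ref - 1e-12).mean())
        n_eff = n_total
    else:
        rng = np.random.default_rng(seed)
        G = np.zeros((n_perm, n_animals), dtype=bool)
        for i in range(n_perm):
            G[i, rng.choice(n_animals, size=n1, replace=False)] = True
        null = _assignment_statistics(X, d, w, coord, G, statistic)
        vals = np.abs(null) if two_tailed else null
        ref = abs(obs) if two_tailed else obs
        p = (1.0 + float((vals >= ref - 1e-12).sum())) / (n_perm + 1.0)
        n_eff = n_perm
    return PermutationResult(
        statistic=statistic,
        observed=obs,
        p_value=p,
        n_perm=n_eff,
        exact=exact,
        null_mean=float(np.nanmean(null)),
        null_sd=float(np.nanstd(null)),
        tail="two-tailed" if two_tailed else "one-tailed",
    )


# ---------------------------------------------------------------------------
# colocalization


def colocalization_summary(counts: pd.DataFrame) -> dict:
    """Per-mouse colocalization ratios and category fractions.

    Per slice: BF ratio = n_coloc / n_red, PRN ratio = n_coloc / n_green
    (red = BF-tagged, green = PRN-tagged); zero-denominator slices are
    skipped with a log entry.  Per-mouse means of the slice ratios are
    returned, plus category fractions (PRN-only, BF-only, both, none) when
    an ``n_total`` column supplies the total-cell denominator.
    """
    required = {"mouse_id", "slice_id", "n_red", "n_green", "n_coloc"}
    if not required <= set(counts.columns):
        raise ValueError(f"colocalization table needs columns {sorted(required)}")
    bad = counts["n_coloc"] > counts[["n_red", "n_green"]].min(axis=1)
    if bad.any():
        raise ValueError(f"n_coloc exceeds channel counts at rows {list(counts.index[bad])}")
    df = counts.copy()
    zero_red = df["n_red"] == 0
    zero_green = df["n_green"] == 0
    if (zero_red | zero_green).any():
        log.info("skipping zero-denominator slices: %d", int((zero_red | zero_green).sum()))
    df["bf_ratio"] = np.where(zero_red, np.nan, df["n_coloc"] / df["n_red"].replace(0, np.nan))
    df["prn_ratio"] = np.where(zero_green, np.nan, df["n_coloc"] / df["n_green"].replace(0, np.nan))
    per_mouse = df.groupby("mouse_id")[["bf_ratio", "prn_ratio"]].mean()
    out = {"per_slice": df, "per_mouse": per_mouse}
    if "n_total" in df.columns:
        g = df.groupby("mouse_id")[["n_red", "n_green", "n_coloc", "n_total"]].sum()
        frac = pd.DataFrame(
            {
                "prn_only": (g["n_green"] - g["n_coloc"]) / g["n_total"],
                "bf_only": (g["n_red"] - g["n_coloc"]) / g["n_total"],
                "both": g["n_coloc"] / g["n_total"],
            }
        )
        frac["none"] = 1.0 - frac.sum(axis=1)
        out["category_fractions"] = frac
    return out


def subpopulation_test(
    per_mouse_ratios: np.ndarray | pd.Series,
    null_value: float = 1.0,
    alternative: str = "less",
) -> tuple[float, int, float]:
    """One-sample t of per-mouse colocalization ratios against full overlap.

    A ratio of 1 would mean one subpopulation is entirely contained in the
    other; the default alternative tests ratio < 1.
    Returns ``(t, df, p)``.
    """
    r = np.asarray(per_mouse_ratios, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 2:
        raise ValueError("need at least two mice")
    if np.std(r, ddof=1) == 0:
        raise ValueError("zero variance across mice; t undefined")
    res = stats.ttest_1samp(r, null_value, alternative=alternative)
    return float(res.statistic), r.size - 1, float(res.pvalue)
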