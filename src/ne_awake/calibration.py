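"""Cohort-level calibration and power studies for the statistical stages.

These routines run a stage many times on freshly generated synthetic
cohorts and report empirical error or recovery rates.  They back both the
calibration tests and the reproduction script; problem sizes are arguments
so callers choose their own compute budget.
"""

from __future__ import annotations

import numpy as np

from . import anatomy, eeg, photometry, synth

__all__ = [
    "anatomy_null_rejection_rate",
    "window_detection_rates",
    "cluster_null_rejection_rate",
    "cluster_effect_overlap",
]


def anatomy_null_rejection_rate(
    n_cohorts: int = 500,
    n_per_group: dict[str, int] | None = None,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    missing_slice_prob: float = 0.3,
) -> float:
    """Overall-statistic rejection rate on cohorts with identical gradients.

    Both groups draw from the same spatial distribution, so rejections are
    false positives; a calibrated test rejects at about ``alpha``.
    """
    if n_per_group is None:
        n_per_group = {"PRN": 8, "BF": 7}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_cohorts, dtype=np.uint32)
    rejections = 0
    for i in range(n_cohorts):
        table, _ = synth.generate_cell_counts(
            n_per_group,
            gradient=None,  # identical default gradient for both groups
            missing_slice_prob=missing_slice_prob,
            seed=int(child_seeds[2 * i]),
        )
        res = anatomy.permutation_test(
            table, statistic="overall", n_perm=n_perm, seed=int(child_seeds[2 * i + 1])
        )
        rejections += res.p_value <= alpha
    return rejections / n_cohorts


def window_detection_rates(
    n_runs: int = 100,
    n_mice: int = 7,
    n_trials: int = 40,
    noise_sd: float = 1.0,
    bump_window_s: tuple[float, float] | None = (0.3, 0.6),
    bump_amp: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Window-detection outcome rates over repeated synthetic cohorts.

    With a bump injected, ``exact_recovery`` counts runs whose detected
    window set contains exactly the injected window and nothing else.  With
    ``bump_window_s=None`` the cohorts are pure noise and ``any_window`` is
    the family-wise false-window rate.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_runs, dtype=np.uint32)
    exact = 0
    contains = 0
    any_window = 0
    for i in range(n_runs):
        cohort = synth.generate_epoch_cohort(
            n_mice=n_mice,
            n_trials=n_trials,
            noise_sd=noise_sd,
            bump_window_s=bump_window_s,
            bump_amp=bump_amp if bump_window_s else 0.0,
            seed=int(child_seeds[2 * i]),
        )
        res = photometry.detect_response_windows(
            cohort, alpha=alpha, seed=int(child_seeds[2 * i + 1])
        )
        wins = [(round(w.start_s, 6), round(w.end_s, 6)) for w in res.windows]
        any_window += bool(wins)
        if bump_window_s is not None:
            target = (round(bump_window_s[0], 6), round(bump_window_s[1], 6))
            contains += target in wins
            exact += wins == [target]
    out = {"any_window": any_window / n_runs}
    if bump_window_s is not None:
        out["exact_recovery"] = exact / n_runs
        out["contains_target"] = contains / n_runs
    return out


def _null_map_cohort(rng, n_mice: int, shape: tuple[int, int]):
    cond = rng.normal(size=(n_mice, *shape))
    sham = rng.normal(size=(n_mice, *shape))
    return cond, sham


def cluster_null_rejection_rate(
    n_reps: int = 200,
    n_mice: int = 7,
    map_shape: tuple[int, int] = (20, 30),
    n_perm: int = 500,
    alpha: float = 0.05,
    alpha_cluster: float = 0.1,
    seed: int = 0,
) -> float:
    """Fraction of exchangeable-null paired map sets with min cluster p <= alpha."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_reps, dtype=np.uint32)
    hits = 0
    for i in range(n_reps):
        rng = np.random.default_rng(int(child_seeds[2 * i]))
        cond, sham = _null_map_cohort(rng, n_mice, map_shape)
        res = eeg.cluster_permutation_test(
            cond, sham, n_perm=n_perm, alpha_cluster=alpha_cluster, seed=int(child_seeds[2 * i + 1])
        )
        hits += res.min_p() <= alpha
    return hits / n_reps


def cluster_effect_overlap(
    n_mice: int = 7,
    map_shape: tuple[int, int] = (20, 30),
    effect_region: tuple[slice, slice] = (slice(5, 12), slice(10, 22)),
    effect_size: float = 2.0,
    n_perm: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Overlap of the best detected cluster with an injected rectangular effect.

    Returns ``(overlap_fraction, cluster_p)`` where overlap is the share of
    the injected region covered by the minimum-p cluster.
    """
    rng = np.random.default_rng(seed)
    cond, sham = _null_map_cohort(rng, n_mice, map_shape)
    cond[:, effect_region[0], effect_region[1]] += effect_size
    res = eeg.cluster_permutation_test(cond, sham, n_perm=n_perm, seed=seed + 1)
    truth = np.zeros(map_shape, dtype=bool)
    truth[effect_region] = True
    if not res.clusters:
        return 0.0, 1.0
    best = res.clusters[0]
    overlap = float((best["mask"] & truth).sum() / truth.sum())
    return overlap, best["p"]
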