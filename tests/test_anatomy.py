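"""Normalization chain, distribution maps, permutation inference, colocalization."""

import numpy as np
import pandas as pd
import pytest

from ne_awake import anatomy, synth


def _table(counts_by_animal, groups, ap=-5.5):
    """Build a tidy table from {animal: {dv: count}} dicts (None = missing)."""
    rows = []
    for animal, counts in counts_by_animal.items():
        for dv, c in counts.items():
            if c is None:
                continue
            rows.append(
                {
                    "animal_id": animal,
                    "group": groups[animal],
                    "ap_mm": ap,
                    "dv_strip_mm": dv,
                    "count": c,
                }
            )
    return pd.DataFrame(rows)


class TestNormalizeCounts:
    def test_single_animal_gradient_is_uniform(self):
        # one animal: expected yield equals its own counts, so the chain
        # collapses to 1 at every available location
        t = _table({"a": {-3.3: 7, -3.4: 2, -3.5: 11}}, {"a": "PRN"})
        nc = anatomy.normalize_counts(t)
        assert np.allclose(nc.norm.loc["a"].dropna(), 1.0)

    def test_two_animal_hand_oracle(self):
        # counts [[2,0],[0,2]] on two strips:
        # E=(1,1); A=2 for both; N=2; denom = E*(A/N)=1 -> norm = raw counts
        t = _table(
            {"a": {-3.3: 2, -3.4: 0}, "b": {-3.3: 0, -3.4: 2}},
            {"a": "PRN", "b": "BF"},
        )
        nc = anatomy.normalize_counts(t)
        assert np.allclose(nc.expected_yield, [1.0, 1.0])
        assert nc.norm.loc["a", (-5.5, -3.3)] == pytest.approx(2.0)
        assert nc.norm.loc["a", (-5.5, -3.4)] == pytest.approx(0.0)
        assert nc.norm.loc["b", (-5.5, -3.3)] == pytest.approx(0.0)
        assert nc.norm.loc["b", (-5.5, -3.4)] == pytest.approx(2.0)
        assert np.allclose(nc.avg_dist, [0.5, 0.5])

    def test_animal_distribution_invariant_to_count_scaling(self):
        table, _ = synth.generate_cell_counts(
            {"PRN": 4, "BF": 3}, missing_slice_prob=0.3, seed=2
        )
        nc = anatomy.normalize_counts(table)
        doubled = table.copy()
        sel = doubled["animal_id"] == "PRN_0"
        doubled.loc[sel, "count"] *= 2
        nc2 = anatomy.normalize_counts(doubled)
        d1 = nc.animal_distribution("PRN_0").dropna()
        d2 = nc2.animal_distribution("PRN_0").dropna()
        assert np.allclose(d1, d2)

    def test_all_missing_animal_excluded(self):
        t = _table(
            {"a": {-3.3: 2, -3.4: 3}, "b": {-3.3: 1, -3.4: 1}},
            {"a": "PRN", "b": "BF"},
        )
        nc = anatomy.normalize_counts(t)
        assert set(nc.norm.index) == {"a", "b"}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            anatomy.normalize_counts(
                pd.DataFrame(columns=["animal_id", "group", "ap_mm", "dv_strip_mm", "count"])
            )


class TestGroupDistribution:
    def test_identical_animals_group_equals_individual(self):
        t = _table(
            {"a": {-3.3: 3, -3.4: 6}, "b": {-3.3: 3, -3.4: 6}},
            {"a": "PRN", "b": "PRN"},
        )
        nc = anatomy.normalize_counts(t)
        g = anatomy.group_distribution(nc, "PRN")
        assert np.allclose(g, nc.animal_distribution("a"))

    def test_sums_to_one(self):
        table, _ = synth.generate_cell_counts(
            {"PRN": 5, "BF": 4}, missing_slice_prob=0.2, seed=3
        )
        nc = anatomy.normalize_counts(table)
        for grp in ("PRN", "BF"):
            assert anatomy.group_distribution(nc, grp).sum() == pytest.approx(1.0)

    def test_hand_built_two_animal_value(self):
        # animals a (PRN): counts (2,0); b (PRN): (0,2) -> mean norm = (1,1)
        # map = (1,1)*avgDist = (0.5,0.5)
        t = _table(
            {"a": {-3.3: 2, -3.4: 0}, "b": {-3.3: 0, -3.4: 2}},
            {"a": "PRN", "b": "PRN"},
        )
        nc = anatomy.normalize_counts(t)
        g = anatomy.group_distribution(nc, "PRN")
        assert np.allclose(g, [0.5, 0.5])

    def test_missing_group_raises(self):
        t = _table({"a": {-3.3: 1}}, {"a": "PRN"})
        nc = anatomy.normalize_counts(t)
        with pytest.raises(ValueError, match="BF"):
            anatomy.group_distribution(nc, "BF")


class TestDiffStatistic:
    def test_identical_maps_zero(self):
        m = np.array([0.2, 0.3, 0.5])
        assert anatomy.diff_statistic(m, m) == 0.0

    def test_uniform_offset_closed_form(self):
        a = np.full(6, 0.5)
        b = np.full(6, 0.5 - 0.07)
        assert anatomy.diff_statistic(a, b) == pytest.approx(0.07)

    def test_asymmetric_weights_hand_case(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        w = np.array([3.0, 1.0])
        # weighted mean of (1,1) squared diffs with weights (3,1) -> 1 -> sqrt 1
        assert anatomy.diff_statistic(a, b, w) == pytest.approx(1.0)
        w2 = np.array([1.0, 0.0])
        assert anatomy.diff_statistic(a, b, w2) == pytest.approx(1.0)


class TestPermutationTest:
    def test_identical_animals_stat_zero_p_one(self):
        t = _table(
            {f"m{i}": {-3.3: 4, -3.4: 8} for i in range(6)},
            {f"m{i}": ("PRN" if i < 3 else "BF") for i in range(6)},
        )
        res = anatomy.permutation_test(t, n_perm=500, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_monte_carlo_close_to_exact_three_vs_two(self):
        table, _ = synth.generate_cell_counts({"PRN": 3, "BF": 2}, seed=11)
        ex = anatomy.permutation_test(table, n_perm=10, seed=0)  # exact path
        assert ex.exact and ex.n_perm == 10
        mc = anatomy.permutation_test(table, n_perm=100_000, seed=0, exact_threshold=0)
        assert not mc.exact
        assert abs(ex.p_value - mc.p_value) < 0.02

    def test_axis_statistic_sign_invariance_under_label_swap(self):
        table, _ = synth.generate_cell_counts(
            {"PRN": 4, "BF": 4},
            gradient={"PRN": {"dv_mean": -3.5}, "BF": {"dv_mean": -3.9}},
            seed=5,
        )
        res1 = anatomy.permutation_test(table, statistic="dv_location", seed=1)
        swapped = table.assign(group=table["group"].map({"PRN": "BF", "BF": "PRN"}))
        res2 = anatomy.permutation_test(swapped, statistic="dv_location", seed=1)
        assert res1.p_value == pytest.approx(res2.p_value)
        assert res1.observed == pytest.approx(-res2.observed)

    def test_dorsal_shift_detected_with_power(self):
        # strongly shifted DV gradient for one group; n = 8 vs 7 animals
        hits = 0
        n_runs = 20
        for i in range(n_runs):
            table, _ = synth.generate_cell_counts(
                {"PRN": 8, "BF": 7},
                gradient={"PRN": {"dv_mean": -3.45}, "BF": {"dv_mean": -3.95}},
                missing_slice_prob=0.2,
                seed=100 + i,
            )
            res = anatomy.permutation_test(table, statistic="dv_location", n_perm=2000, seed=i)
            hits += res.p_value <= 0.05
        assert hits / n_runs > 0.8

    def test_small_group_rejected(self):
        t = _table(
            {"a": {-3.3: 1}, "b": {-3.3: 2}, "c": {-3.3: 3}},
            {"a": "PRN", "b": "BF", "c": "BF"},
        )
        with pytest.raises(ValueError, match="two animals"):
            anatomy.permutation_test(t)


class TestColocalization:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["mouse_id", "slice_id", "n_red", "n_green", "n_coloc"])

    def test_zero_coloc_zero_ratios(self):
        df = self._counts([("m0", 0, 10, 8, 0), ("m0", 1, 5, 6, 0)])
        out = anatomy.colocalization_summary(df)
        assert (out["per_mouse"] == 0).all().all()

    def test_ratio_arithmetic(self):
        df = self._counts([("m0", 0, 10, 5, 4)])
        out = anatomy.colocalization_summary(df)
        assert out["per_mouse"].loc["m0", "bf_ratio"] == pytest.approx(0.4)
        assert out["per_mouse"].loc["m0", "prn_ratio"] == pytest.approx(0.8)

    def test_zero_denominator_slice_skipped(self):
        df = self._counts([("m0", 0, 0, 5, 0), ("m0", 1, 10, 5, 2)])
        out = anatomy.colocalization_summary(df)
        assert out["per_mouse"].loc["m0", "bf_ratio"] == pytest.approx(0.2)

    def test_invalid_coloc_count_rejected(self):
        df = self._counts([("m0", 0, 3, 5, 4)])
        with pytest.raises(ValueError, match="n_coloc"):
            anatomy.colocalization_summary(df)


class TestSubpopulationTest:
    def test_symmetric_about_one_t_zero(self):
        t, df, _ = anatomy.subpopulation_test([0.8, 1.2, 0.9, 1.1], alternative="two-sided")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 3

    def test_closed_form_oracle(self):
        r = np.array([0.4, 0.5, 0.3, 0.45, 0.35])
        t, df, p = anatomy.subpopulation_test(r)
        manual = (r.mean() - 1.0) / (r.std(ddof=1) / np.sqrt(r.size))
        assert t == pytest.approx(manual, rel=1e-12)
        assert df == 4
        assert p < 0.001  # ratios far below full overlap

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            anatomy.subpopulation_test([0.5, 0.5, 0.5])


class TestCalibrationProperties:
    def test_null_rejection_rate_near_nominal_small(self):
        from ne_awake import calibration

        rate = calibration.anatomy_null_rejection_rate(n_cohorts=60, n_perm=1000, seed=9)
        # 95% binomial band around 0.05 at n=60
        assert 0.0 <= rate <= 0.13

    def test_yield_scale_variation_leaves_distributions_unchanged(self):
        base, _ = synth.generate_cell_counts({"PRN": 3, "BF": 3}, yield_scale=1.0, seed=6)
        nc = anatomy.normalize_counts(base)
        scaled = base.copy()
        factors = {a: f for a, f in zip(scaled["animal_id"].unique(), [1, 2, 5, 10, 3, 7])}
        scaled["count"] = [
            int(c * factors[a]) for c, a in zip(scaled["count"], scaled["animal_id"])
        ]
        nc2 = anatomy.normalize_counts(scaled)
        for a in nc.norm.index:
            assert np.allclose(
                nc.animal_distribution(a).dropna(), nc2.animal_distribution(a).dropna()
            )
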