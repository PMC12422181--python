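"""ΔF/F preprocessing, epoching, window detection and quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ne_awake import photometry, synth
from ne_awake.photometry import IsosbesticFit
from ne_awake.types import DffTrace, EpochMatrix, PhotometrySession, ResponseWindow


def _epochs(data, t, baseline=(-5.0, 0.0)):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return EpochMatrix(
        data=data,
        t=np.asarray(t, dtype=float),
        fs=1.0 / (t[1] - t[0]),
        baseline_window_s=baseline,
        trial_ids=np.arange(data.shape[0]),
    )


class TestIsosbesticFit:
    def test_identity_channels(self):
        x = 50.0 + np.sin(np.linspace(0, 20, 1000))
        s = PhotometrySession(signal=x, isosbestic=x, fs=100.0)
        fit = photometry.fit_isosbestic(s)
        a, b = fit.coefficients[0]
        assert a == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(fit.fitted, x)

    def test_closed_form_linear_recovery(self, linear_session):
        fit = photometry.fit_isosbestic(linear_session)
        a, b = fit.coefficients[0]
        assert a == pytest.approx(2.0, abs=1e-10)
        assert b == pytest.approx(1.0, abs=1e-7)

    def test_per_block_differs_from_global_under_blockwise_drift(self):
        # two LED blocks with different signal/iso relations
        iso = np.concatenate([70 + np.sin(np.linspace(0, 10, 500)), 60 + np.sin(np.linspace(0, 10, 500))])
        sig = np.concatenate([2 * iso[:500] + 1, 3 * iso[500:] - 5])
        s = PhotometrySession(
            signal=sig, isosbestic=iso, fs=100.0, led_epochs=[(0.0, 4.5), (5.5, 9.99)]
        )
        per_block = photometry.fit_isosbestic(s, per_block=True)
        global_fit = photometry.fit_isosbestic(s, per_block=False)
        assert len(per_block.coefficients) == 2
        assert per_block.coefficients[0][0] == pytest.approx(2.0, abs=1e-8)
        assert per_block.coefficients[1][0] == pytest.approx(3.0, abs=1e-8)
        v = s.valid_mask()
        assert not np.allclose(per_block.fitted[v], global_fit.fitted[v])

    def test_constant_isosbestic_degenerate(self):
        s = PhotometrySession(signal=np.arange(100.0), isosbestic=np.ones(100), fs=10.0)
        with pytest.raises(ValueError, match="degenerate"):
            photometry.fit_isosbestic(s)


class TestComputeDff:
    def test_printed_formula_arithmetic(self):
        s = PhotometrySession(signal=np.full(10, 110.0), isosbestic=np.arange(10.0) + 1, fs=10.0)
        fit = IsosbesticFit(fitted=np.full(10, 100.0), coefficients=[(0.0, 100.0)], per_block=False)
        dff = photometry.compute_dff(s, fit)
        assert np.allclose(dff.values, 10.0)

    def test_signal_equals_fit_gives_zero(self, linear_session):
        fit = photometry.fit_isosbestic(linear_session)
        dff = photometry.compute_dff(linear_session, fit)
        assert np.allclose(dff.values, 0.0, atol=1e-8)

    def test_bleaching_only_residual_below_noise_floor(self, clean_session):
        _, _, session, _ = clean_session
        dff = photometry.compute_dff(session, photometry.fit_isosbestic(session))
        assert np.nanmax(np.abs(dff.values)) < 1e-6

    def test_nonpositive_reference_names_range(self):
        s = PhotometrySession(signal=np.ones(10), isosbestic=np.arange(10.0), fs=1.0)
        fit = IsosbesticFit(
            fitted=np.array([1.0] * 5 + [-1.0] * 5), coefficients=[(1.0, 0.0)], per_block=False
        )
        with pytest.raises(ValueError, match="5..9"):
            photometry.compute_dff(s, fit)

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_to_common_positive_scaling(self, scale):
        rng = np.random.default_rng(0)
        iso = 70 + rng.normal(size=500).cumsum() * 0.01 + np.linspace(0, -2, 500)
        sig = 1.5 * iso + 3 + 0.1 * rng.normal(size=500)
        s1 = PhotometrySession(signal=sig, isosbestic=iso, fs=100.0)
        s2 = PhotometrySession(signal=scale * sig, isosbestic=scale * iso, fs=100.0)
        d1 = photometry.compute_dff(s1, photometry.fit_isosbestic(s1))
        d2 = photometry.compute_dff(s2, photometry.fit_isosbestic(s2))
        assert np.allclose(d1.values, d2.values, atol=1e-8)


class TestEpochTrials:
    def _dff(self, values, fs=100.0):
        values = np.asarray(values, dtype=float)
        return DffTrace(values=values, fs=fs, valid_mask=np.isfinite(values))

    def test_constant_trace_all_zero_epochs(self):
        dff = self._dff(np.full(10000, 3.0))
        ep = photometry.epoch_trials(dff, [40.0, 60.0])
        assert np.allclose(ep.data, 0.0)

    def test_step_at_onset_preserved(self):
        v = np.zeros(10000)
        onset = 50.0
        v[int(onset * 100):] = 5.0
        ep = photometry.epoch_trials(self._dff(v), [onset])
        post = ep.t > 0.05
        assert ep.data[0, post].mean() == pytest.approx(5.0, abs=1e-9)
        assert abs(ep.data[0, ep.t < -0.05].mean()) < 1e-9

    def test_edge_trial_dropped_others_kept(self):
        dff = self._dff(np.zeros(10000))
        ep = photometry.epoch_trials(dff, [2.0, 50.0])  # first window leaves trace
        assert ep.n_dropped == 1
        assert ep.n_trials == 1
        assert ep.trial_ids[0] == 1

    def test_all_dropped_raises(self):
        dff = self._dff(np.zeros(100))
        with pytest.raises(ValueError, match="dropped"):
            photometry.epoch_trials(dff, [0.1])

    def test_baseline_mean_zero_invariant(self):
        rng = np.random.default_rng(3)
        dff = self._dff(rng.normal(size=20000))
        ep = photometry.epoch_trials(dff, [30.0, 80.0, 120.0])
        base = (ep.t >= -5.0) & (ep.t < 0.0)
        assert np.abs(ep.data[:, base].mean(axis=1)).max() < 1e-9


class TestDetectResponseWindows:
    def test_separated_bins_never_merged(self):
        # construct per-mouse epochs with strong bumps in bins 2 and 5 only
        fs = 101.725
        t = np.arange(-5 * fs, 4 * fs) / fs
        rng = np.random.default_rng(0)
        cohort = []
        for m in range(7):
            data = rng.normal(0, 0.05, size=(20, t.size))
            for b in (2, 5):
                sel = (t >= 0.3 * b) & (t < 0.3 * (b + 1))
                data[:, sel] += 2.0
            cohort.append(_epochs(data, t))
        res = photometry.detect_response_windows(cohort, seed=0)
        starts_ends = [(round(w.start_s, 4), round(w.end_s, 4)) for w in res.windows]
        assert (0.6, 0.9) in starts_ends
        assert (1.5, 1.8) in starts_ends
        assert len(res.windows) == 2

    def test_omnibus_gate_blocks_windows(self):
        cohort = synth.generate_epoch_cohort(n_mice=5, n_trials=10, seed=100)
        res = photometry.detect_response_windows(cohort, seed=0)
        if res.kw_p >= 0.05:
            assert res.windows == []
            assert np.isnan(res.corrected_p).all()

    def test_corrected_decisions_subset_of_uncorrected(self):
        from scipy import stats

        cohort = synth.generate_epoch_cohort(
            bump_window_s=(0.3, 0.9), bump_amp=0.6, seed=12
        )
        res = photometry.detect_response_windows(cohort, seed=0)
        M = res.bin_means
        n = M.shape[0]
        t = M.mean(0) / (M.std(0, ddof=1) / np.sqrt(n))
        p_unc = stats.t.sf(t, n - 1)
        sig_corr = res.corrected_p <= 0.05
        sig_unc = p_unc <= 0.05
        assert not (sig_corr & ~sig_unc).any()
        assert (res.corrected_p >= p_unc - 1e-12).all()

    def test_requires_two_mice(self):
        cohort = synth.generate_epoch_cohort(n_mice=1, seed=0)
        with pytest.raises(ValueError, match="two mice"):
            photometry.detect_response_windows(cohort)


class TestScoreElements:
    def test_flat_epoch_scores_zero(self):
        t = np.arange(-5, 4, 0.01)
        ep = _epochs(np.zeros((3, t.size)), t)
        w = ResponseWindow("r", 0.3, 0.6)
        s = photometry.score_elements(ep, w)
        assert (s["score"] == 0).all() and (s["drop"] == 0).all()

    def test_window_indicator_scores_amplitude(self):
        t = np.arange(-5, 4, 0.01)
        data = np.zeros((2, t.size))
        data[:, (t >= 0.3) & (t < 0.6)] = 4.0
        s = photometry.score_elements(_epochs(data, t), ResponseWindow("r", 0.3, 0.6))
        assert np.allclose(s["score"], 4.0)

    def test_hand_built_matrix_matches_manual(self):
        t = np.array([-0.5, 0.05, 0.15, 0.25, 0.35, 0.45])
        data = np.array(
            [
                [0.0, 1.0, 3.0, -1.0, -2.0, 0.0],
                [0.0, 2.0, 2.0, 0.0, -4.0, 1.0],
                [0.0, 0.0, 6.0, 2.0, 0.0, -1.0],
            ]
        )
        ep = _epochs(data, t, baseline=(-1.0, 0.0))
        w = ResponseWindow("r", 0.0, 0.3)
        s = photometry.score_elements(ep, w, drop_span_s=0.2)
        # manual: mean of samples at t in [0, 0.3); min of samples in (0.3, 0.5]
        assert np.allclose(s["score"], [1.0, 4 / 3, 8 / 3])
        assert np.allclose(s["drop"], [-2.0, -4.0, -1.0])


class TestOutcomeComparisons:
    def test_identical_outcome_means_t_zero(self):
        rows = []
        for m in range(5):
            for o in ("awakening", "maintained"):
                rows.append({"mouse": f"m{m}", "outcome": o, "score": float(m)})
        res = photometry.compare_outcomes(pd.DataFrame(rows))
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_closed_form_paired_t(self, scored_trials):
        res = photometry.compare_outcomes(scored_trials)
        m = res.per_mouse_means
        d = (m["awakening"] - m["maintained"]).to_numpy()
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.t == pytest.approx(t_manual, rel=1e-12)
        assert res.df == d.size - 1

    def test_too_few_mice_raises(self):
        df = pd.DataFrame(
            {"mouse": ["a", "a"], "outcome": ["awakening", "maintained"], "score": [1.0, 0.0]}
        )
        with pytest.raises(ValueError, match="two mice"):
            photometry.compare_outcomes(df)


class TestCorrelations:
    def test_covariate_equals_score_gives_r_one(self, scored_trials):
        df = scored_trials.assign(cov=scored_trials["score"])
        r = photometry.per_mouse_correlations(df, "score", "cov")
        assert np.allclose(r, 1.0)

    def test_negated_covariate_gives_negative_r(self, scored_trials):
        rng = np.random.default_rng(1)
        df = scored_trials.assign(
            cov=-scored_trials["score"] + 0.05 * rng.normal(size=len(scored_trials))
        )
        r = photometry.per_mouse_correlations(df, "score", "cov")
        assert (r < 0).all()

    def test_independent_covariate_mean_r_near_zero(self):
        rng = np.random.default_rng(2)
        rows = []
        for m in range(50):
            for i in range(30):
                rows.append({"mouse": m, "score": rng.normal(), "cov": rng.normal()})
        r = photometry.per_mouse_correlations(pd.DataFrame(rows), "score", "cov")
        se = r.std(ddof=1) / np.sqrt(len(r))
        assert abs(r.mean()) < 3 * se + 1e-6

    def test_zero_variance_mouse_excluded(self, scored_trials):
        df = scored_trials.assign(cov=1.0)
        r = photometry.per_mouse_correlations(df, "score", "cov")
        assert len(r) == 0

    def test_group_tests_structure(self, scored_trials):
        df = scored_trials.assign(cov=scored_trials["score"] * 0.5)
        r = photometry.per_mouse_correlations(df, "score", "cov")
        out = photometry.correlate_with_physiology({"surge": r, "rise": -r})
        assert "anova" in out and out["per_element"]["surge"]["mean_r"] > 0.99


class TestPeakDrop:
    def test_exact_anticorrelation(self, scored_trials):
        df = scored_trials.assign(drop=-scored_trials["score"])
        r, _ = photometry.peak_drop_correlation(df)
        assert r == pytest.approx(-1.0)

    def test_exact_correlation(self, scored_trials):
        df = scored_trials.assign(drop=scored_trials["score"])
        r, _ = photometry.peak_drop_correlation(df)
        assert r == pytest.approx(1.0)

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            df = pd.DataFrame({"score": rng.normal(size=30), "drop": rng.normal(size=30)})
            _, p = photometry.peak_drop_correlation(df)
            ps.append(p)
        # mean of uniform p is 0.5 with sd 1/sqrt(12 n)
        assert abs(np.mean(ps) - 0.5) < 4 / np.sqrt(12 * 200)

    def test_degenerate_variance_raises(self):
        df = pd.DataFrame({"score": [1.0, 1.0, 1.0], "drop": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="variance"):
            photometry.peak_drop_correlation(df)


class TestOutcomeModel:
    def test_dominant_feature_identified(self):
        rng = np.random.default_rng(4)
        n = 400
        X = pd.DataFrame({"bf_rise": rng.normal(size=n), "prn_surge": rng.normal(size=n)})
        y = np.where(X["prn_surge"] + 0.3 * rng.normal(size=n) > 0, "awakening", "maintained")
        res = photometry.fit_outcome_model(X, y)
        coefs = res.params.abs()
        # row order: const, bf_rise, prn_surge
        assert coefs.iloc[2, 0] > 3 * coefs.iloc[1, 0]
        assert res.p_lrt < 1e-6

    def test_constant_features_chi2_zero(self):
        X = pd.DataFrame({"a": np.ones(60)})
        y = np.array(["x", "y"] * 30)
        res = photometry.fit_outcome_model(X, y)
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_null_lrt_calibration(self):
        rng = np.random.default_rng(5)
        chi2s, ps = [], []
        for _ in range(100):
            X = pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)})
            y = rng.choice(["x", "y"], size=80)
            res = photometry.fit_outcome_model(X, y)
            chi2s.append(res.chi2)
            ps.append(res.p_lrt)
        # under the null chi2 has mean df=2; p approximately uniform
        assert np.mean(chi2s) == pytest.approx(2.0, abs=0.6)
        assert abs(np.mean(ps) - 0.5) < 0.12

    def test_separation_flagged(self):
        X = pd.DataFrame({"a": np.r_[np.zeros(20), np.ones(20)]})
        y = np.array(["x"] * 20 + ["y"] * 20)
        res = photometry.fit_outcome_model(X, y)
        assert res.separation

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two outcome classes"):
            photometry.fit_outcome_model(pd.DataFrame({"a": [1.0, 2.0]}), np.array(["x", "x"]))


class TestCrossCorrelate:
    def test_self_correlation_peaks_at_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=2000)
        _, _, lag, val = photometry.cross_correlate(x, x, fs=100.0, max_lag_s=2.0)
        assert lag == 0.0
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_delayed_copy_peaks_at_positive_lag(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=4000)
        shift = 50  # 0.5 s at 100 Hz
        b = np.r_[np.zeros(shift), x[:-shift]]
        _, _, lag, val = photometry.cross_correlate(x, b, fs=100.0, max_lag_s=2.0)
        assert lag == pytest.approx(0.5, abs=1e-9)
        assert val > 0.9

    def test_white_noise_below_multiplicity_corrected_threshold(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        n, fs = 5000, 100.0
        a, b = rng.normal(size=n), rng.normal(size=n)
        lags, cc, _, _ = photometry.cross_correlate(a, b, fs=fs, max_lag_s=1.0)
        thresh = stats.norm.ppf(1 - 0.005 / lags.size) / np.sqrt(n)
        assert np.abs(cc).max() < thresh

    def test_short_trace_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            photometry.cross_correlate(np.ones(10), np.ones(10), fs=10.0, max_lag_s=2.0)
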