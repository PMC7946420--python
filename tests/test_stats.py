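import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from spikeramp.processing import AnalysisWindows, align_spikes, bin_rates, truncate_at_stop
from spikeramp.stats import (
    BootstrapConfig,
    InsufficientDataError,
    SeparationError,
    TimeSlopeResult,
    bootstrap_mode_comparison,
    classify_neuron,
    compare_two_slopes,
    fit_choice_logistic,
    fit_time_slope,
    fit_value_regression_cue,
    fit_value_regression_stop,
    gaze_rate_correlation,
    mode_period_rates,
    population_correlations,
)
from spikeramp.synth import NeuronGroundTruth, simulate_choice_sessions, simulate_population
from spikeramp.task import VALUE_DECREASE, VALUE_FIXED, VALUE_INCREASE, TaskConfig


CENTERS = AnalysisWindows().tonic_bin_centers


class TestFitTimeSlope:
    def test_exact_line(self):
        rates = np.arange(3.0, 12.0)  # 3..11 over nine bins, +1 per 0.2 s
        fit = fit_time_slope(rates, CENTERS)
        assert fit.slope == pytest.approx(5.0, abs=1e-9)
        assert fit.p_value < 1e-50

    def test_constant_rates(self):
        fit = fit_time_slope(np.full(9, 4.0), CENTERS)
        assert fit.slope == 0.0
        assert fit.p_value == 1.0

    def test_matches_scipy_linregress(self, rng):
        for _ in range(50):
            y = rng.normal(5, 1, size=9)
            fit = fit_time_slope(y, CENTERS)
            ref = sps.linregress(CENTERS / 1000.0, y)
            assert fit.slope == pytest.approx(ref.slope, rel=1e-10)
            assert fit.slope_se == pytest.approx(ref.stderr, rel=1e-10)
            assert fit.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_weighted_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            y = rng.normal(5, 1, size=9)
            w = rng.uniform(1, 10, size=9)
            fit = fit_time_slope(y, CENTERS, weights=w)
            X = sm.add_constant(CENTERS / 1000.0)
            res = sm.WLS(y, X, weights=w).fit()
            assert fit.slope == pytest.approx(res.params[1], rel=1e-10)
            assert fit.slope_se == pytest.approx(res.bse[1], rel=1e-8)
            assert fit.p_value == pytest.approx(res.pvalues[1], rel=1e-8)

    def test_nan_bins_dropped(self):
        rates = np.array([3, 4, 5, 6, np.nan, np.nan, np.nan, np.nan, np.nan])
        fit = fit_time_slope(rates, CENTERS)
        assert fit.n_bins == 4
        assert fit.slope == pytest.approx(5.0)

    def test_too_few_bins(self):
        rates = np.array([3, 4] + [np.nan] * 7)
        with pytest.raises(InsufficientDataError):
            fit_time_slope(rates, CENTERS)


class TestCompareTwoSlopes:
    def _fit(self, slope, se):
        return TimeSlopeResult(slope, 0.0, se, 0.5, 9)

    def test_identical_fits(self):
        z, p = compare_two_slopes(self._fit(1.0, 0.2), self._fit(1.0, 0.2))
        assert z == 0.0
        assert p == 1.0

    def test_separated_slopes(self):
        z, p = compare_two_slopes(self._fit(5.0, 0.01), self._fit(-5.0, 0.01))
        assert p < 1e-6

    def test_zero_se_error(self):
        with pytest.raises(ValueError):
            compare_two_slopes(self._fit(1.0, 0.0), self._fit(2.0, 0.0))

    def test_null_calibration_same_generator(self, config, windows):
        gen = np.random.default_rng(0)
        neuron = NeuronGroundTruth(0, baseline_rate=4.0, tonic_gain_increase=12.0)
        rej = 0
        n_pairs = 60
        for _ in range(n_pairs):
            fits = []
            for _ in range(2):
                sess = simulate_population(
                    config, {}, gen, n_blocks=1, block_order=[VALUE_INCREASE], neurons=[neuron]
                )
                al = truncate_at_stop(align_spikes(sess, 0, "cs_onset", conditions=[VALUE_INCREASE]))
                b = bin_rates(al, windows)
                fits.append(fit_time_slope(b.rates, b.centers_ms, weights=b.n_trials))
            _, p = compare_two_slopes(*fits)
            rej += p < 0.05
        # nominal 5 %; allow generous binomial slack at n = 60
        assert rej / n_pairs < 0.17


class TestValueRegressions:
    def test_cue_exact_line(self, config, windows, monkeypatch):
        # craft rates 5/10/15 at levels 1/2/3 via a deterministic session stub
        gen = np.random.default_rng(1)
        sess = simulate_population(
            config, {}, gen, n_blocks=1, block_order=[VALUE_FIXED],
            neurons=[NeuronGroundTruth(0, baseline_rate=3.0)],
        )
        trials = sess.trials
        rows = []
        rates = {"fixed_small": 10, "fixed_medium": 20, "fixed_large": 30}
        for row in trials.itertuples(index=False):
            n = rates.get(row.cs_type, 0)
            lo = row.cs_onset_ms + windows.cue_response[0]
            for k in range(int(n * 0.3)):  # n spk/s over the 300 ms window
                rows.append({"session_id": "s", "neuron_id": 0, "trial_id": row.trial_id,
                             "spike_time_ms": lo + k * 280.0 / max(n * 0.3, 1)})
        sess.spikes = pd.DataFrame(rows)
        fit = fit_value_regression_cue(sess, 0, windows)
        assert fit.coefficient == pytest.approx(10.0)
        assert fit.value_coding == "level_0p1ml"

    def test_cue_missing_level_error(self, config, windows, rng):
        sess = simulate_population(
            config, {}, rng, n_blocks=1, block_order=[VALUE_FIXED],
            neurons=[NeuronGroundTruth(0, baseline_rate=3.0)],
        )
        sess.trials = sess.trials[sess.trials.cs_type != "fixed_large"]
        with pytest.raises(InsufficientDataError, match="fixed_large"):
            fit_value_regression_cue(sess, 0, windows)

    def test_cue_null_neuron_calibration(self, config, windows):
        gen = np.random.default_rng(2)
        neuron = NeuronGroundTruth(0, baseline_rate=4.0)
        rej = 0
        n_rep = 100
        for _ in range(n_rep):
            sess = simulate_population(
                config, {}, gen, n_blocks=1, block_order=[VALUE_FIXED], neurons=[neuron]
            )
            fit = fit_value_regression_cue(sess, 0, windows)
            rej += fit.p_value < 0.05
        assert 0.0 <= rej / n_rep <= 0.12

    def test_stop_three_point_closed_form(self, config, windows):
        # closed-form OLS on the three group means, hand-computed
        gen = np.random.default_rng(3)
        sess = simulate_population(
            config, {}, gen, n_blocks=1, block_order=[VALUE_DECREASE],
            neurons=[NeuronGroundTruth(0, baseline_rate=4.0)],
        )
        fit = fit_value_regression_stop(sess, 0, windows, VALUE_DECREASE)
        aligned = align_spikes(sess, 0, "stop_onset", conditions=[VALUE_DECREASE])
        from spikeramp.processing import window_rate_per_trial

        rates = window_rate_per_trial(aligned, windows.stop_response)
        rewards = aligned.trials["reward_ml"].to_numpy()
        groups = windows.value_group_of(rewards)
        y = np.array([rates[groups == g].mean() for g in range(3)])
        x = np.array([rewards[groups == g].mean() for g in range(3)]) / 0.1
        slope_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.coefficient == pytest.approx(slope_hand, rel=1e-12)

    def test_stop_identical_means_zero(self, windows):
        from spikeramp.stats import _ols

        coef, _, _, _ = _ols(np.array([1.3, 1.95, 2.65]), np.array([4.0, 4.0, 4.0]))
        assert coef == 0.0

    def test_stop_empty_group_error(self, config, windows, rng):
        sess = simulate_population(
            config, {}, rng, n_blocks=1, block_order=[VALUE_DECREASE],
            neurons=[NeuronGroundTruth(0, baseline_rate=3.0)],
        )
        sess.trials = sess.trials[sess.trials.reward_ml >= 0.16]
        with pytest.raises(InsufficientDataError, match="occupancies"):
            fit_value_regression_stop(sess, 0, windows, VALUE_DECREASE)

    def test_stop_directional_recovery(self, config, windows):
        gen = np.random.default_rng(4)
        pos = 0
        n_rep = 40
        for _ in range(n_rep):
            sess = simulate_population(
                config, {}, gen, n_blocks=2, block_order=[VALUE_DECREASE],
                neurons=[NeuronGroundTruth(0, baseline_rate=4.0, stop_phasic_gain=4.0)],
            )
            fit = fit_value_regression_stop(sess, 0, windows, VALUE_DECREASE)
            pos += fit.coefficient > 0
        assert pos / n_rep > 0.9


class TestGazeRateCorrelation:
    def _session(self, config, gen, couple=False):
        sess = simulate_population(
            config, {}, gen, n_blocks=2, block_order=[VALUE_INCREASE],
            neurons=[NeuronGroundTruth(0, baseline_rate=4.0)], with_gaze=True,
        )
        if couple:
            # rebuild spikes as an affine function of mean gaze per bin
            w = AnalysisWindows()
            rows = []
            for row in sess.trials.itertuples(index=False):
                g = sess.gaze[sess.gaze.trial_id == row.trial_id]
                rel = g["sample_time_ms"].to_numpy() - row.cs_onset_ms
                for k in range(w.n_tonic_bins):
                    lo, hi = w.tonic_bin_edges[k], w.tonic_bin_edges[k + 1]
                    m = (rel >= lo) & (rel < hi)
                    if not m.any():
                        continue
                    n_spk = max(int(round(2.0 * g["y_deg"].to_numpy()[m].mean() + 10.0)), 0)
                    for j in range(n_spk):
                        rows.append(
                            {"session_id": "s", "neuron_id": 0, "trial_id": row.trial_id,
                             "spike_time_ms": row.cs_onset_ms + lo + j * (hi - lo) / max(n_spk, 1)}
                        )
            sess.spikes = pd.DataFrame(rows)
        return sess

    def test_independent_gaze_near_zero(self, config, windows):
        gen = np.random.default_rng(5)
        sess = self._session(config, gen)
        df = gaze_rate_correlation(sess, 0, windows, VALUE_INCREASE)
        ok = df.dropna(subset=["r"])
        assert len(ok) >= 3
        assert (ok["r"].abs() < 0.6).all()

    def test_affine_dependence_r_near_one(self, config, windows):
        gen = np.random.default_rng(6)
        sess = self._session(config, gen, couple=True)
        df = gaze_rate_correlation(sess, 0, windows, VALUE_INCREASE)
        first = df.dropna(subset=["r"]).iloc[0]
        assert first["r"] > 0.9

    def test_constant_gaze_flagged(self, config, windows):
        gen = np.random.default_rng(7)
        sess = self._session(config, gen)
        sess.gaze["y_deg"] = 0.0
        df = gaze_rate_correlation(sess, 0, windows, VALUE_INCREASE)
        assert df["r"].isna().all()

    def test_missing_gaze_rejected(self, small_session, windows):
        with pytest.raises(ValueError, match="gaze"):
            gaze_rate_correlation(small_session, 0, windows, VALUE_INCREASE)


class TestBootstrap:
    def test_all_tie_never_significant(self, rng):
        rates = np.tile(np.array([[1.0, 2.0, 3.0]]), (10, 1))
        res = bootstrap_mode_comparison(rates, rates.copy(), BootstrapConfig(), rng)
        for r in res:
            assert not r.significant
            assert r.count_tie == 1000

    def test_deterministic_dominance(self, rng):
        nb = np.full((8, 3), 2.0)
        b = np.full((8, 3), 1.0)
        res = bootstrap_mode_comparison(nb, b, BootstrapConfig(), rng)
        for r in res:
            assert r.significant and r.direction == "non_burst"
            assert r.count_non_burst_greater == 1000

    def test_counts_sum_to_repetitions(self, rng):
        nb = rng.normal(0, 1, (12, 3))
        b = rng.normal(0, 1, (12, 3))
        for r in bootstrap_mode_comparison(nb, b, BootstrapConfig(), rng):
            assert r.count_non_burst_greater + r.count_burst_greater + r.count_tie == 1000

    def test_seed_determinism(self):
        nb = np.random.default_rng(0).normal(0, 1, (12, 3))
        b = np.random.default_rng(1).normal(0, 1, (12, 3))
        r1 = bootstrap_mode_comparison(nb, b, BootstrapConfig(), np.random.default_rng(5))
        r2 = bootstrap_mode_comparison(nb, b, BootstrapConfig(), np.random.default_rng(5))
        assert [x.count_non_burst_greater for x in r1] == [x.count_non_burst_greater for x in r2]

    def test_zero_neurons_error(self, rng):
        with pytest.raises(ValueError):
            bootstrap_mode_comparison(np.empty((0, 3)), np.empty((0, 3)), BootstrapConfig(), rng)

    def test_nan_neurons_excluded(self, rng):
        nb = np.full((5, 3), 2.0)
        b = np.full((5, 3), 1.0)
        nb[0, 2] = np.nan
        res = bootstrap_mode_comparison(nb, b, BootstrapConfig(), rng)
        assert res[0].count_non_burst_greater == 1000  # still runs on 4 neurons

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            BootstrapConfig(n_repetitions=100, significance_count=200)


class TestChoiceLogistic:
    def test_recovery(self, config):
        gen = np.random.default_rng(8)
        df = simulate_choice_sessions(config, 0.0, 10.0, 5000, gen)
        m = fit_choice_logistic(df)
        assert m.beta1 == pytest.approx(10.0, abs=4 * m.se1)
        assert m.n_trials == 5000

    def test_matches_statsmodels(self, config):
        import statsmodels.api as sm

        gen = np.random.default_rng(9)
        df = simulate_choice_sessions(config, 0.5, 8.0, 2000, gen)
        m = fit_choice_logistic(df)
        X = sm.add_constant((df.v_right_ml - df.v_left_ml).to_numpy())
        ref = sm.Logit(df.chose_right.to_numpy(), X).fit(disp=0)
        assert m.beta0 == pytest.approx(ref.params[0], abs=1e-5)
        assert m.beta1 == pytest.approx(ref.params[1], rel=1e-4)
        assert m.se1 == pytest.approx(ref.bse[1], rel=1e-3)

    def test_null_within_two_se(self, config):
        gen = np.random.default_rng(10)
        inside = 0
        for _ in range(50):
            df = simulate_choice_sessions(config, 0.0, 0.0, 2000, gen)
            m = fit_choice_logistic(df)
            inside += abs(m.beta1) < 2 * m.se1
        assert inside >= 42

    def test_single_outcome_rejected(self, config):
        df = pd.DataFrame({"v_right_ml": [0.2, 0.3], "v_left_ml": [0.1, 0.1], "chose_right": [1, 1]})
        with pytest.raises(SeparationError):
            fit_choice_logistic(df)

    def test_separation_detected_and_penalized_fallback(self, config):
        gen = np.random.default_rng(11)
        df = simulate_choice_sessions(config, 0.0, 1e6, 400, gen)
        with pytest.raises(SeparationError):
            fit_choice_logistic(df)
        m = fit_choice_logistic(df, penalized=True)
        assert np.isfinite(m.beta1)


class TestClassifyNeuron:
    def test_strong_tonic_increaser_flagged(self, config, windows):
        gen = np.random.default_rng(12)
        flagged = 0
        n_rep = 20
        for _ in range(n_rep):
            sess = simulate_population(
                config, {}, gen, n_blocks=3, block_order=[VALUE_INCREASE],
                neurons=[NeuronGroundTruth(0, baseline_rate=4.0, tonic_gain_increase=20.0)],
            )
            s = classify_neuron(sess, 0, windows)
            flagged += s.tonic_increaser
        assert flagged / n_rep > 0.9

    def test_flags_match_invariants(self, small_session, windows):
        s = classify_neuron(small_session, 0, windows)
        if s.slope_increase is not None:
            assert s.tonic_increaser == (
                s.slope_increase.slope > 0 and s.slope_increase.p_value < 0.05
            )
        if s.cue_regression is not None:
            assert s.cue_value_coder == (s.cue_regression.p_value < 0.05)
        row = s.to_row()
        assert row["neuron_id"] == 0
        assert "slope_increase_p" in row

    def test_null_neuron_usually_unflagged(self, config, windows):
        gen = np.random.default_rng(13)
        flags = 0
        n_rep = 30
        for _ in range(n_rep):
            sess = simulate_population(
                config, {}, gen, n_blocks=1,
                neurons=[NeuronGroundTruth(0, baseline_rate=4.0)],
            )
            s = classify_neuron(sess, 0, windows)
            flags += s.tonic_increaser
        assert flags / n_rep <= 0.2  # one-sided 2.5 % nominal

    def test_mode_period_rates_shapes(self, small_session, windows):
        nb, b = mode_period_rates(small_session, 0, windows)
        assert nb.shape == (3,)
        assert b.shape == (3,)

    def test_population_correlations_frame(self, config, windows):
        gen = np.random.default_rng(14)
        sess = simulate_population(config, {"null": 4}, gen, n_blocks=1)
        from spikeramp.stats import analyze_population

        summary = analyze_population(sess, windows)
        corr = population_correlations(summary)
        assert set(corr.columns) == {"x", "y", "r", "p_value", "n"}
        assert len(corr) == 6
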