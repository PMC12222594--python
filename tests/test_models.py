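"""Ridge TRF and stimulus-reconstruction models."""

import numpy as np
import pytest

from speechtrack.models import (
    LagGrid,
    StimulusDecoder,
    TemporalResponseFunction,
    build_lagged_design,
    default_lambda_grid,
    loo_reconstruction,
    pearson_r,
    ridge_solve,
)

FS = 256.0


class TestLagGrid:
    def test_forward_default_span(self):
        grid = LagGrid(-250.0, 700.0, FS)
        assert grid.lags[0] == round(-0.25 * FS)
        assert grid.lags[-1] == round(0.70 * FS)
        assert np.all(np.diff(grid.lags) == 1)

    def test_lambda_grid_is_20_logspaced(self):
        lams = default_lambda_grid()
        assert lams.size == 20
        assert lams[0] == pytest.approx(1e-6)
        assert lams[-1] == pytest.approx(1e6)
        np.testing.assert_allclose(np.diff(np.log10(lams)), np.diff(np.log10(lams))[0])


class TestLaggedDesign:
    def test_single_zero_lag_equals_source(self, rng):
        s = rng.standard_normal(50)
        design = build_lagged_design(s, LagGrid(0.0, 0.0, 1000.0), "forward")
        np.testing.assert_array_equal(design[:, 0], s)

    def test_impulse_source_gives_identity_pattern(self):
        s = np.zeros(8)
        s[0] = 1.0
        grid = LagGrid(0.0, 3.0, 1000.0)  # lags 0..3 samples
        design = build_lagged_design(s, grid, "forward")
        np.testing.assert_array_equal(design[:4, :], np.eye(4))
        assert np.all(design[4:] == 0)

    def test_forward_prediction_matches_double_sum_oracle(self, rng):
        s = rng.standard_normal(120)
        grid = LagGrid(-20.0, 60.0, 500.0)
        h = rng.standard_normal((grid.n_lags, 3))
        predicted = build_lagged_design(s, grid, "forward") @ h
        oracle = np.zeros_like(predicted)
        for t in range(s.size):
            for j, tau in enumerate(grid.lags):
                if 0 <= t - tau < s.size:
                    oracle[t] += s[t - tau] * h[j]
        np.testing.assert_allclose(predicted, oracle, atol=1e-10)

    def test_backward_design_shifts_in_opposite_direction(self, rng):
        r = rng.standard_normal((2, 40))
        grid = LagGrid(0.0, 10.0, 1000.0)
        design = build_lagged_design(r, grid, "backward")
        assert design.shape == (40, 2 * grid.n_lags)
        for n in range(2):
            for j, tau in enumerate(grid.lags):
                col = design[:, n * grid.n_lags + j]
                for t in range(40):
                    expected = r[n, t + tau] if t + tau < 40 else 0.0
                    assert col[t] == expected

    def test_source_shorter_than_lags_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_lagged_design(np.zeros(3), LagGrid(0.0, 10.0, 1000.0), "forward")


class TestRidgeSolve:
    def test_zero_lambda_equals_ols(self, rng):
        design = rng.standard_normal((60, 5))
        target = rng.standard_normal(60)
        w = ridge_solve(design, target, 0.0)
        w_ols = np.linalg.lstsq(design, target, rcond=None)[0]
        np.testing.assert_allclose(w, w_ols, atol=1e-8)

    def test_huge_lambda_shrinks_weights_to_zero(self, rng):
        design = rng.standard_normal((60, 5))
        target = rng.standard_normal(60)
        w = ridge_solve(design, target, 1e12)
        assert np.linalg.norm(w) < 1e-6

    def test_hand_assembled_normal_equations(self):
        design = np.array(
            [[1, 0, 2], [0, 1, 1], [2, 1, 0], [1, 1, 1], [0, 2, 1]], dtype=float
        )
        target = np.array([1.0, 2.0, 0.0, 1.0, 3.0])
        lam = 1.0
        # hand-assembled 3x3 system: explicit loops, no shared code path
        gram = np.zeros((3, 3))
        xty = np.zeros(3)
        for i in range(5):
            for a in range(3):
                xty[a] += design[i, a] * target[i]
                for b in range(3):
                    gram[a, b] += design[i, a] * design[i, b]
        for a in range(3):
            gram[a, a] += lam
        expected = np.linalg.solve(gram, xty)
        np.testing.assert_allclose(ridge_solve(design, target, lam), expected, atol=1e-10)

    def test_singular_system_at_zero_lambda_raises(self):
        design = np.ones((10, 3))  # rank 1
        with pytest.raises(np.linalg.LinAlgError):
            ridge_solve(design, np.ones(10), 0.0)


class TestTemporalResponseFunction:
    def _noiseless_data(self, rng, n_trials=3, t_len=2000, n_chan=2):
        kernel_ms = np.arange(0, 80)
        kernel = np.sin(2 * np.pi * kernel_ms / 40.0) * np.exp(-kernel_ms / 30.0)
        topo = np.array([1.0, -0.5])[:n_chan]
        stims, resps = [], []
        for _ in range(n_trials):
            s = rng.standard_normal(t_len)
            r = np.convolve(s, kernel)[:t_len]
            resps.append(topo[:, None] * r[None, :])
            stims.append(s)
        return stims, resps, kernel

    def test_recovers_generating_kernel(self, rng):
        stims, resps, kernel = self._noiseless_data(rng)
        model = TemporalResponseFunction(
            stims, resps, fs=1000.0, lag_span_ms=(0.0, 79.0), lambdas=[1e-6]
        )
        res = model.fit()
        assert pearson_r(res.weights[:, 0], kernel[: res.weights.shape[0]]) > 0.99

    def test_zero_stimulus_gives_zero_trf(self):
        stims = [np.zeros(500)]
        resps = [np.random.default_rng(0).standard_normal((2, 500))]
        res = TemporalResponseFunction(stims, resps, fs=FS).fit()
        np.testing.assert_allclose(res.weights, 0.0, atol=1e-10)

    def test_single_lambda_equals_ridge_solve_on_concatenation(self, rng):
        stims = [rng.standard_normal(300) for _ in range(2)]
        resps = [rng.standard_normal((2, 300)) for _ in range(2)]
        lam = 10.0
        grid = LagGrid(-20.0, 100.0, FS)
        res = TemporalResponseFunction(
            stims, resps, fs=FS, lag_span_ms=(-20.0, 100.0), lambdas=[lam]
        ).fit()
        designs = np.vstack(
            [build_lagged_design(s, grid, "forward") for s in stims]
        )
        targets = np.vstack([r.T for r in resps])
        expected = ridge_solve(designs, targets, lam)
        np.testing.assert_allclose(res.weights, expected, atol=1e-8)

    def test_stimulus_delay_shifts_trf(self, rng):
        stims, resps, kernel = self._noiseless_data(rng, n_trials=2)
        d = 5
        delayed = [np.concatenate([np.zeros(d), s[:-d]]) for s in stims]
        res_base = TemporalResponseFunction(
            stims, resps, fs=1000.0, lag_span_ms=(-20.0, 99.0), lambdas=[1e-4]
        ).fit()
        res_delay = TemporalResponseFunction(
            delayed, resps, fs=1000.0, lag_span_ms=(-20.0, 99.0), lambdas=[1e-4]
        ).fit()
        # delaying s by d shifts h by -d lags
        base = res_base.weights[:, 0]
        shifted = res_delay.weights[:, 0]
        np.testing.assert_allclose(shifted[:-d], base[d:], atol=0.02 * np.abs(base).max())

    def test_trial_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="samples"):
            TemporalResponseFunction(
                [rng.standard_normal(100)], [rng.standard_normal((2, 90))], fs=FS
            )

    def test_summary_mentions_lambdas_and_lags(self, rng):
        stims = [rng.standard_normal(400)]
        resps = [rng.standard_normal((2, 400))]
        res = TemporalResponseFunction(stims, resps, fs=FS).fit()
        text = res.summary()
        assert "lambda" in text.lower()
        assert "-250..700" in text


class TestPostprocess:
    def _fit(self, rng):
        stims = [rng.standard_normal(2000)]
        resps = [rng.standard_normal((2, 2000))]
        return TemporalResponseFunction(stims, resps, fs=FS).fit()

    def test_trimmed_axis_spans_minus50_to_500(self, rng):
        wave = self._fit(rng).postprocess()
        assert wave.times_ms[0] >= -50.0 - 1e-9
        assert wave.times_ms[-1] <= 500.0 + 1e-9
        assert wave.times_ms[0] == pytest.approx(-50.0, abs=1000.0 / FS)
        assert wave.times_ms[-1] == pytest.approx(500.0, abs=1000.0 / FS)

    def test_constant_weights_become_zero(self, rng):
        res = self._fit(rng)
        res.weights = np.ones_like(res.weights)
        wave = res.postprocess()
        np.testing.assert_allclose(wave.data, 0.0, atol=1e-9)

    def test_high_frequency_ripple_removed(self, rng):
        res = self._fit(rng)
        lags = res.lag_grid.lags.astype(float)
        ripple = np.sin(2 * np.pi * 100.0 * lags / FS)  # 100 Hz along lag axis
        res.weights = np.tile(ripple[:, None], (1, 2))
        wave = res.postprocess()
        spectrum = np.abs(np.fft.rfft(wave.data[0]))
        freqs = np.fft.rfftfreq(wave.data.shape[1], 1 / FS)
        hi = spectrum[freqs > 60].max()
        ripple_in = np.abs(np.fft.rfft(ripple)).max()
        assert hi < ripple_in * 10 ** (-20 / 20)

    def test_double_postprocess_raises(self, rng):
        res = self._fit(rng)
        res.postprocess()
        with pytest.raises(RuntimeError, match="already"):
            res.postprocess()


class TestDecoder:
    def test_identity_mapping_reconstructs_training_stimulus(self, rng):
        s = rng.standard_normal(800)
        eeg = s[None, :].copy()
        model = StimulusDecoder(
            [eeg], [s], fs=FS, lag_span_ms=(0.0, 50.0), lambdas=[1e-8]
        )
        res = model.fit()
        assert res.accuracy(eeg, s) > 0.999

    def test_noise_eeg_reconstructs_nothing_held_out(self, rng):
        t_len = 2000
        eeg = [rng.standard_normal((4, t_len)) for _ in range(4)]
        stim = [rng.standard_normal(t_len) for _ in range(4)]
        r_folds, _ = loo_reconstruction(eeg, stim, fs=FS, lambdas=[1.0])
        assert np.all(np.abs(r_folds) < 3.0 / np.sqrt(t_len))

    def test_channel_subset_selects_channels(self, rng):
        s = rng.standard_normal(600)
        eeg = np.vstack([rng.standard_normal(600), s])
        res = StimulusDecoder(
            [eeg], [s], fs=FS, lag_span_ms=(0.0, 20.0), lambdas=[1e-8], channels=[1]
        ).fit()
        assert res.accuracy(eeg, s) > 0.999

    def test_per_trial_and_concatenated_agree_on_identical_trials(self, rng):
        s = rng.standard_normal(500)
        eeg = rng.standard_normal((2, 500))
        trials_r = [eeg, eeg.copy(), eeg.copy()]
        trials_s = [s, s.copy(), s.copy()]
        a = StimulusDecoder(trials_r, trials_s, fs=FS, lambdas=[1.0]).fit()
        b = StimulusDecoder(
            trials_r, trials_s, fs=FS, lambdas=[1.0], scheme="concatenated"
        ).fit()
        # identical trials: per-trial average equals the concatenated solve up
        # to the lambda scaling of triple-counted data
        assert pearson_r(a.weights, b.weights) > 0.999


class TestLeaveOneOut:
    def test_each_trial_held_out_exactly_once(self, rng):
        eeg = [rng.standard_normal((2, 400)) for _ in range(5)]
        stim = [rng.standard_normal(400) for _ in range(5)]
        r_folds, mean_r = loo_reconstruction(eeg, stim, fs=FS, lambdas=[1.0])
        assert r_folds.size == 5
        assert mean_r == pytest.approx(r_folds.mean())

    def test_identical_noiseless_trials_reproduce_training_accuracy(self, rng):
        s = rng.standard_normal(600)
        eeg = s[None, :].copy()
        trials_r = [eeg.copy() for _ in range(4)]
        trials_s = [s.copy() for _ in range(4)]
        r_folds, _ = loo_reconstruction(
            trials_r, trials_s, fs=FS, lag_span_ms=(0.0, 30.0), lambdas=[1e-8]
        )
        single = StimulusDecoder(
            [eeg], [s], fs=FS, lag_span_ms=(0.0, 30.0), lambdas=[1e-8]
        ).fit().accuracy(eeg, s)
        np.testing.assert_allclose(r_folds, single, atol=1e-6)

    def test_shuffled_stimulus_labels_destroy_reconstruction(self, rng):
        # EEG encodes each trial's own stimulus at a positive latency, so the
        # causal (0..500 ms) decoder can invert it; mismatched labels -> r ~ 0
        kernel = np.concatenate([np.zeros(8), np.exp(-np.arange(22) / 10.0)])
        stims = [rng.standard_normal(1500) for _ in range(4)]
        eeg = [np.convolve(s, kernel)[:1500][None, :] for s in stims]
        shuffled = [stims[(k + 1) % 4] for k in range(4)]
        _, mean_matched = loo_reconstruction(eeg, stims, fs=FS, lambdas=[1.0])
        _, mean_shuffled = loo_reconstruction(eeg, shuffled, fs=FS, lambdas=[1.0])
        assert mean_matched > 0.9
        assert abs(mean_shuffled) < 0.1

    def test_too_few_trials_rejected(self, rng):
        eeg = [rng.standard_normal((1, 100))] * 2
        stim = [rng.standard_normal(100)] * 2
        with pytest.raises(ValueError, match="3 trials"):
            loo_reconstruction(eeg, stim, fs=FS)

    def test_noiseless_single_channel_accuracy_approaches_one_as_lambda_shrinks(
        self, rng
    ):
        kernel = np.concatenate([np.zeros(8), np.exp(-np.arange(12) / 5.0)])
        stims = [rng.standard_normal(1200) for _ in range(3)]
        eeg = [np.convolve(s, kernel)[:1200][None, :] for s in stims]
        accs = []
        for lam in (1e2, 1e-2, 1e-8):
            _, mean_r = loo_reconstruction(
                eeg, stims, fs=FS, lag_span_ms=(0.0, 100.0), lambdas=[lam]
            )
            accs.append(mean_r)
        # approaches 1 (trial-edge zero padding keeps it just below)
        assert accs[-1] > 0.99
        assert accs[0] <= accs[1] <= accs[2] + 1e-12
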