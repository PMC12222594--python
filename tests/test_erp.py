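"""Epoching, baseline, rejection, sweep matching and component measures."""

import numpy as np
import pytest

from speechtrack import ContinuousRecording
from speechtrack.erp import (
    EpochSet,
    average_erp,
    baseline_correct,
    component_amplitude,
    epoch,
    match_sweep_counts,
    peak_latency,
    reject_artifacts,
)
from speechtrack.simulate import default_attended_kernel, default_ignored_kernel, render_kernel

FS = 256.0


def make_epochs(data, fs=FS, t0_ms=-500.0, baseline_applied=False):
    data = np.asarray(data, dtype=float)
    times = t0_ms + np.arange(data.shape[2]) / fs * 1000.0
    return EpochSet(data, times, fs, baseline_applied=baseline_applied)


class TestEpoch:
    def test_matches_direct_indexing_oracle(self, random_recording):
        triggers = np.array([300, 700, 1200])
        eps = epoch(random_recording, triggers, window_ms=(-100.0, 200.0))
        lo = int(round(-0.1 * random_recording.fs))
        for k, trg in enumerate(triggers):
            for n in range(random_recording.n_channels):
                for j in range(eps.data.shape[2]):
                    assert eps.data[k, n, j] == random_recording.data[n, trg + lo + j]

    def test_zero_window_gives_single_sample_sweeps(self, random_recording):
        eps = epoch(random_recording, np.array([50, 100]), window_ms=(0.0, 0.0))
        assert eps.data.shape[2] == 1
        np.testing.assert_array_equal(
            eps.data[:, :, 0], random_recording.data[:, [50, 100]].T
        )

    def test_out_of_bounds_triggers_dropped(self, random_recording):
        eps = epoch(random_recording, np.array([2, 500, 2047]), window_ms=(-100.0, 200.0))
        assert eps.n_sweeps == 1
        np.testing.assert_array_equal(eps.trigger_indices, [500])

    def test_empty_trigger_set_gives_empty_epochset(self, random_recording):
        eps = epoch(random_recording, np.array([], dtype=int))
        assert eps.n_sweeps == 0

    def test_noiseless_sweep_recovers_scaled_kernel(self):
        # triggers at the exact event onset of kernel responses
        kernel = render_kernel(default_attended_kernel(), FS)
        data = np.zeros((2, 4000))
        topo = np.array([1.0, 0.5])
        onsets = [1000, 2500]
        for o in onsets:
            data[:, o : o + kernel.size] += topo[:, None] * kernel[None, :]
        rec = ContinuousRecording(data, fs=FS)
        eps = epoch(rec, np.array(onsets), window_ms=(0.0, 500.0))
        span = kernel.size
        for k in range(2):
            for n in range(2):
                seg = eps.data[k, n, :span]
                expected = topo[n] * kernel[: seg.size]
                rms = np.sqrt(np.mean((seg - expected) ** 2))
                assert rms < 0.01 * np.sqrt(np.mean(expected**2))


class TestBaseline:
    def test_constant_sweep_becomes_zero(self):
        eps = make_epochs(np.full((1, 2, 768), 7.0))
        out = baseline_correct(eps)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_zero_mean_baseline_unchanged(self, rng):
        data = rng.standard_normal((3, 2, 768))
        eps = make_epochs(data)
        sel = eps.time_slice(-50.0, 0.0)
        data -= data[:, :, sel].mean(axis=2, keepdims=True)
        out = baseline_correct(make_epochs(data))
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_window_mean_zero_after_correction(self, rng):
        eps = make_epochs(rng.standard_normal((5, 3, 768)))
        out = baseline_correct(eps)
        sel = out.time_slice(-50.0, 0.0)
        np.testing.assert_allclose(
            out.data[:, :, sel].mean(axis=2), 0.0, atol=1e-12
        )

    def test_double_application_raises(self, rng):
        out = baseline_correct(make_epochs(rng.standard_normal((2, 1, 768))))
        with pytest.raises(RuntimeError, match="already"):
            baseline_correct(out)


class TestRejectArtifacts:
    def test_clean_sweeps_all_kept(self, rng):
        eps = make_epochs(
            50.0 * rng.uniform(-1, 1, (10, 4, 100)), baseline_applied=True
        )
        assert reject_artifacts(eps).n_accepted == 10

    def test_single_excursion_rejects_exactly_that_sweep(self, rng):
        data = rng.uniform(-50, 50, (5, 3, 100))
        data[2, 1, 40] = 101.0
        out = reject_artifacts(make_epochs(data, baseline_applied=True))
        np.testing.assert_array_equal(out.mask, [True, True, False, True, True])

    def test_matches_exhaustive_scan_oracle(self, rng):
        data = rng.normal(0, 60, (40, 4, 80))
        out = reject_artifacts(make_epochs(data, baseline_applied=True))
        oracle = np.array(
            [not np.any(np.abs(data[k]) > 100.0) for k in range(40)]
        )
        np.testing.assert_array_equal(out.mask, oracle)

    def test_requires_baseline_state(self, rng):
        with pytest.raises(RuntimeError, match="baseline"):
            reject_artifacts(make_epochs(rng.standard_normal((2, 1, 50))))

    def test_nonpositive_threshold_rejected(self, rng):
        eps = make_epochs(rng.standard_normal((2, 1, 50)), baseline_applied=True)
        with pytest.raises(ValueError, match="threshold"):
            reject_artifacts(eps, abs_threshold=0.0)


class TestMatchSweepCounts:
    def _pair(self, rng, n_a=30, n_b=20):
        return {
            "attended": make_epochs(rng.standard_normal((n_a, 2, 50)), baseline_applied=True),
            "ignored": make_epochs(rng.standard_normal((n_b, 2, 50)), baseline_applied=True),
        }

    def test_defaults_to_minimum_count(self, rng):
        out = match_sweep_counts(self._pair(rng), seed=0)
        assert out["attended"].n_accepted == 20
        assert out["ignored"].n_accepted == 20

    def test_n_equal_to_available_is_identity_as_set(self, rng):
        eps = self._pair(rng, 25, 25)
        out = match_sweep_counts(eps, n=25, seed=0)
        np.testing.assert_array_equal(
            np.sort(out["attended"].trigger_indices),
            np.sort(eps["attended"].trigger_indices),
        )

    def test_same_seed_same_subset(self, rng):
        eps = self._pair(rng)
        a = match_sweep_counts(eps, seed=5)
        b = match_sweep_counts(eps, seed=5)
        np.testing.assert_array_equal(
            a["attended"].trigger_indices, b["attended"].trigger_indices
        )

    def test_insufficient_sweeps_named_in_error(self, rng):
        with pytest.raises(ValueError, match="short of"):
            match_sweep_counts(self._pair(rng), n=25, seed=0)

    def test_selection_is_uniform(self, rng):
        # each of 200 sweeps should appear with frequency ~ n/N = 0.5
        eps = {"only": make_epochs(rng.standard_normal((200, 1, 4)), baseline_applied=True)}
        counts = np.zeros(200)
        reps = 10000
        master = np.random.default_rng(0)
        for _ in range(reps):
            out = match_sweep_counts(eps, n=100, seed=master)
            counts[out["only"].trigger_indices] += 1
        freq = counts / reps
        assert np.all(np.abs(freq - 0.5) < 0.02)


class TestAveraging:
    def test_single_sweep_average_is_itself(self, rng):
        data = rng.standard_normal((1, 2, 30))
        np.testing.assert_array_equal(average_erp(make_epochs(data)), data[0])

    def test_opposite_sweeps_cancel(self, rng):
        sweep = rng.standard_normal((2, 30))
        eps = make_epochs(np.stack([sweep, -sweep]))
        np.testing.assert_allclose(average_erp(eps), 0.0, atol=1e-12)

    def test_matches_loop_summation_oracle(self, rng):
        data = rng.standard_normal((7, 3, 20))
        eps = make_epochs(data)
        oracle = np.zeros((3, 20))
        for k in range(7):
            oracle += data[k]
        oracle /= 7
        np.testing.assert_allclose(average_erp(eps), oracle, atol=1e-12)

    def test_rejected_sweeps_excluded(self, rng):
        data = rng.standard_normal((4, 1, 10))
        eps = make_epochs(data)
        eps.mask[1] = False
        np.testing.assert_allclose(
            average_erp(eps), data[[0, 2, 3]].mean(axis=0), atol=1e-12
        )

    def test_zero_accepted_raises(self, rng):
        eps = make_epochs(rng.standard_normal((2, 1, 10)))
        eps.mask[:] = False
        with pytest.raises(ValueError, match="no accepted"):
            average_erp(eps)

    def test_average_then_window_equals_window_then_average(self, rng):
        data = rng.standard_normal((6, 2, 768))
        eps = make_epochs(data)
        avg_first = component_amplitude(average_erp(eps), eps.times_ms, 0, 136.7)
        times = eps.times_ms
        per_sweep = [
            component_amplitude(data[k], times, 0, 136.7) for k in range(6)
        ]
        assert avg_first == pytest.approx(np.mean(per_sweep), abs=1e-12)


class TestPeakAndAmplitude:
    def test_cosine_extremum_at_analytic_latency(self):
        fs = 256.0
        times = -500.0 + np.arange(641) / fs * 1000.0
        wave = np.cos(2 * np.pi * 5.0 * times / 1000.0)[None, :]
        # 5 Hz cosine: minimum at 100 ms
        lat = peak_latency(wave, times, 0, -1, (80.0, 120.0))
        assert lat == pytest.approx(100.0, abs=1000.0 / fs)

    def test_flat_window_returns_earliest_sample(self):
        times = np.arange(0.0, 400.0, 4.0)
        wave = np.ones((1, times.size))
        assert peak_latency(wave, times, 0, -1, (100.0, 200.0)) == 100.0

    def test_empty_window_raises(self):
        times = np.arange(0.0, 100.0, 4.0)
        with pytest.raises(ValueError, match="empty"):
            peak_latency(np.ones((1, times.size)), times, 0, -1, (500.0, 600.0))

    def test_kernel_n1_latency_recovered(self):
        kernel = render_kernel(default_attended_kernel(), FS)
        times = np.arange(kernel.size) / FS * 1000.0
        lat = peak_latency(kernel[None, :], times, 0, -1, (80.0, 180.0))
        assert lat == pytest.approx(135.0, abs=4.0)

    def test_constant_waveform_mean(self):
        times = np.arange(0.0, 500.0, 4.0)
        wave = np.full((1, times.size), 3.0)
        assert component_amplitude(wave, times, 0, 136.7) == pytest.approx(3.0)

    def test_n1_windowed_mean_matches_analytic_kernel(self):
        spec = default_attended_kernel()
        kernel = render_kernel(spec, FS)
        times = np.arange(kernel.size) / FS * 1000.0
        measured = component_amplitude(kernel[None, :], times, 0, 135.0)
        # analytic windowed mean of the Gaussian mixture on a fine grid
        fine = np.linspace(115.0, 155.0, 20001)
        analytic = np.mean(
            sum(
                pol * amp * np.exp(-0.5 * ((fine - peak) / width) ** 2)
                for pol, peak, width, amp in spec.components
            )
        )
        assert measured < 0
        assert measured == pytest.approx(analytic, rel=0.10)

    def test_attended_n1p2_exceeds_ignored_on_rendered_kernels(self):
        att = render_kernel(default_attended_kernel(), FS)
        ign = render_kernel(default_ignored_kernel(0.4), FS)
        times = np.arange(att.size) / FS * 1000.0

        def n1p2(k):
            n1 = component_amplitude(k[None, :], times, 0, 135.0)
            p2 = component_amplitude(k[None, :], times, 0, 225.0)
            return p2 - n1

        assert n1p2(att) > n1p2(ign)

    def test_window_outside_span_raises(self):
        times = np.arange(0.0, 100.0, 4.0)
        with pytest.raises(ValueError, match="outside"):
            component_amplitude(np.ones((1, times.size)), times, 0, 500.0)
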