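"""Metric suite: phase locking, trial correlation, entrainment, envelope
tracking, onset latency/jitter and rate epochs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bushycell import (StimulusSpec, correlation_index, corr_norm,
                       entrainment_index, fsl_min, vector_strength)
from bushycell.an_surrogate import vector_strength_from_kappa
from bushycell.response_metrics import (PSTH, first_spike_jitter, make_psth,
                                        onset_probability, rate_epochs,
                                        sam_envelope)


class TestVectorStrength:
    def test_perfect_locking(self):
        spikes = np.array([0.0, 10.0, 20.0, 30.0])  # 100 Hz period 10 ms
        assert vector_strength(spikes, 100.0) == pytest.approx(1.0)

    def test_antiphase_cancellation(self):
        spikes = np.array([0.0, 5.0, 10.0, 15.0])  # alternating 0 and pi
        assert vector_strength(spikes, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_empty_window_is_nan(self):
        assert np.isnan(vector_strength(np.array([1.0]), 100.0, (5.0, 6.0)))

    def test_von_mises_sample_matches_analytic(self):
        rng = np.random.default_rng(0)
        kappa = 2.0
        n = 20_000
        phases = rng.vonmises(0.0, kappa, n)
        times = (phases / (2 * np.pi)) * 10.0  # 100 Hz
        vs = vector_strength(times, 100.0)
        expected = vector_strength_from_kappa(kappa)
        se = np.sqrt((1 - expected**2) / (2 * n))
        assert abs(vs - expected) < 3 * se

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.0, 500.0), min_size=1, max_size=50),
           st.integers(0, 5))
    def test_bounds_and_period_translation(self, times, k_periods):
        spikes = np.array(times)
        vs = vector_strength(spikes, 100.0)
        assert 0.0 <= vs <= 1.0 + 1e-12
        shifted = vector_strength(spikes + 10.0 * k_periods, 100.0)
        assert shifted == pytest.approx(vs, abs=1e-9)


class TestCorrelationIndex:
    def test_independent_poisson_is_chance(self):
        rng = np.random.default_rng(1)
        dur = 1000.0
        trials = [np.sort(rng.uniform(0, dur, rng.poisson(0.1 * dur)))
                  for _ in range(20)]
        ci = correlation_index(trials, coinc_window=0.05, duration=dur)
        assert ci == pytest.approx(1.0, abs=0.1)

    def test_identical_sparse_trains(self):
        # 3 spikes repeated over trials, sparser than the window:
        # every cross-trial pair coincides exactly once per spike
        train = np.array([10.0, 20.0, 30.0])
        trials = [train.copy() for _ in range(4)]
        dur, w = 100.0, 0.05
        ci = correlation_index(trials, coinc_window=w, duration=dur)
        # N(N-1)*3 coincidences over N(N-1) r^2 w D with r = 3/100
        expected = 3.0 / ((3.0 / dur) ** 2 * w * dur)
        assert ci == pytest.approx(expected)
        assert ci > 100  # far above chance

    def test_no_coincidences_is_zero(self):
        trials = [np.array([10.0]), np.array([50.0])]
        assert correlation_index(trials, 0.05, duration=100.0) == 0.0

    def test_trial_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        trials = [np.sort(rng.uniform(0, 200, 30)) for _ in range(6)]
        ci1 = correlation_index(trials, 0.05, duration=200.0)
        ci2 = correlation_index(trials[::-1], 0.05, duration=200.0)
        assert ci1 == pytest.approx(ci2)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            correlation_index([np.array([1.0])], 0.05, duration=10.0)

    def test_cross_fiber_independence_of_surrogate(self):
        # different fibers' trains behave as independent trials: CI ~ 1.
        # A flat rate keeps the chance normalization unbiased (the SAC
        # denominator assumes stationarity).
        from bushycell import ANFiberParams, StimulusSpec, generate_trains
        stim = StimulusSpec(duration=0.0, pause=1000.0, n_reps=1,
                            onset_latency=0.0)
        params = ANFiberParams(sr=200.0, onset_rate=200.0,
                               sustained_rate=200.0)
        trains = generate_trains(stim, params, 30, seed=3)
        per_fiber = [trains.spikes[f][0] for f in range(30)]
        ci = correlation_index(per_fiber, 0.05, window=(0.0, 1000.0))
        assert ci == pytest.approx(1.0, abs=0.1)


class TestEntrainmentIndex:
    def test_one_spike_per_cycle(self):
        trials = [np.arange(0.0, 100.0, 5.0)]  # period 5 ms
        assert entrainment_index(trials, period=5.0) == 1.0

    def test_every_second_cycle(self):
        trials = [np.arange(0.0, 100.0, 10.0)]
        assert entrainment_index(trials, period=5.0) == 0.0

    def test_mixture_fraction(self):
        # 7 one-cycle intervals and 3 two-cycle intervals
        isis = [5.0] * 7 + [10.0] * 3
        trials = [np.concatenate([[0.0], np.cumsum(isis)])]
        assert entrainment_index(trials, period=5.0) == pytest.approx(0.7)

    def test_no_intervals_is_nan(self):
        assert np.isnan(entrainment_index([np.array([1.0])], period=5.0))


class TestCorrNorm:
    def _psth(self, rates, bin_width=0.5):
        edges = np.arange(0, (len(rates) + 1) * bin_width - 1e-9, bin_width)
        counts = np.asarray(rates) * bin_width * 1e-3  # 1 trial
        return PSTH(edges=edges, counts=counts, n_trials=1,
                    bin_width=bin_width)

    def test_proportional_signals_give_one(self):
        env = 1.0 + np.cos(2 * np.pi * np.arange(100) / 10.0)
        psth = self._psth(200.0 * env)
        assert corr_norm(psth, env, max_lag=0.0) == pytest.approx(1.0)

    def test_constant_response_floor(self):
        # flat PSTH against a fully modulated envelope: 1/sqrt(1.5) ~ 0.82
        n = 1000  # many whole cycles
        env = 1.0 + np.cos(2 * np.pi * np.arange(n) / 10.0)
        psth = self._psth(np.full(n, 150.0))
        assert corr_norm(psth, env, max_lag=5.0) == pytest.approx(
            1.0 / np.sqrt(1.5), abs=0.005)

    def test_halfwave_rectified_sine(self):
        # p = max(cos, 0) against e = 1 + cos over whole cycles:
        # <pe> = 1/pi + 1/4, <p^2> = 1/4, <e^2> = 3/2 (numeric oracle below)
        n = 10_000
        phase = 2 * np.pi * np.arange(n) / 100.0
        p = np.maximum(np.cos(phase), 0.0)
        e = 1.0 + np.cos(phase)
        expected = float(np.sum(p * e)
                         / np.sqrt(np.sum(p * p) * np.sum(e * e)))
        analytic = (1 / np.pi + 0.25) / np.sqrt(0.25 * 1.5)
        assert expected == pytest.approx(analytic, abs=1e-3)
        psth = self._psth(p * 400.0)
        assert corr_norm(psth, e, max_lag=0.0) == pytest.approx(expected,
                                                               abs=1e-9)

    def test_scale_invariance_and_lag_recovery(self):
        n = 400
        env = 1.0 + np.cos(2 * np.pi * np.arange(n) / 20.0)
        shifted = np.roll(env, 6)  # response lags the envelope by 6 bins
        psth = self._psth(shifted * 123.0)
        assert corr_norm(psth, env, max_lag=5.0) == pytest.approx(1.0,
                                                                  abs=1e-6)
        psth10 = self._psth(shifted * 1230.0)
        assert corr_norm(psth10, env, max_lag=5.0) == pytest.approx(
            corr_norm(psth, env, max_lag=5.0))

    def test_all_zero_response_is_nan(self):
        psth = self._psth(np.zeros(100))
        assert np.isnan(corr_norm(psth, np.ones(100)))


class TestOnsetMetrics:
    def test_fsl_with_zero_spontaneous_rate(self):
        trials = [np.array([5.0, 8.0]) for _ in range(30)]
        fsl = fsl_min(trials, sr=0.0, onset=0.0)
        assert fsl == pytest.approx(5.0, abs=0.1)

    def test_fsl_poisson_step_detection(self):
        # SR 60 Hz stepping to 600 Hz at 10 ms, 100 trials
        rng = np.random.default_rng(5)
        trials = []
        for _ in range(100):
            spont = rng.uniform(0, 10, rng.poisson(60 * 10e-3))
            driven = 10.0 + rng.uniform(0, 40, rng.poisson(600 * 40e-3))
            trials.append(np.sort(np.concatenate([spont, driven])))
        fsl = fsl_min(trials, sr=60.0, onset=0.0, t_max=50.0)
        assert 10.0 <= fsl <= 11.0

    def test_pure_spontaneous_activity_stays_undetected(self):
        rng = np.random.default_rng(6)
        trials = [np.sort(rng.uniform(0, 200, rng.poisson(60 * 0.2)))
                  for _ in range(100)]
        assert np.isnan(fsl_min(trials, sr=60.0, onset=0.0, t_max=200.0))

    def test_jitter_zero_for_identical_first_spikes(self):
        trials = [np.array([5.0, 9.0]) for _ in range(20)]
        assert first_spike_jitter(trials, fsl=5.0) == 0.0

    def test_jitter_of_uniform_latencies(self):
        rng = np.random.default_rng(7)
        # first spikes uniform over the 1.8 ms analysis window
        trials = [np.array([rng.uniform(4.4, 6.2)]) for _ in range(4000)]
        jit = first_spike_jitter(trials, fsl=5.0)
        assert jit == pytest.approx(1.8 / np.sqrt(12), rel=0.05)

    def test_onset_probability_counts_trials(self):
        trials = [np.array([5.2]) for _ in range(9)] + [np.array([40.0])]
        assert onset_probability(trials, fsl=5.0) == pytest.approx(0.9)
        assert np.isnan(onset_probability(trials, fsl=float("nan")))


class TestRateEpochs:
    def test_hand_counted_rates(self):
        stim = StimulusSpec(duration=200.0, pause=200.0, n_reps=1,
                            onset_latency=0.0)
        # 10 spikes in the sustained window, 3 in the final 150 ms pause
        sustained = np.linspace(60.0, 140.0, 10)
        spont = np.array([260.0, 300.0, 390.0])
        trials = [np.sort(np.concatenate([sustained, spont]))]
        evoked, sust, sp = rate_epochs(trials, stim)
        assert evoked == pytest.approx(10 / 0.2)
        assert sust == pytest.approx(10 / 0.15)
        assert sp == pytest.approx(3 / 0.15)

    def test_no_spikes_gives_zero(self):
        stim = StimulusSpec(duration=200.0, pause=200.0, n_reps=1,
                            onset_latency=0.0)
        evoked, sust, sp = rate_epochs([np.empty(0)], stim)
        assert evoked == sust == sp == 0.0


class TestEnvelope:
    def test_sam_envelope_bounds_and_support(self):
        stim = StimulusSpec(kind="sam", frequency=13000.0, mod_frequency=200.0,
                            duration=100.0, pause=50.0, n_reps=1,
                            onset_latency=2.4)
        t = np.arange(0, 150, 0.5)
        env = sam_envelope(t, stim)
        assert env[t < 2.4].max() == 0.0
        assert env[t > 102.4].max() == 0.0
        inside = env[(t >= 2.4) & (t < 102.4)]
        assert inside.max() == pytest.approx(2.0, abs=0.01)
        assert inside.min() == pytest.approx(0.0, abs=0.01)

    def test_make_psth_rate_normalization(self):
        trials = [np.array([1.0, 2.0]), np.array([1.2])]
        psth = make_psth(trials, t_stop=4.0, bin_width=1.0)
        assert psth.counts.sum() == 3
        # 2 spikes in bin [1,2) over 2 trials of 1 ms: 1000 spikes/s
        assert psth.rate[1] == pytest.approx(1000.0)
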