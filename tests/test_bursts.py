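"""Burst detection against an exhaustive oracle, plus the timing and
amplitude statistics built on it."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metronome.bursts import (BurstEvent, BurstThreshold, burst_threshold,
                              detect_bursts, fit_amplitude_growth,
                              onset_distribution_chi2, sort_and_align,
                              switch_vs_mid_test)
from metronome.config import ConfigError
from metronome.spectral import GammaEnvelope, InputError


from conftest import oracle_scan  # noqa: E402


def make_env(amp, step=1.0, t0=0.0, trial_id=0):
    amp = np.asarray(amp, float)
    return GammaEnvelope(amplitude=amp, time_ms=t0 + step * np.arange(amp.size),
                         band_hz=(30.0, 40.0), method="bandpass-analytic",
                         trial_id=trial_id)


class TestThreshold:
    def test_percentile_linear_interpolation(self):
        env = make_env(np.arange(1.0, 101.0))
        thr = burst_threshold([env], 90.0)
        assert thr.value == pytest.approx(90.1)

    def test_degenerate_distribution(self):
        thr = burst_threshold([make_env(np.full(50, 3.25))], 90.0)
        assert thr.value == 3.25

    def test_scale_equivariance(self, rng):
        amp = rng.exponential(1.0, 500)
        t1 = burst_threshold([make_env(amp)]).value
        t2 = burst_threshold([make_env(2 * amp)]).value
        assert t2 == pytest.approx(2 * t1)

    def test_empty_pool_rejected(self):
        with pytest.raises(InputError):
            burst_threshold([make_env(np.ones(10))], window=(900.0, 1000.0))


class TestDetect:
    def test_all_below_threshold(self):
        evs = detect_bursts(make_env(np.ones(500)), BurstThreshold(2.0, 90, ""))
        assert evs == []

    def test_duration_gate_99_vs_101(self):
        thr = BurstThreshold(1.0, 90, "")
        base = np.zeros(400)
        a99 = base.copy()
        a99[100:199] = 2.0
        assert detect_bursts(make_env(a99), thr, 100.0) == []
        a101 = base.copy()
        a101[100:201] = 2.0
        evs = detect_bursts(make_env(a101), thr, 100.0)
        assert len(evs) == 1
        assert evs[0].onset_ms == 100.0
        assert evs[0].duration_ms == 101.0

    def test_min_dur_must_span_two_samples(self):
        with pytest.raises(ConfigError):
            detect_bursts(make_env(np.ones(100), step=60.0),
                          BurstThreshold(0.5, 90, ""), 100.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        amp = np.abs(rng.standard_normal(2000).cumsum() / 10.0)
        env = make_env(amp, step=5.0)
        thr = BurstThreshold(float(np.percentile(amp, 80)), 80, "")
        evs = detect_bursts(env, thr, 100.0)
        ref = oracle_scan(amp, env.time_ms, thr.value, 100.0, 5.0)
        assert len(evs) == len(ref)
        for ev, (onset, dur, peak, mean) in zip(evs, ref):
            assert ev.onset_ms == onset
            assert ev.duration_ms == pytest.approx(dur)
            assert ev.peak_amp == pytest.approx(peak)
            assert ev.mean_amp == pytest.approx(mean)

    def test_threshold_nesting_and_duration_monotonicity(self, rng):
        # raising the threshold shrinks the supra-threshold set: every
        # burst found at a high threshold lies inside one found at a lower
        # threshold, and a stricter duration gate never adds bursts
        amp = np.abs(rng.standard_normal(3000).cumsum() / 10.0)
        env = make_env(amp)
        lo = detect_bursts(env, BurstThreshold(
            float(np.percentile(amp, 70)), 70, ""), 20.0)
        hi = detect_bursts(env, BurstThreshold(
            float(np.percentile(amp, 90)), 90, ""), 20.0)
        for h in hi:
            assert any(b.onset_ms <= h.onset_ms
                       and h.offset_ms <= b.offset_ms for b in lo)
        thr = BurstThreshold(float(np.percentile(amp, 70)), 70, "")
        counts_dur = [len(detect_bursts(env, thr, d))
                      for d in (20.0, 50.0, 100.0, 200.0)]
        assert counts_dur == sorted(counts_dur, reverse=True)


class TestSortAlign:
    def test_stable_order_on_ties_and_counting(self):
        envs = []
        for tid in range(4):
            amp = np.zeros(600)
            amp[200:350] = 2.0
            envs.append(make_env(amp, trial_id=tid))
        thr = BurstThreshold(1.0, 90, "")
        bursts = [b for e in envs for b in detect_bursts(e, thr, 100.0)]
        order, aligned, onsets = sort_and_align(bursts, envs, (0.0, 600.0))
        assert list(order) == [0, 1, 2, 3]          # identical onsets: stable
        assert aligned.shape[0] == len(bursts)
        assert np.all(np.isfinite(onsets))

    def test_burstless_trial_goes_last(self):
        amp = np.zeros(600)
        amp[100:300] = 2.0
        envs = [make_env(amp, trial_id=0), make_env(np.zeros(600), trial_id=1)]
        bursts = detect_bursts(envs[0], BurstThreshold(1.0, 90, ""), 100.0)
        order, _, onsets = sort_and_align(bursts, envs, (0.0, 600.0))
        assert order[-1] == 1
        assert np.isnan(onsets[1])

    def test_aligned_matrix_peaks_after_onset(self, fast_tempo_session):
        from metronome.bursts import detect_session_bursts
        from metronome.spectral import trial_envelopes
        session, _ = fast_tempo_session
        envs = trial_envelopes(session, channel=0,
                               method="bandpass-analytic")
        bursts = detect_session_bursts(envs, session.trials)
        order, aligned, _ = sort_and_align(bursts, envs, (1500.0, 3500.0))
        profile = aligned.mean(axis=0)
        lag_ms = -100.0 + np.argmax(profile) * envs[0].step_ms
        assert 0.0 < lag_ms < 250.0   # peak follows onset by ~ the rise time


class TestSwitchVsMid:
    def test_flat_envelope_gives_null(self, rng):
        from metronome.synth import make_trials
        from metronome.config import TaskConfig
        trials = make_trials(TaskConfig(tempos_ms=(500.0,)), 10, 0)
        envs = [make_env(1.0 + 0.01 * rng.standard_normal(4000), t0=-500.0,
                         trial_id=t.trial_id) for t in trials]
        res = switch_vs_mid_test(envs, trials)
        assert abs(res["t"]) < 3.0

    def test_switch_locked_bursts_detected(self, fast_tempo_session):
        from metronome.spectral import trial_envelopes
        session, _ = fast_tempo_session
        envs = trial_envelopes(session, channel=0,
                               method="bandpass-analytic")
        res = switch_vs_mid_test(envs, session.trials, epoch="maintenance")
        assert res["mean_switch"] > res["mean_mid"]
        assert res["p"] < 0.01

    def test_degrees_of_freedom_count(self, rng):
        # 131 paired observations x 3 switch/mid pairs -> df = 392
        from metronome.session import TrialRecord
        bounds = {"baseline": (-500.0, 0.0), "entrainment": (0.0, 1500.0),
                  "maintenance": (1500.0, 3500.0)}
        recs, envs = [], []
        for k in range(131):
            recs.append(TrialRecord(
                trial_id=k, tempo_ms=500.0, start_side="left",
                n_maintenance=4, switch_times_ms=500.0 * np.arange(1, 7),
                go_cue_ms=3250.0, epoch_bounds=bounds))
            envs.append(make_env(rng.random(4000), t0=-500.0, trial_id=k))
        res = switch_vs_mid_test(envs, recs, epoch="maintenance")
        assert res["df"] == 131 * 3 - 1


class TestOnsetChi2:
    @staticmethod
    def _bursts(phases, group, tempo=500.0):
        return [BurstEvent(trial_id=0, onset_ms=group * 10000 + p * tempo,
                           offset_ms=0, duration_ms=100, peak_amp=1,
                           mean_amp=1, interval_index=group, tempo_ms=tempo)
                for p in phases]

    def test_identical_groups_give_zero_statistic(self, rng):
        ph = rng.random(100)
        bursts = self._bursts(ph, 0) + self._bursts(ph, 1)
        out = onset_distribution_chi2(bursts)
        assert out["chi2"].iloc[0] == 0.0
        assert out["p_bonferroni"].iloc[0] == 1.0

    def test_phase_shift_detected(self, rng):
        ph = rng.beta(2, 5, 200)
        bursts = self._bursts(ph, 0) + self._bursts((ph + 0.25) % 1.0, 1)
        out = onset_distribution_chi2(bursts)
        assert out["p_bonferroni"].iloc[0] < 0.01

    def test_small_group_excluded(self, rng):
        bursts = self._bursts(rng.random(100), 0) + self._bursts(
            rng.random(5), 1)
        with pytest.raises(InputError):
            onset_distribution_chi2(bursts)


class TestGrowthFit:
    @staticmethod
    def _bursts(t_s, amps):
        return [BurstEvent(trial_id=0, onset_ms=t * 1000.0, offset_ms=0,
                           duration_ms=100, peak_amp=a, mean_amp=a,
                           interval_index=int(t), tempo_ms=1000.0)
                for t, a in zip(t_s, amps)]

    def test_exact_exponential_recovery(self):
        t = np.linspace(0.1, 3.0, 30)
        amps = 1.4 * np.exp(0.45 * t)
        fit = fit_amplitude_growth(self._bursts(t, amps), "exponential")
        assert fit["coef"]["a"] == pytest.approx(1.4, abs=1e-6)
        assert fit["coef"]["b"] == pytest.approx(0.45, abs=1e-6)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_noisy_linear_slope_within_two_se(self, rng):
        t = rng.uniform(0.0, 3.5, 500)
        amps = 1.5 + 0.5 * t + rng.normal(0.0, 0.1, t.size)
        fit = fit_amplitude_growth(self._bursts(t, amps), "linear")
        se = 0.1 / (np.std(t) * np.sqrt(t.size))
        assert abs(fit["coef"]["slope"] - 0.5) < 2 * se

    def test_constant_amplitudes_flat(self, rng):
        t = rng.uniform(0.0, 3.0, 100)
        fit = fit_amplitude_growth(self._bursts(t, np.full(100, 2.0)),
                                   "linear")
        assert fit["coef"]["slope"] == pytest.approx(0.0, abs=1e-9)
        assert fit["r2"] == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_amplitude_rejected_for_exponential(self):
        with pytest.raises(InputError):
            fit_amplitude_growth(self._bursts([0.1, 0.2, 0.3], [1.0, -1.0,
                                                                2.0]),
                                 "exponential")
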