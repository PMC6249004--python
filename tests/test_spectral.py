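"""Spectral estimation: multitaper spectrogram, baseline normalization,
gamma envelope, envelope periodogram, permutation testing."""

import numpy as np
import pytest
from scipy import stats

from metronome.config import AnalysisConfig, ConfigError
from metronome.spectral import (GammaEnvelope, InputError,
                                envelope_periodogram, gamma_envelope,
                                multitaper_spectrogram, normalize_to_baseline,
                                permutation_test_bins, spectral_centroid,
                                Spectrogram)

FS = 1000.0


def tone(f, dur_s, amp=1.0, fs=FS):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * f * t)


class TestMultitaper:
    def test_tone_peaks_at_its_frequency(self):
        spec = multitaper_spectrogram(tone(35.0, 2.0), FS)
        mean_p = spec.power.mean(axis=0)
        assert spec.freq_hz[np.argmax(mean_p)] == pytest.approx(35.0, abs=2.5)

    def test_power_scales_quadratically(self):
        p1 = multitaper_spectrogram(tone(35.0, 2.0), FS).power
        p2 = multitaper_spectrogram(tone(35.0, 2.0, amp=2.0), FS).power
        band = np.argmax(p1.mean(axis=0))
        assert p2[:, band].mean() / p1[:, band].mean() == pytest.approx(
            4.0, rel=0.01)

    def test_white_noise_is_flat(self, rng):
        # mean power equal across the 5-80 Hz axis within Monte-Carlo error
        levels = []
        for _ in range(2):
            spec = multitaper_spectrogram(rng.standard_normal(4000), FS)
            levels.append(spec.power.mean(axis=0))
        m = np.mean(levels, axis=0)
        se = np.std(levels, axis=0, ddof=1) / np.sqrt(len(levels))
        grand = m.mean()
        # use pooled spread across frequencies as the reference scale
        assert np.all(np.abs(m - grand) < 6 * m.std(ddof=1) + 3 * se.max())

    def test_short_signal_rejected(self):
        with pytest.raises(InputError):
            multitaper_spectrogram(np.zeros(100), FS)

    def test_time_axis_step_and_window_count(self):
        spec = multitaper_spectrogram(np.zeros(1000) + tone(35, 1.0), FS,
                                      t0_ms=-500.0)
        assert np.allclose(np.diff(spec.time_ms), 5.0)
        assert spec.time_ms[0] == pytest.approx(-400.0)  # first center


class TestBaselineNormalization:
    def test_stationary_signal_normalizes_to_one(self, rng):
        x = rng.standard_normal(4000)
        spec = multitaper_spectrogram(x, FS, t0_ms=-2000.0)
        norm = normalize_to_baseline(spec, (-2000.0, 0.0))
        rows = norm.time_ms < 0
        assert np.allclose(norm.power[rows].mean(axis=0), 1.0, atol=1e-9)
        # the rest of a stationary signal stays near 1 within estimator noise
        assert norm.power[~rows].mean() == pytest.approx(1.0, abs=0.35)

    def test_step_change_in_power_is_recovered(self):
        x = np.concatenate([tone(35.0, 1.0), tone(35.0, 2.0, amp=np.sqrt(2))])
        spec = multitaper_spectrogram(x, FS, t0_ms=-1000.0)
        norm = normalize_to_baseline(spec, (-1000.0, 0.0))
        f35 = np.argmin(np.abs(norm.freq_hz - 35.0))
        late = norm.time_ms > 200.0
        assert norm.power[late, f35].mean() == pytest.approx(2.0, rel=0.1)

    def test_baseline_bin_count(self):
        x = tone(35.0, 2.0)
        spec = multitaper_spectrogram(x, FS, t0_ms=-600.0)
        rows = (spec.time_ms >= -500.0) & (spec.time_ms < 0.0)
        assert rows.sum() == 100   # 500 ms at 5 ms steps

    def test_empty_baseline_rejected(self):
        spec = multitaper_spectrogram(tone(35.0, 1.0), FS)
        with pytest.raises(InputError):
            normalize_to_baseline(spec, (-500.0, 0.0))


class TestGammaEnvelope:
    def test_methods_agree_on_modulated_tone(self):
        # 35 Hz carrier under a slow continuous amplitude modulation: both
        # envelope paths must rank time points the same way
        t = np.arange(3000) / FS
        x = (1.0 + 0.8 * np.sin(2 * np.pi * 1.0 * (t - 1.0))) \
            * np.sin(2 * np.pi * 35.0 * t)
        spec = normalize_to_baseline(
            multitaper_spectrogram(x, FS, t0_ms=-1000.0), (-1000.0, 0.0))
        e1 = gamma_envelope(spec)
        e2 = gamma_envelope(x, method="bandpass-analytic", fs=FS,
                            t0_ms=-1000.0, baseline_window=(-1000.0, 0.0))
        a2 = np.interp(e1.time_ms, e2.time_ms, e2.amplitude)
        rho = stats.spearmanr(e1.amplitude, a2).statistic
        assert rho > 0.9

    def test_methods_see_step_amplitude_at_same_time(self):
        x = np.concatenate([tone(35.0, 1.0, amp=0.5), tone(35.0, 1.0, 2.0)])
        spec = normalize_to_baseline(
            multitaper_spectrogram(x, FS, t0_ms=-1000.0), (-1000.0, 0.0))
        e1 = gamma_envelope(spec)
        e2 = gamma_envelope(x, method="bandpass-analytic", fs=FS,
                            t0_ms=-1000.0, baseline_window=(-1000.0, 0.0))
        for env in (e1, e2):
            step = env.time_ms > 150.0
            pre = (env.time_ms > -900) & (env.time_ms < -150)
            assert env.amplitude[step].mean() > 2 * env.amplitude[pre].mean()

    def test_out_of_band_tone_stays_at_baseline(self, rng):
        x = tone(10.0, 2.0) + 0.1 * rng.standard_normal(2000)
        env = gamma_envelope(x, method="bandpass-analytic", fs=FS,
                             t0_ms=-500.0, baseline_window=(-500.0, 0.0))
        post = env.time_ms > 0
        assert env.amplitude[post].mean() == pytest.approx(1.0, rel=0.25)

    def test_baseline_mean_is_one(self, rng):
        x = rng.standard_normal(3000)
        env = gamma_envelope(x, method="bandpass-analytic", fs=FS,
                             t0_ms=-500.0, baseline_window=(-500.0, 0.0))
        base = (env.time_ms >= -500) & (env.time_ms < 0)
        assert env.amplitude[base].mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(env.amplitude >= 0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            gamma_envelope(np.zeros(1000), method="wavelet-magic", fs=FS,
                           baseline_window=(-500.0, 0.0))


class TestEnvelopePeriodogram:
    @staticmethod
    def _env(amplitude, t0=0.0, step=5.0):
        n = amplitude.size
        return GammaEnvelope(amplitude=amplitude,
                             time_ms=t0 + step * np.arange(n),
                             band_hz=(30.0, 40.0), method="bandpass-analytic",
                             trial_id=0)

    def test_cosine_envelope_peaks_at_its_rate(self):
        t = np.arange(0, 2000.0, 5.0) / 1000.0
        env = self._env(1.0 + np.cos(2 * np.pi * 2.0 * t))
        f, p = envelope_periodogram([env], (0.0, 2000.0))
        assert f[np.argmax(p[1:]) + 1] == pytest.approx(2.0, abs=0.5)

    def test_parseval_total_power_equals_variance(self, rng):
        amp = rng.standard_normal(400)
        env = self._env(amp)
        f, p = envelope_periodogram([env], (0.0, 2000.0), fmax_hz=None)
        df = f[1] - f[0]
        total = p.sum() * df
        assert total == pytest.approx(amp.var(), rel=0.01)

    def test_too_short_epoch_rejected(self):
        env = self._env(np.ones(4))
        with pytest.raises(InputError, match="common length"):
            envelope_periodogram([env], (0.0, 20.0))

    def test_centroid_requires_power(self):
        f = np.arange(0, 5.0, 0.5)
        with pytest.raises(InputError):
            spectral_centroid(f, np.zeros_like(f))


class TestPermutationTest:
    @staticmethod
    def _null_specs(rng, n_trials=20, n_time=40, n_freq=3):
        time_ms = np.arange(n_time) * 25.0 - 500.0
        freq = np.array([30.0, 35.0, 40.0])[:n_freq]
        return [Spectrogram(power=rng.exponential(1.0, (n_time, n_freq)),
                            time_ms=time_ms, freq_hz=freq, window_ms=200,
                            step_ms=25, n_tapers=1, bandwidth_hz=5)
                for _ in range(n_trials)]

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        specs = self._null_specs(rng)
        for s in specs:          # make task bins hugely elevated
            s.power[s.time_ms >= 0] += 100.0
        p, _, _ = permutation_test_bins(specs, (-500.0, 0.0), 1000, 0)
        assert p.min() == pytest.approx(1.0 / 1001.0)

    def test_null_p_values_superuniform(self, rng):
        ps = []
        for sim in range(20):
            specs = self._null_specs(rng)
            p, _, _ = permutation_test_bins(specs, (-500.0, 0.0), 200, sim)
            ps.append(p.ravel())
        ps = np.concatenate(ps)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
        assert abs((ps < 0.05).mean() - 0.05) < 0.02

    def test_detects_switch_locked_gamma(self, fast_tempo_session):
        from metronome.spectral import multitaper_spectrogram
        session, _ = fast_tempo_session
        cfg = AnalysisConfig()
        trials = [t for t in session.trials if t.n_maintenance >= 2][:20]
        specs = []
        for tr in trials:
            x = session.trial_slice(tr.trial_id, -600.0, 2500.0)
            specs.append(multitaper_spectrogram(x, FS, cfg, t0_ms=-600.0))
        p, t_axis, f_axis = permutation_test_bins(specs, (-500.0, 0.0),
                                                  1000, 1)
        gamma = (f_axis >= 30) & (f_axis <= 40)
        late = t_axis > 1500.0    # well into the trial, bursts grown
        assert p[np.ix_(late, gamma)].min() <= 1.5 / 1001.0

    def test_low_n_perm_rejected(self, rng):
        with pytest.raises(ConfigError):
            permutation_test_bins(self._null_specs(rng), (-500.0, 0.0), 50, 0)
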