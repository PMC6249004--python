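"""Firing-rate analyses and spike-triggered-average coupling."""

import numpy as np
import pandas as pd
import pytest

from metronome.config import ConfigError
from metronome.session import TrialRecord
from metronome.spectral import InputError
from metronome.spikefield import (RateSeries, detrend_rates, firing_rate,
                                  rate_crosscorr_lag, spatial_preference,
                                  spike_triggered_average, sta_band_anova,
                                  sta_jitter_control)


def make_trial(tid, tempo=500.0, n_m=4, start="left", correct=True):
    ent_off = 3 * tempo
    return TrialRecord(
        trial_id=tid, tempo_ms=tempo, start_side=start, n_maintenance=n_m,
        switch_times_ms=tempo * np.arange(1, 3 + n_m),
        go_cue_ms=ent_off + (n_m - 0.5) * tempo,
        epoch_bounds={"baseline": (-500.0, 0.0),
                      "entrainment": (0.0, ent_off),
                      "maintenance": (ent_off, ent_off + n_m * tempo)},
        correct=correct)


class TestFiringRate:
    def test_poisson_rate_recovered(self, rng):
        trials = [make_trial(i) for i in range(500)]
        onsets = {i: 6000.0 * i for i in range(500)}
        spikes = np.sort(rng.uniform(0.0, 3_000_000.0, 60000))
        rate = firing_rate(spikes, trials, onsets, window_ms=(0.0, 3500.0))
        assert rate.rates_hz["all"].mean() == pytest.approx(20.0, abs=1.0)

    def test_empty_spike_train(self):
        trials = [make_trial(0)]
        rate = firing_rate(np.empty(0), trials, {0: 500.0})
        assert np.allclose(rate.rates_hz["all"], 0.0)

    def test_kernel_preserves_spike_mass(self):
        trials = [make_trial(0)]
        spikes = np.array([1500.0, 1600.0, 1700.0, 1800.0]) + 500.0
        rate = firing_rate(spikes, trials, {0: 500.0},
                           window_ms=(0.0, 3500.0))
        mass = rate.rates_hz["all"].sum() / 1000.0   # Hz * 1 ms bins
        assert mass == pytest.approx(4.0, rel=0.01)

    def test_bad_kernel_rejected(self):
        with pytest.raises(ConfigError):
            firing_rate(np.empty(0), [make_trial(0)], {0: 0.0},
                        kernel_sd_ms=0.0)


class TestSpatialPreference:
    @staticmethod
    def _rates(mod):
        tr = make_trial(0)
        t = np.arange(0.0, 3500.0)
        pos_left = -((-1.0) ** np.floor(t / 500.0))
        return RateSeries(
            unit_id=0, time_ms=t,
            rates_hz={"left": 10.0 + mod * pos_left,
                      "right": 10.0 - mod * pos_left},
            kernel_sd_ms=25.0), tr

    def test_right_modulated_rate(self):
        rate, tr = self._rates(0.5)
        res = spatial_preference(rate, tr)
        assert res["preference"] == "right"
        assert abs(res["peak_lag_ms"]) <= 5.0

    def test_sign_flip_gives_left(self):
        rate, tr = self._rates(-0.5)
        assert spatial_preference(rate, tr)["preference"] == "left"

    def test_flat_rate_flagged(self):
        rate, tr = self._rates(0.0)
        res = spatial_preference(rate, tr)
        assert res["preference"] == "none" and res["flat"]


class TestDetrend:
    def test_identical_conditions_vanish(self):
        t = np.arange(100.0)
        rs = RateSeries(0, t, {"a": np.sin(t / 9.0), "b": np.sin(t / 9.0)},
                        25.0)
        det = detrend_rates(rs)
        assert np.allclose(det.rates_hz["a"], 0.0)

    def test_symmetric_construction(self):
        t = np.arange(200.0)
        s = np.sin(2 * np.pi * t / 50.0)
        rs = RateSeries(0, t, {"pref": 10.0 + s, "nonpref": 10.0 - s}, 25.0)
        det = detrend_rates(rs)
        assert np.allclose(det.rates_hz["pref"], s, atol=1e-12)
        assert np.allclose(det.rates_hz["nonpref"], -s, atol=1e-12)
        total = sum(det.rates_hz.values())
        assert np.allclose(total, 0.0, atol=1e-12)


class TestCrossCorrLag:
    def test_delayed_error_gives_negative_lag(self, rng):
        t = np.arange(3000.0)
        base = np.sin(2 * np.pi * t / 500.0) * np.exp(-t / 5000.0)
        correct = base
        error = np.roll(base, 60)      # error delayed by 60 ms
        res = rate_crosscorr_lag(correct, error, 250)
        assert res["peak_lag_ms"] == pytest.approx(-60.0, abs=2.0)

    def test_identity_zero_lag_unit_peak(self, rng):
        x = rng.standard_normal(1000)
        res = rate_crosscorr_lag(x, x, 100)
        assert res["peak_lag_ms"] == 0.0
        assert res["peak_value"] == pytest.approx(1.0)

    def test_short_series_rejected(self):
        with pytest.raises(InputError):
            rate_crosscorr_lag(np.ones(50), np.ones(50), 100)


class TestSTA:
    def test_matches_brute_force_snippet_mean(self, rng):
        lfp = rng.standard_normal(20000)
        spikes = rng.uniform(200.0, 19800.0, 300)
        sta = spike_triggered_average(spikes, lfp, halfwidth_ms=100.0)
        centers = np.round(spikes).astype(int)
        ref = np.mean([lfp[c - 100:c + 101] for c in centers], axis=0)
        assert np.allclose(sta.raw_waveform, ref)

    def test_locked_spikes_dominant_gamma(self):
        t = np.arange(60000) / 1000.0
        lfp = np.sin(2 * np.pi * 35.0 * t)
        peaks = np.arange(250.0, 59000.0, 1000.0 / 35.0)
        sta = spike_triggered_average(peaks + 250.0 / 35.0, lfp)
        assert sta.band_power["gamma"] > 5 * sta.band_power["alpha"]
        assert sta.band_power["gamma"] > 5 * sta.band_power["beta"]

    def test_incoherent_spikes_flatten_with_n(self, rng):
        t = np.arange(200000) / 1000.0
        lfp = np.sin(2 * np.pi * 35.0 * t)
        amp = []
        for n in (200, 5000):
            spikes = rng.uniform(200.0, 199800.0, n)
            sta = spike_triggered_average(spikes, lfp)
            amp.append(np.ptp(sta.raw_waveform))
        assert amp[1] < amp[0] / 2.0

    def test_normalization_bounds_exact(self, rng):
        sta = spike_triggered_average(rng.uniform(200, 9800, 100),
                                      rng.standard_normal(10000))
        assert sta.waveform.min() == 0.0
        assert sta.waveform.max() == 1.0

    def test_zero_jitter_is_identity(self, rng):
        lfp = rng.standard_normal(20000)
        spikes = rng.uniform(200.0, 19800.0, 500)
        a = spike_triggered_average(spikes, lfp)
        b = sta_jitter_control(spikes, lfp, jitter_halfwidth_ms=0.0)
        assert np.allclose(a.waveform, b.waveform)

    def test_jitter_seeds_within_resampling_spread(self, rng):
        t = np.arange(100000) / 1000.0
        lfp = np.sin(2 * np.pi * 35.0 * t) + 0.5 * rng.standard_normal(
            t.size)
        spikes = np.arange(250.0, 99000.0, 1000.0 / 35.0)
        g = [sta_jitter_control(spikes, lfp, jitter_halfwidth_ms=15.0,
                                seed=s).band_power["gamma"]
             for s in (1, 2, 3, 4)]
        assert np.std(g) < np.mean(g)   # stochastically stable


class TestSwitchVsNonswitch:
    @staticmethod
    def _session(rng, locked_at_switch=True, n_trials=20, n_units=6):
        from metronome.session import SessionData
        trials = [make_trial(i) for i in range(n_trials)]
        span = 4500.0
        onsets = {i: 500.0 + span * i for i in range(n_trials)}
        n = int(span * n_trials + 1000)
        t = np.arange(n) / 1000.0
        # noise matters: peak-to-valley normalization compares STA *shape*,
        # so the nonswitch STA must be noise-dominated, not a rescaled sine
        lfp = (np.sin(2 * np.pi * 35.0 * t)
               + rng.standard_normal(n))[None, :]
        period = 1000.0 / 35.0
        units = []
        for u in range(n_units):
            spikes = []
            for tr in trials:
                on = onsets[tr.trial_id]
                for sw in tr.switch_times_ms:
                    if sw >= tr.go_cue_ms:
                        continue
                    lo, hi = on + sw - 125.0, on + sw + 125.0
                    if locked_at_switch:   # spikes on field peaks
                        k = np.arange(np.ceil(lo / period) * period, hi,
                                      period)
                        spikes.extend(k + period / 4.0)
                    else:
                        spikes.extend(rng.uniform(lo, hi, 8))
                    mid_lo = lo - 250.0
                    spikes.extend(rng.uniform(mid_lo, mid_lo + 250.0, 8))
            units.append(np.sort(np.array(spikes)))
        session = SessionData(trials=trials, lfp=lfp.astype(np.float32),
                              sampling_rate_hz=1000.0, spike_trains=units,
                              electrode_xy=np.zeros((1, 2)),
                              trial_onsets_ms=onsets)
        return session

    def test_switch_locking_detected_and_abolished_by_jitter(self, rng):
        from metronome.spikefield import sta_switch_vs_nonswitch
        session = self._session(rng, locked_at_switch=True)
        res = sta_switch_vs_nonswitch(session.spike_trains, session)
        assert res["t"] > 0 and res["p"] < 0.01
        assert res["p_jittered"] > res["p"]

    def test_uniform_locking_gives_no_difference(self, rng):
        from metronome.spikefield import sta_switch_vs_nonswitch
        session = self._session(rng, locked_at_switch=False)
        res = sta_switch_vs_nonswitch(session.spike_trains, session)
        assert res["p"] > 0.01


class TestBandANOVA:
    @staticmethod
    def _frame(rng, gamma_boost=0.0, n_units=25):
        rows = []
        for u in range(n_units):
            for cond in ("baseline", "entrainment", "maintenance"):
                for band in ("alpha", "beta", "gamma"):
                    x = rng.normal()
                    if band == "gamma" and cond == "maintenance":
                        x += gamma_boost
                    rows.append({"unit": u, "condition": cond,
                                 "band": band, "power": x})
        return pd.DataFrame(rows)

    def test_interaction_detected_when_present(self, rng):
        res = sta_band_anova(self._frame(rng, gamma_boost=2.0))
        assert res["interaction_p"] < 0.001
        posthoc = res["gamma_posthoc"].set_index("pair")
        assert posthoc.loc["maintenance vs baseline", "p_bonferroni"] < 0.01

    def test_single_unit_rejected(self, rng):
        df = self._frame(rng, n_units=1)
        with pytest.raises(InputError):
            sta_band_anova(df)

    def test_missing_cells_rejected(self, rng):
        df = self._frame(rng)
        df = df[~((df.condition == "baseline") & (df.band == "alpha"))]
        with pytest.raises(InputError):
            sta_band_anova(df)
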