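"""Synthetic replication studies.

Each function generates its own data with the package's default study
conditions, runs the relevant analysis path end to end, and returns the
measured quantities.  They back both the acceptance checks and the
worked examples; problem sizes are chosen so each study runs in minutes
on one core (the methods note lists them).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import bursts as bursts_mod
from . import spectral
from .behavior import fit_scalar_model, pcorrect_scalar, rt_regression
from .config import AnalysisConfig, TaskConfig
from .decode import bin_gamma, classifier_accuracy_curves
from .session import SessionData
from .spikefield import (alternation_components, rate_crosscorr_lag,
                         spike_triggered_average, sta_band_anova,
                         sta_jitter_control)
from .synth import (BurstGenParams, ScalarTimingParams, default_units,
                    make_trials, simulate_behavior, synth_lfp, synth_spikes)


def _spawn(seed: int, k: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, k)]


def fixed_maintenance_session(tempo_ms: float, clock_gain: float, seed: int,
                              n_rep: int = 24, n_units: int = 6,
                              with_spikes: bool = True
                              ) -> tuple[SessionData, list]:
    """Single-tempo session with every go-cue in the 4th maintenance
    interval (equal-length trials, the decoding/periodogram condition)."""
    s1, s2, s3, s4 = _spawn(seed, 4)
    task = TaskConfig(tempos_ms=(tempo_ms,))
    trials = [t for t in make_trials(task, n_rep, s1) if t.n_maintenance == 4]
    for i, t in enumerate(trials):
        t.trial_id = i
    simulate_behavior(trials, ScalarTimingParams(clock_gain=clock_gain), s2)
    xy = np.zeros((1, 2))
    lfp, onsets, _ = synth_lfp(trials, BurstGenParams(), xy, 300.0, s3)
    session = SessionData(trials=trials, lfp=lfp, sampling_rate_hz=1000.0,
                          spike_trains=[], electrode_xy=xy,
                          trial_onsets_ms=onsets)
    units = default_units(n_units, s4, n_channels=1)
    if with_spikes:
        session.spike_trains = synth_spikes(session, units, s4)
    return session, units


# ---------------------------------------------------------------------------


def tempo_recovery_study(seed: int = 0, n_per_cell: int = 40,
                         method: str = "bandpass-analytic") -> dict:
    """Median inter-burst onset interval per tempo on a default session."""
    from .synth import simulate_session
    session, _ = simulate_session(task=TaskConfig(), n_per_cell=n_per_cell,
                                  seed=seed, with_spikes=False)
    envs = spectral.trial_envelopes(session, channel=0, method=method)
    events = bursts_mod.detect_session_bursts(envs, session.trials)
    ibis = bursts_mod.interburst_intervals(events)
    return {f"{int(T)}": float(np.median(v)) for T, v in sorted(ibis.items())}


def envelope_centroids(session: SessionData, tempo_ms: float) -> dict:
    """Rhythm-band periodogram centroid of correct vs error envelopes."""
    envs = spectral.trial_envelopes(session, channel=0,
                                    method="bandpass-analytic")
    by_id = {t.trial_id: t for t in session.trials}
    groups: dict = {True: [], False: []}
    for e in envs:
        groups[by_id[e.trial_id].correct].append(e)
    f0 = 1000.0 / tempo_ms
    out = {}
    for key, envs_k in groups.items():
        f, p = spectral.envelope_periodogram(envs_k,
                                             (3 * tempo_ms, 7 * tempo_ms))
        sel = (f >= 0.5 * f0) & (f <= 1.5 * f0)
        out["correct" if key else "error"] = float(
            np.sum(f[sel] * p[sel]) / np.sum(p[sel]))
    return out


def clock_bias_study(tempo_ms: float, clock_gain: float, n_sessions: int,
                     seed: int = 0, n_rep: int = 24) -> dict:
    """Both neural error signatures over repeated sessions.

    Returns the number of sessions in which (a) the error-trial envelope
    periodogram centroid falls on the biased side of the correct-trial
    one, and (b) the correct-vs-error rate cross-correlogram peak lag has
    the sign of the clock bias (negative = lagging).
    """
    want = -1 if clock_gain > 1 else +1
    seeds = _spawn(seed, n_sessions)
    n_centroid = n_lag = 0
    lags, cent_diffs = [], []
    for s in seeds:
        session, units = fixed_maintenance_session(tempo_ms, clock_gain, s,
                                                   n_rep=n_rep)
        cents = envelope_centroids(session, tempo_ms)
        d = cents["error"] - cents["correct"]
        cent_diffs.append(d)
        n_centroid += int(np.sign(d) == want)
        comp = alternation_components(
            session.spike_trains, [u.preferred_side for u in units],
            session, (3 * tempo_ms, 7 * tempo_ms))
        lag = rate_crosscorr_lag(comp["correct"], comp["error"],
                                 int(tempo_ms))["peak_lag_ms"]
        lags.append(lag)
        n_lag += int(np.sign(lag) == want)
    return {"n_sessions": n_sessions, "centroid_correct_sign": n_centroid,
            "lag_correct_sign": n_lag,
            "median_lag_ms": float(np.median(lags)),
            "mean_centroid_diff_hz": float(np.mean(cent_diffs))}


def decoder_study(seed: int = 0, tempo_ms: float = 500.0,
                  clock_gain: float = 1.15, n_rep: int = 200,
                  n_iter: int = 100) -> dict:
    """Cumulative and sliding decoding curves on drifting-clock data."""
    session, _ = fixed_maintenance_session(tempo_ms, clock_gain, seed,
                                           n_rep=n_rep, with_spikes=False)
    envs = spectral.trial_envelopes(session, channel=0,
                                    method="bandpass-analytic")
    fm = bin_gamma(envs, session.trials, 10)
    out = {"n_trials": int(fm.labels.size),
           "n_errors": int((fm.labels == 0).sum())}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for scheme in ("cumulative", "sliding"):
            res = classifier_accuracy_curves(fm, scheme, 50, n_iter, seed)
            out[scheme] = res
    return out


def jitter_attenuation_study(seed: int = 0, n_spikes: int = 10_000,
                             carrier_hz: float = 35.0,
                             jitter_halfwidth_ms: float = 15.0,
                             n_repeats: int = 10) -> dict:
    """Measured vs predicted STA attenuation under uniform spike jitter.

    Spikes perfectly locked to a pure carrier; the jitter multiplies the
    expected STA amplitude at the carrier by |sinc(2 f h)|.
    """
    fs = 1000.0
    period_ms = 1000.0 / carrier_hz
    dur_ms = (n_spikes + 20) * period_ms
    t = np.arange(int(dur_ms * fs / 1000.0)) / fs
    field = np.sin(2 * np.pi * carrier_hz * t)
    spikes = (np.arange(n_spikes) + 10) * period_ms + 0.25 * period_ms
    sta = spike_triggered_average(spikes, field, fs)
    jit = sta_jitter_control(spikes, field, fs,
                             jitter_halfwidth_ms=jitter_halfwidth_ms,
                             n_repeats=n_repeats, seed=seed)
    measured = jit.amplitude_at(carrier_hz) / sta.amplitude_at(carrier_hz)
    predicted = float(abs(np.sinc(2 * carrier_hz
                                  * jitter_halfwidth_ms / 1000.0)))
    return {"measured_attenuation": float(measured),
            "predicted_attenuation": predicted,
            "n_spikes": n_spikes}


def plv_null_study(seed: int = 0, n_samples: int = 4000,
                   n_draws: int = 300) -> dict:
    """PLV of independent channels against the Rayleigh 3/sqrt(n) bound."""
    from .coherence import pairwise_plv
    rng = np.random.default_rng(seed)
    draws = [pairwise_plv(rng.uniform(-np.pi, np.pi, n_samples),
                          rng.uniform(-np.pi, np.pi, n_samples))
             for _ in range(n_draws)]
    ph = rng.uniform(-np.pi, np.pi, n_samples)
    return {"identical_plv": pairwise_plv(ph, ph),
            "frac_below_bound": float(np.mean(
                np.array(draws) < 3.0 / np.sqrt(n_samples))),
            "mean_null_plv": float(np.mean(draws)), "n": n_samples}


def scalar_consistency_study(seed: int = 0, n_per_cell: int = 100_000,
                             weber: float = 0.15, lapse: float = 0.02
                             ) -> dict:
    """Closed-form p(correct) vs the Monte-Carlo agent on the 12-cell
    tempo x go-cue grid; reports the worst z-score."""
    params = ScalarTimingParams(weber_fraction=weber, lapse=lapse)
    seeds = _spawn(seed, 12)
    worst = 0.0
    cells = []
    i = 0
    for T in (0.5, 0.75, 1.0):
        for n_m in (1, 2, 3, 4):
            t_go = (n_m - 0.5) * T
            p_an = pcorrect_scalar(t_go, T, params)
            task = TaskConfig(tempos_ms=(T * 1000.0,), max_maintenance=4)
            trials = [t for t in make_trials(task, n_per_cell // 2,
                                             seeds[i])
                      if t.n_maintenance == n_m]
            simulate_behavior(trials, params, seeds[i])
            i += 1
            pc = float(np.mean([t.correct for t in trials]))
            se = np.sqrt(p_an * (1 - p_an) / len(trials))
            z = abs(pc - p_an) / se
            worst = max(worst, z)
            cells.append({"tempo_s": T, "t_go_s": t_go, "analytic": p_an,
                          "monte_carlo": pc, "z": float(z),
                          "n": len(trials)})
    return {"worst_z": float(worst), "cells": cells}


def weber_recovery_study(seed: int = 0, n_replicates: int = 100,
                         n_trials: int = 5000, weber: float = 0.12,
                         lapse: float = 0.02) -> dict:
    """Coverage of the 95% profile CI for the Weber fraction."""
    truth = ScalarTimingParams(weber_fraction=weber, lapse=lapse)
    seeds = _spawn(seed, 2 * n_replicates)
    covered = 0
    estimates = []
    per_cell = int(np.ceil(n_trials / 24))
    for r in range(n_replicates):
        trials = make_trials(TaskConfig(), per_cell, seeds[2 * r])[:n_trials]
        simulate_behavior(trials, truth, seeds[2 * r + 1])
        fit = fit_scalar_model(trials)
        lo, hi = fit["w_ci"]
        covered += int(lo <= weber <= hi)
        estimates.append(fit["weber_fraction"])
    return {"n_replicates": n_replicates, "covered": covered,
            "mean_estimate": float(np.mean(estimates)), "true_w": weber}


def rt_slope_study(seed: int = 0, n_sessions: int = 131,
                   n_per_cell: int = 10) -> dict:
    """RT-vs-elapsed-time regression on pooled synthetic sessions."""
    truth = ScalarTimingParams()
    seeds = _spawn(seed, 2 * n_sessions)
    rt, el = [], []
    for s in range(n_sessions):
        trials = make_trials(TaskConfig(), n_per_cell, seeds[2 * s])
        simulate_behavior(trials, truth, seeds[2 * s + 1])
        rt.extend(t.rt_ms for t in trials)
        el.extend(t.t_go_ms / 1000.0 for t in trials)
    return rt_regression(np.array(rt), np.array(el))


def calibration_study(seed: int = 0, n_sims: int = 200) -> dict:
    """False-positive rates of the three null-calibrated tests at
    alpha = 0.05: per-bin permutation test, burst-onset chi-squared
    homogeneity, and the condition x band ANOVA interaction."""
    import pandas as pd
    rng = np.random.default_rng(seed)

    # permutation test: task and baseline bins share one distribution
    hits = total = 0
    for sim in range(max(n_sims // 10, 20)):   # many bins per simulation
        time_ms = np.arange(40) * 25.0 - 500.0
        freq = np.array([30.0, 35.0, 40.0])
        specs = [spectral.Spectrogram(
            power=rng.exponential(1.0, (40, 3)), time_ms=time_ms,
            freq_hz=freq, window_ms=200, step_ms=25, n_tapers=1,
            bandwidth_hz=5) for _ in range(20)]
        p, _, _ = spectral.permutation_test_bins(
            specs, (-500.0, 0.0), 1000, int(rng.integers(2 ** 31)))
        hits += int((p < 0.05).sum())
        total += p.size
    fpr_perm = hits / total

    # chi-squared onset homogeneity on identical phase distributions
    chi_hits = 0
    for sim in range(n_sims):
        evs = []
        for grp in (0, 1):
            for x in rng.beta(2.0, 3.0, 200):
                evs.append(bursts_mod.BurstEvent(
                    trial_id=0, onset_ms=x * 500.0 + grp * 10_000.0,
                    offset_ms=0.0, duration_ms=100.0, peak_amp=1.0,
                    mean_amp=1.0, interval_index=grp, tempo_ms=500.0))
        out = bursts_mod.onset_distribution_chi2(evs, "interval-index")
        chi_hits += int(out["p"].iloc[0] < 0.05)

    # ANOVA interaction on iid cell data
    anova_hits = 0
    for sim in range(n_sims):
        rows = [{"unit": u, "condition": c, "band": b,
                 "power": rng.normal()}
                for u in range(20)
                for c in ("baseline", "entrainment", "maintenance")
                for b in ("alpha", "beta", "gamma")]
        res = sta_band_anova(pd.DataFrame(rows))
        anova_hits += int(res["interaction_p"] < 0.05)

    return {"permutation_fpr": float(fpr_perm),
            "chi2_fpr": chi_hits / n_sims,
            "anova_fpr": anova_hits / n_sims, "n_sims": n_sims}


def growth_fit_study(seed: int = 0, n_per_cell: int = 30) -> dict:
    """Burst-amplitude growth fits on a default synthetic session:
    linear over entrainment, exponential over the whole trial (interval
    means, as in the published growth curves)."""
    from .synth import simulate_session
    session, _ = simulate_session(task=TaskConfig(), n_per_cell=n_per_cell,
                                  seed=seed, with_spikes=False)
    envs = spectral.trial_envelopes(session, channel=0,
                                    method="bandpass-analytic")
    events = bursts_mod.detect_session_bursts(envs, session.trials)
    ent = [b for b in events if b.epoch == "entrainment"]
    full = [b for b in events if b.epoch in ("entrainment", "maintenance")]
    lin = bursts_mod.fit_amplitude_growth(ent, "linear",
                                          aggregate="interval-mean")
    expo = bursts_mod.fit_amplitude_growth(full, "exponential",
                                           aggregate="interval-mean")
    return {"entrainment_linear_r2": lin["r2"],
            "full_exponential_r2": expo["r2"],
            "n_bursts": len(full)}


def sta_anova_study(seed: int = 0, tempo_ms: float = 500.0,
                    n_rep: int = 20, n_units: int = 30) -> dict:
    """Condition x band ANOVA of STA band power on one synthetic session."""
    import pandas as pd
    from .spikefield import spikes_by_epoch
    session, units = fixed_maintenance_session(tempo_ms, 1.0, seed,
                                               n_rep=n_rep, n_units=n_units)
    cfg = AnalysisConfig()
    rows = []
    lfp = session.lfp[0].astype(float)
    for k, spikes in enumerate(session.spike_trains):
        parts = spikes_by_epoch(spikes, session.trials,
                                session.trial_onsets_ms)
        for epoch, sp in parts.items():
            if sp.size < 25:
                continue
            sta = spike_triggered_average(sp, lfp, cfg=cfg, epoch=epoch,
                                          unit_id=k)
            for band, power in sta.band_power.items():
                rows.append({"unit": k, "condition": epoch, "band": band,
                             "power": power})
    res = sta_band_anova(pd.DataFrame(rows))
    return {"interaction_F": res["interaction_F"],
            "interaction_p": res["interaction_p"], "n_units": n_units}


def coherence_distance_study(seed: int = 0, n_sessions: int = 8,
                             n_channels: int = 12,
                             extent_um: float = 900.0,
                             n_per_cell: int = 4) -> dict:
    """PLV vs electrode distance, pairs pooled over repeated sessions
    with distinct random array geometries (the published regression
    pools pairs across recording sessions)."""
    from .coherence import coherence_vs_distance, session_coherence_pairs
    from .synth import electrode_grid_random, simulate_session
    pairs = []
    for s in _spawn(seed, n_sessions):
        xy = electrode_grid_random(n_channels, extent_um, s)
        session, _ = simulate_session(task=TaskConfig(tempos_ms=(500.0,)),
                                      n_per_cell=n_per_cell,
                                      electrode_xy=xy,
                                      mixing_length_um=300.0, seed=s,
                                      with_spikes=False)
        pairs.extend(session_coherence_pairs(session))
    fit = coherence_vs_distance(pairs, min(50, len(pairs)))
    rho, p = stats.spearmanr([q.distance_um for q in pairs],
                             [q.plv for q in pairs])
    return {"slope_per_um": fit["slope_per_um"], "r2": fit["r2"],
            "spearman_rho": float(rho), "spearman_p": float(p),
            "n_pairs": len(pairs)}
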