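"""Firing-rate analyses and spike-triggered-average (STA) spike-field
coupling.

Rates are Gaussian-kernel-smoothed (sd 25 ms) trial-aligned spike trains
averaged per condition.  A unit's spatial preference comes from the sign
of the peak of the cross-correlogram between its mean rate and the +/-1
stimulus-position signal.  The STA averages 200 ms LFP snippets centered
on each spike, is normalized peak-to-valley to [0, 1] *before* spectral
decomposition, and its alpha (6-10), beta (15-24) and gamma (30-40 Hz)
band powers feed a condition x band factorial ANOVA.  A +/-15 ms uniform
spike-time jitter — which spans more than one gamma cycle — serves as the
control: it multiplies the expected STA amplitude at frequency ``f`` by
``|sinc(2 f h)|``, wiping out the gamma peak while leaving slow bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import periodogram

import statsmodels.api as sm
from statsmodels.formula.api import ols

from .config import AnalysisConfig, ConfigError
from .session import SessionData, TrialRecord
from .spectral import InputError


@dataclass
class RateSeries:
    unit_id: int | None
    time_ms: np.ndarray
    rates_hz: dict[str, np.ndarray]     # condition -> mean rate
    kernel_sd_ms: float
    n_trials: dict[str, int] | None = None


@dataclass
class STAResult:
    unit_id: int | None
    epoch: str
    waveform: np.ndarray                # normalized to [0, 1] peak-to-valley
    lags_ms: np.ndarray
    freq_hz: np.ndarray
    power: np.ndarray
    band_power: dict[str, float]
    n_spikes: int
    low_n: bool = False
    raw_waveform: np.ndarray | None = None  # plain snippet mean (microvolts)

    def amplitude_at(self, f_hz: float, fs: float = 1000.0) -> float:
        """Amplitude of the raw STA at one frequency (direct projection)."""
        w = self.raw_waveform - self.raw_waveform.mean()
        t = np.arange(w.size) / fs
        phasor = np.exp(-2j * np.pi * f_hz * t)
        return float(2.0 * np.abs(np.sum(w * phasor)) / w.size)


# ---------------------------------------------------------------------------
# firing rates


def _smoothed_rate(spikes_ms: np.ndarray, t0: float, t1: float,
                   kernel_sd_ms: float) -> np.ndarray:
    """Kernel rate on a 1 ms grid over [t0, t1) from one trial's spikes."""
    n = int(round(t1 - t0))
    counts = np.zeros(n)
    idx = np.floor(spikes_ms - t0).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(counts, idx, 1.0)
    half = int(np.ceil(4 * kernel_sd_ms))
    k = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (k / kernel_sd_ms) ** 2)
    kernel /= kernel.sum()
    return np.convolve(counts, kernel, mode="same") * 1000.0  # Hz


def firing_rate(spikes_ms: np.ndarray, trials: list[TrialRecord],
                trial_onsets_ms: dict[int, float],
                condition_of=lambda tr: "all",
                window_ms: tuple[float, float] | None = None,
                kernel_sd_ms: float = 25.0) -> RateSeries:
    """Trial-aligned, kernel-smoothed mean rate per condition.

    ``condition_of`` maps a trial to its condition label (e.g. start side
    or correctness); trials mapping to None are skipped.  The window
    defaults to trial onset .. shortest maintenance offset.
    """
    if kernel_sd_ms <= 0:
        raise ConfigError("kernel_sd_ms must be positive")
    if window_ms is None:
        window_ms = (0.0, min(tr.epoch_bounds["maintenance"][1]
                              for tr in trials))
    per_cond: dict[str, list[np.ndarray]] = {}
    for tr in trials:
        cond = condition_of(tr)
        if cond is None:
            continue
        onset = trial_onsets_ms[tr.trial_id]
        rel = spikes_ms - onset
        rate = _smoothed_rate(rel, window_ms[0], window_ms[1], kernel_sd_ms)
        per_cond.setdefault(cond, []).append(rate)
    if not per_cond:
        raise InputError("no trials matched any condition")
    time = np.arange(window_ms[0], window_ms[1])
    return RateSeries(unit_id=None, time_ms=time,
                      rates_hz={c: np.mean(v, axis=0)
                                for c, v in per_cond.items()},
                      kernel_sd_ms=kernel_sd_ms,
                      n_trials={c: len(v) for c, v in per_cond.items()})


def _position_signal(trial_template: TrialRecord, time_ms: np.ndarray,
                     start_side: str) -> np.ndarray:
    """+1 (right) / -1 (left) stimulus position along the trial."""
    T = trial_template.tempo_ms
    start = 1.0 if start_side == "right" else -1.0
    sign = start * (-1.0) ** np.floor(np.maximum(time_ms, 0.0) / T)
    sign[time_ms < 0] = 0.0
    return sign


def spatial_preference(rate: RateSeries, trial_template: TrialRecord) -> dict:
    """Side preference from the rate x stimulus-position cross-correlogram.

    The left-start and right-start mean rates are concatenated alongside
    the matching +/-1 position signal; the sign of the peak of their
    normalized cross-correlogram gives the preference (positive = right).
    A flat rate yields ``"none"`` with a flag.
    """
    for cond in ("left", "right"):
        if cond not in rate.rates_hz:
            raise InputError(f"missing start-side condition {cond!r}")
    r = np.concatenate([rate.rates_hz["left"], rate.rates_hz["right"]])
    pos = np.concatenate([
        _position_signal(trial_template, rate.time_ms, "left"),
        _position_signal(trial_template, rate.time_ms, "right")])
    r = r - r.mean()
    pos = pos - pos.mean()
    denom = np.sqrt(np.sum(r ** 2) * np.sum(pos ** 2))
    if denom == 0:
        return {"preference": "none", "flat": True, "peak_corr": 0.0,
                "peak_lag_ms": np.nan}
    max_lag = int(trial_template.tempo_ms / 2)
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.array([np.sum(r * np.roll(pos, lag)) for lag in lags]) / denom
    i = int(np.argmax(np.abs(cc)))
    return {"preference": "right" if cc[i] > 0 else "left", "flat": False,
            "peak_corr": float(cc[i]), "peak_lag_ms": float(lags[i])}


def detrend_rates(rate: RateSeries) -> RateSeries:
    """Subtract the across-condition grand mean from each condition mean."""
    if len(rate.rates_hz) < 2:
        raise InputError("detrending needs >= 2 conditions")
    grand = np.mean(list(rate.rates_hz.values()), axis=0)
    return RateSeries(unit_id=rate.unit_id, time_ms=rate.time_ms,
                      rates_hz={c: v - grand for c, v in rate.rates_hz.items()},
                      kernel_sd_ms=rate.kernel_sd_ms, n_trials=rate.n_trials)


def rate_crosscorr_lag(correct: np.ndarray, error: np.ndarray,
                       max_lag_ms: int) -> dict:
    """Normalized cross-correlogram and its peak lag.

    Sign convention: a *negative* peak lag means the error-trial series is
    delayed (lags behind) relative to the correct-trial series.
    """
    correct = np.asarray(correct, float)
    error = np.asarray(error, float)
    if correct.size != error.size:
        raise InputError("series must have equal length")
    if correct.size <= max_lag_ms:
        raise InputError("series shorter than max_lag")
    c = correct - correct.mean()
    e = error - error.mean()
    denom = np.sqrt(np.sum(c ** 2) * np.sum(e ** 2))
    lags = np.arange(-max_lag_ms, max_lag_ms + 1)
    cc = np.empty(lags.size)
    for i, lag in enumerate(lags):
        # cc(lag) = sum_t e(t) c(t + lag): a delayed error series
        # (e(t) = c(t - d)) peaks at lag = -d, i.e. negative = lagging
        if lag >= 0:
            cc[i] = np.sum(e[:e.size - lag] * c[lag:])
        else:
            cc[i] = np.sum(e[-lag:] * c[:c.size + lag])
    cc = cc / denom if denom > 0 else cc
    i = int(np.argmax(cc))
    return {"lags_ms": lags, "cc": cc, "peak_lag_ms": float(lags[i]),
            "peak_value": float(cc[i])}


def alternation_components(spike_trains: list[np.ndarray],
                           preferred_sides: list[str],
                           session: SessionData,
                           window_ms: tuple[float, float],
                           kernel_sd_ms: float = 25.0
                           ) -> dict[str, np.ndarray]:
    """Population side-alternation rate for correct and for error trials.

    Per unit and outcome class, the mean rate over preferred-side-start
    trials minus the mean over all trials of that class — removing the
    common elapsed-time ramp while keeping the left/right alternation with
    a consistent phase across units (preferred side = phase zero).  The
    unit-averaged correct and error components are what the correct/error
    cross-correlogram compares.
    """
    acc: dict[str, list[np.ndarray]] = {"correct": [], "error": []}
    for spikes, pref in zip(spike_trains, preferred_sides):
        for outcome in ("correct", "error"):
            want = outcome == "correct"
            cls = [tr for tr in session.trials if tr.correct is want]
            if not cls or not any(tr.start_side == pref for tr in cls):
                continue
            r_all = firing_rate(spikes, cls, session.trial_onsets_ms,
                                window_ms=window_ms,
                                kernel_sd_ms=kernel_sd_ms)
            r_pref = firing_rate(
                spikes, [tr for tr in cls if tr.start_side == pref],
                session.trial_onsets_ms, window_ms=window_ms,
                kernel_sd_ms=kernel_sd_ms)
            acc[outcome].append(r_pref.rates_hz["all"]
                                - r_all.rates_hz["all"])
    if not acc["correct"] or not acc["error"]:
        raise InputError("need correct and error trials with "
                         "preferred-side starts")
    return {k: np.mean(v, axis=0) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# spike-triggered average


def _epoch_of(t_rel: float, trial: TrialRecord) -> str | None:
    for epoch in ("baseline", "entrainment", "maintenance"):
        on, off = trial.epoch_bounds[epoch]
        if on <= t_rel < off:
            # movement period (go-cue to trial end) excluded
            if epoch == "maintenance" and t_rel >= trial.go_cue_ms:
                return None
            return epoch
    return None


def spikes_by_epoch(spikes_ms: np.ndarray, trials: list[TrialRecord],
                    trial_onsets_ms: dict[int, float]
                    ) -> dict[str, np.ndarray]:
    """Partition session-clock spike times by trial epoch."""
    out = {"baseline": [], "entrainment": [], "maintenance": []}
    for tr in trials:
        onset = trial_onsets_ms[tr.trial_id]
        lo = onset + tr.epoch_bounds["baseline"][0]
        hi = onset + tr.epoch_bounds["maintenance"][1]
        sel = spikes_ms[(spikes_ms >= lo) & (spikes_ms < hi)]
        for s in sel:
            ep = _epoch_of(s - onset, tr)
            if ep is not None:
                out[ep].append(s)
    return {k: np.array(v) for k, v in out.items()}


def spike_triggered_average(spikes_ms: np.ndarray, lfp: np.ndarray,
                            fs: float = 1000.0, halfwidth_ms: float = 100.0,
                            epoch: str = "all", unit_id: int | None = None,
                            min_spikes: int = 50,
                            cfg: AnalysisConfig | None = None) -> STAResult:
    """Average LFP in ``+/-halfwidth_ms`` around each spike.

    The average is normalized peak-to-valley to [0, 1] before its power
    spectrum is taken (so band powers compare shape, not raw amplitude);
    spikes whose snippet would cross the recording edge are skipped and
    counted.  Fewer than ``min_spikes`` usable spikes flags ``low_n``.
    """
    cfg = cfg or AnalysisConfig()
    half = int(round(halfwidth_ms * fs / 1000.0))
    n = lfp.size
    centers = np.round(np.asarray(spikes_ms, float) * fs / 1000.0).astype(int)
    ok = (centers - half >= 0) & (centers + half < n)
    centers = centers[ok]
    if centers.size == 0:
        raise InputError("no usable spikes for the STA")
    idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
    waveform = lfp[idx].mean(axis=0)
    rng_pv = waveform.max() - waveform.min()
    norm = (waveform - waveform.min()) / rng_pv if rng_pv > 0 \
        else np.zeros_like(waveform)
    freq, power = periodogram(norm - norm.mean(), fs=fs, detrend=False)
    bands = {}
    for name, (lo, hi) in cfg.bands.items():
        sel = (freq >= lo) & (freq <= hi)
        bands[name] = float(power[sel].mean())
    return STAResult(unit_id=unit_id, epoch=epoch, waveform=norm,
                     lags_ms=np.arange(-half, half + 1) * 1000.0 / fs,
                     freq_hz=freq, power=power, band_power=bands,
                     n_spikes=int(centers.size),
                     low_n=centers.size < min_spikes, raw_waveform=waveform)


def sta_jitter_control(spikes_ms: np.ndarray, lfp: np.ndarray,
                       fs: float = 1000.0, halfwidth_ms: float = 100.0,
                       jitter_halfwidth_ms: float = 15.0, n_repeats: int = 1,
                       seed: int = 0, epoch: str = "all",
                       unit_id: int | None = None,
                       cfg: AnalysisConfig | None = None) -> STAResult:
    """STA after displacing each spike by Uniform(-h, +h) ms.

    The jittered snippet average is taken over ``n_repeats`` independent
    jitter draws before normalization and spectral decomposition.
    """
    rng = np.random.default_rng(seed)
    spikes_ms = np.asarray(spikes_ms, float)
    if jitter_halfwidth_ms == 0:
        return spike_triggered_average(spikes_ms, lfp, fs, halfwidth_ms,
                                       epoch, unit_id, cfg=cfg)
    half = int(round(halfwidth_ms * fs / 1000.0))
    n = lfp.size
    sums = np.zeros(2 * half + 1)
    count = 0
    for _ in range(n_repeats):
        jit = spikes_ms + rng.uniform(-jitter_halfwidth_ms,
                                      jitter_halfwidth_ms, spikes_ms.size)
        centers = np.round(jit * fs / 1000.0).astype(int)
        ok = (centers - half >= 0) & (centers + half < n)
        centers = centers[ok]
        idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
        sums += lfp[idx].sum(axis=0)
        count += centers.size
    if count == 0:
        raise InputError("no usable spikes after jitter")
    waveform = sums / count
    cfg = cfg or AnalysisConfig()
    rng_pv = waveform.max() - waveform.min()
    norm = (waveform - waveform.min()) / rng_pv if rng_pv > 0 \
        else np.zeros_like(waveform)
    freq, power = periodogram(norm - norm.mean(), fs=fs, detrend=False)
    bands = {name: float(power[(freq >= lo) & (freq <= hi)].mean())
             for name, (lo, hi) in cfg.bands.items()}
    return STAResult(unit_id=unit_id, epoch=f"{epoch}+jitter", waveform=norm,
                     lags_ms=np.arange(-half, half + 1) * 1000.0 / fs,
                     freq_hz=freq, power=power, band_power=bands,
                     n_spikes=int(count // max(n_repeats, 1)),
                     raw_waveform=waveform)


def sta_band_anova(band_powers: pd.DataFrame) -> dict:
    """Two-factor fixed-effects ANOVA of STA band power.

    ``band_powers`` needs columns ``unit``, ``condition`` (baseline /
    entrainment / maintenance), ``band`` (alpha / beta / gamma) and
    ``power``; units are the replicates.  Returns the interaction F and p
    plus Bonferroni-corrected paired comparisons of gamma power across
    conditions.
    """
    required = {"unit", "condition", "band", "power"}
    if not required <= set(band_powers.columns):
        raise InputError(f"band_powers needs columns {sorted(required)}")
    n_units = band_powers["unit"].nunique()
    if n_units < 2:
        raise InputError("ANOVA needs >= 2 units")
    counts = band_powers.groupby(["condition", "band"])["power"].count()
    if len(counts) < 9 or counts.min() < 1:
        raise InputError("all 9 condition x band cells must be populated")
    model = ols("power ~ C(condition) * C(band)", data=band_powers).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = table.loc["C(condition):C(band)"]
    gamma = band_powers[band_powers["band"] == "gamma"].pivot_table(
        index="unit", columns="condition", values="power")
    pairs = [("entrainment", "baseline"), ("maintenance", "baseline"),
             ("maintenance", "entrainment")]
    posthoc = []
    for a, b in pairs:
        t, p = stats.ttest_rel(gamma[a], gamma[b])
        posthoc.append({"pair": f"{a} vs {b}", "t": float(t),
                        "p": float(p),
                        "p_bonferroni": float(min(p * len(pairs), 1.0))})
    return {"interaction_F": float(inter["F"]),
            "interaction_p": float(inter["PR(>F)"]),
            "anova_table": table, "gamma_posthoc": pd.DataFrame(posthoc)}


def sta_switch_vs_nonswitch(spike_trains: list[np.ndarray],
                            session: SessionData, channel_of=None,
                            halfwidth_ms: float = 100.0,
                            jitter_halfwidth_ms: float = 15.0,
                            seed: int = 0,
                            cfg: AnalysisConfig | None = None) -> dict:
    """Paired comparison of STA gamma power at switch vs mid-interval.

    Spikes are partitioned into windows of half the interval length
    centered at the switch times vs centered mid-interval; per unit the
    STA gamma power is computed for each partition and compared with a
    paired t-test across units.  The same comparison on +/-15 ms jittered
    spikes is reported alongside.
    """
    cfg = cfg or AnalysisConfig()
    fs = session.sampling_rate_hz
    rows = []
    excluded = 0
    for k, spikes in enumerate(spike_trains):
        ch = channel_of(k) if channel_of else 0
        lfp = session.lfp[ch].astype(float)
        sw_spikes, mid_spikes = [], []
        for tr in session.trials:
            onset = session.trial_onsets_ms[tr.trial_id]
            T = tr.tempo_ms
            quarter = T / 4.0
            rel = spikes - onset
            for sw in tr.switch_times_ms:
                if sw >= tr.go_cue_ms:
                    continue
                sw_spikes.append(
                    spikes[(rel >= sw - quarter) & (rel < sw + quarter)])
                mid = sw - T / 2.0
                mid_spikes.append(
                    spikes[(rel >= mid - quarter) & (rel < mid + quarter)])
        sw_all = np.concatenate(sw_spikes) if sw_spikes else np.empty(0)
        mid_all = np.concatenate(mid_spikes) if mid_spikes else np.empty(0)
        if sw_all.size < 10 or mid_all.size < 10:
            excluded += 1
            continue
        row = {"unit": k}
        for label, sp in (("switch", sw_all), ("nonswitch", mid_all)):
            sta = spike_triggered_average(sp, lfp, fs, halfwidth_ms, cfg=cfg)
            jit = sta_jitter_control(sp, lfp, fs, halfwidth_ms,
                                     jitter_halfwidth_ms, seed=seed + k,
                                     cfg=cfg)
            row[f"gamma_{label}"] = sta.band_power["gamma"]
            row[f"gamma_{label}_jittered"] = jit.band_power["gamma"]
        rows.append(row)
    if len(rows) < 2:
        raise InputError("need >= 2 units with both partitions populated")
    df = pd.DataFrame(rows)
    t, p = stats.ttest_rel(df["gamma_switch"], df["gamma_nonswitch"])
    tj, pj = stats.ttest_rel(df["gamma_switch_jittered"],
                             df["gamma_nonswitch_jittered"])
    return {"t": float(t), "p": float(p), "t_jittered": float(tj),
            "p_jittered": float(pj), "per_unit": df,
            "n_units": len(rows), "excluded_units": excluded}
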