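"""Gamma-burst detection and burst-timing / burst-amplitude statistics.

A burst is a maximal run of envelope samples strictly above the 90th
percentile of the pooled amplitude distribution, lasting at least 100 ms
(four gamma cycles).  Sub-threshold dips split bursts — threshold plus
duration is the whole definition (a merge-gap parameter exists but
defaults to 0).  Percentiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError
from .session import TrialRecord
from .spectral import GammaEnvelope, InputError


@dataclass
class BurstThreshold:
    value: float
    percentile: float
    pooling_scope: str


@dataclass
class BurstEvent:
    trial_id: int | None
    onset_ms: float
    offset_ms: float
    duration_ms: float
    peak_amp: float
    mean_amp: float
    interval_index: int | None = None   # which interval holds the onset
    epoch: str | None = None            # baseline | entrainment | maintenance
    tempo_ms: float | None = None


def burst_threshold(envelopes: list[GammaEnvelope], percentile: float = 90.0,
                    scope: str = "session-tempo, whole trials",
                    window: tuple[float, float] | None = None
                    ) -> BurstThreshold:
    """Percentile of the pooled envelope distribution.

    ``window`` optionally restricts pooling to a trial-relative time range
    (e.g. maintenance only); the scope string labels the pooling rule in
    the output.
    """
    pool = []
    for env in envelopes:
        amp = env.amplitude
        if window is not None:
            rows = (env.time_ms >= window[0]) & (env.time_ms < window[1])
            amp = amp[rows]
        pool.append(amp)
    pooled = np.concatenate(pool) if pool else np.empty(0)
    if pooled.size == 0:
        raise InputError("empty amplitude pool")
    return BurstThreshold(value=float(np.percentile(pooled, percentile)),
                          percentile=percentile, pooling_scope=scope)


def _assign(ev: BurstEvent, trial: TrialRecord) -> BurstEvent:
    T = trial.tempo_ms
    ev.tempo_ms = T
    ev.interval_index = int(np.floor(ev.onset_ms / T)) if ev.onset_ms >= 0 \
        else -1
    ent_on, ent_off = trial.epoch_bounds["entrainment"]
    if ev.onset_ms < ent_on:
        ev.epoch = "baseline"
    elif ev.onset_ms < ent_off:
        ev.epoch = "entrainment"
    else:
        ev.epoch = "maintenance"
    return ev


def detect_bursts(envelope: GammaEnvelope, thr: BurstThreshold,
                  min_dur_ms: float = 100.0, merge_gap_ms: float = 0.0,
                  trial: TrialRecord | None = None) -> list[BurstEvent]:
    """Maximal supra-threshold runs of duration >= ``min_dur_ms``.

    Onset is the time of the first supra-threshold sample; duration is the
    run length times the envelope step.  Runs separated by sub-threshold
    gaps shorter than ``merge_gap_ms`` are merged (default: no merging).
    """
    dt = envelope.step_ms
    if min_dur_ms < 2 * dt:
        raise ConfigError("min_dur_ms must cover at least 2 envelope samples")
    above = envelope.amplitude > thr.value
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    if merge_gap_ms > 0 and starts.size > 1:
        gaps = (starts[1:] - ends[:-1]) * dt
        keep = gaps >= merge_gap_ms
        starts = np.concatenate([[starts[0]], starts[1:][keep]])
        ends = np.concatenate([ends[:-1][keep], [ends[-1]]])
    out = []
    tid = envelope.trial_id if trial is None else trial.trial_id
    for s, e in zip(starts, ends):
        dur = (e - s) * dt
        if dur < min_dur_ms:
            continue
        amp = envelope.amplitude[s:e]
        ev = BurstEvent(trial_id=tid,
                        onset_ms=float(envelope.time_ms[s]),
                        offset_ms=float(envelope.time_ms[s] + dur),
                        duration_ms=float(dur),
                        peak_amp=float(amp.max()),
                        mean_amp=float(amp.mean()))
        if trial is not None:
            _assign(ev, trial)
        out.append(ev)
    return out


def detect_session_bursts(envelopes: list[GammaEnvelope],
                          trials: list[TrialRecord],
                          percentile: float = 90.0, min_dur_ms: float = 100.0,
                          per_tempo: bool = True) -> list[BurstEvent]:
    """Detect bursts across a session, thresholding per tempo by default."""
    by_id = {tr.trial_id: tr for tr in trials}
    groups: dict = {}
    for env in envelopes:
        tr = by_id[env.trial_id]
        key = tr.tempo_ms if per_tempo else "all"
        groups.setdefault(key, []).append(env)
    out = []
    for key, envs in groups.items():
        thr = burst_threshold(envs, percentile,
                              scope=f"tempo={key}, whole trials")
        for env in envs:
            out.extend(detect_bursts(env, thr, min_dur_ms,
                                     trial=by_id[env.trial_id]))
    return out


def bursts_to_frame(bursts: list[BurstEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": b.trial_id, "epoch": b.epoch,
        "interval_index": b.interval_index, "onset_ms": b.onset_ms,
        "duration_ms": b.duration_ms, "mean_amp": b.mean_amp,
        "peak_amp": b.peak_amp, "tempo_ms": b.tempo_ms,
    } for b in bursts])


def sort_and_align(bursts: list[BurstEvent], envelopes: list[GammaEnvelope],
                   window: tuple[float, float],
                   align_window_ms: tuple[float, float] = (-100.0, 400.0)
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort trials by first burst onset in ``window``; align envelopes.

    Returns ``(order, aligned, onsets)``: a stable permutation of the
    envelope list (trials with no burst in the window are placed last with
    onset NaN), and a bursts x lag matrix of envelope amplitude in
    ``align_window_ms`` around each in-window burst onset, whose column
    mean is the mean burst profile.
    """
    first_onset = np.full(len(envelopes), np.nan)
    by_trial: dict = {}
    for b in bursts:
        by_trial.setdefault(b.trial_id, []).append(b)
    rows = []
    for i, env in enumerate(envelopes):
        cands = [b for b in by_trial.get(env.trial_id, [])
                 if window[0] <= b.onset_ms < window[1]]
        if cands:
            first_onset[i] = min(b.onset_ms for b in cands)
        for b in cands:
            dt = env.step_ms
            k0 = int(round((b.onset_ms + align_window_ms[0]
                            - env.time_ms[0]) / dt))
            n_lag = int(round((align_window_ms[1] - align_window_ms[0]) / dt))
            if k0 < 0 or k0 + n_lag > env.amplitude.size:
                continue
            rows.append(env.amplitude[k0:k0 + n_lag])
    key = np.where(np.isnan(first_onset), np.inf, first_onset)
    order = np.argsort(key, kind="stable")
    aligned = np.array(rows) if rows else np.empty((0, 0))
    return order, aligned, first_onset


def switch_vs_mid_test(envelopes: list[GammaEnvelope],
                       trials: list[TrialRecord], epoch: str = "maintenance",
                       window_rule: str = "quarter-interval",
                       fixed_window_ms: float = 125.0
                       ) -> dict:
    """Paired t-test: envelope at switch times vs mid-interval.

    Window length is tempo/4 under ``"quarter-interval"`` or a fixed
    125 ms under ``"fixed"``.  Each (trial, switch) contributes one pair;
    the t-test is across pairs.
    """
    if len(trials) < 2:
        raise InputError("need at least 2 trials")
    by_id = {tr.trial_id: tr for tr in trials}
    sw_means, mid_means = [], []
    for env in envelopes:
        tr = by_id[env.trial_id]
        T = tr.tempo_ms
        half_w = (T / 4.0 if window_rule == "quarter-interval"
                  else fixed_window_ms) / 2.0
        if half_w * 2 > T / 2.0:
            raise ConfigError("switch and mid windows overlap")
        on, off = tr.epoch_bounds[epoch]
        k = 1
        while on + k * T < off:
            sw = on + k * T if epoch == "maintenance" else k * T
            mid = sw - T / 2.0
            for center, dest in ((sw, sw_means), (mid, mid_means)):
                rows = (env.time_ms >= center - half_w) \
                    & (env.time_ms < center + half_w)
                dest.append(env.amplitude[rows].mean() if rows.any()
                            else np.nan)
            k += 1
    sw_arr, mid_arr = np.array(sw_means), np.array(mid_means)
    ok = np.isfinite(sw_arr) & np.isfinite(mid_arr)
    t, p = stats.ttest_rel(sw_arr[ok], mid_arr[ok])
    return {"t": float(t), "p": float(p), "df": int(ok.sum() - 1),
            "mean_switch": float(sw_arr[ok].mean()),
            "mean_mid": float(mid_arr[ok].mean())}


def onset_distribution_chi2(bursts: list[BurstEvent],
                            grouping: str = "interval-index",
                            n_bins: int = 8, min_group: int = 10
                            ) -> pd.DataFrame:
    """Pairwise chi-squared homogeneity tests of burst-onset phase.

    Onsets are reduced to phase within their interval; groups (by interval
    index or tempo) are compared pairwise with Bonferroni correction.
    Bins with expected counts < 5 are merged with their neighbour.
    """
    groups: dict = {}
    for b in bursts:
        if b.onset_ms < 0 or b.tempo_ms is None:
            continue
        phase = b.onset_ms / b.tempo_ms % 1.0
        key = b.interval_index if grouping == "interval-index" else b.tempo_ms
        groups.setdefault(key, []).append(phase)
    groups = {k: np.array(v) for k, v in groups.items() if len(v) >= min_group}
    keys = sorted(groups)
    if len(keys) < 2:
        raise InputError("need at least two groups with enough bursts")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1:]]
    for a, b in pairs:
        ca = np.histogram(groups[a], edges)[0].astype(float)
        cb = np.histogram(groups[b], edges)[0].astype(float)
        table = np.vstack([ca, cb])
        # merge sparse bins left to right until all expected counts >= 5
        while table.shape[1] > 2:
            exp = stats.contingency.expected_freq(table)
            if exp.min() >= 5:
                break
            j = int(np.argmin(exp.min(axis=0)))
            k = j - 1 if j == table.shape[1] - 1 else j + 1
            table[:, min(j, k)] += table[:, max(j, k)]
            table = np.delete(table, max(j, k), axis=1)
        if np.array_equal(table[0], table[1]):
            chi2, p, dof = 0.0, 1.0, table.shape[1] - 1
        else:
            chi2, p, dof, _ = stats.chi2_contingency(table)
        rows.append({"group_a": a, "group_b": b, "chi2": float(chi2),
                     "df": int(dof), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def fit_amplitude_growth(bursts: list[BurstEvent], model: str = "linear",
                         amplitude: str = "mean_amp",
                         aggregate: str | None = None) -> dict:
    """Least-squares fit of burst amplitude against onset elapsed time.

    ``model='linear'`` fits ``a + b t``; ``model='exponential'`` fits
    ``a * exp(b t)`` by least squares in log-amplitude, with R^2 reported
    on the native scale in both cases.  ``aggregate='interval-mean'``
    first averages amplitudes per interval index (the mean-amplitude
    points of the published growth curves).
    """
    t = np.array([b.onset_ms for b in bursts]) / 1000.0
    y = np.array([getattr(b, amplitude) for b in bursts])
    if aggregate == "interval-mean":
        idx = np.array([b.interval_index for b in bursts])
        uniq = np.unique(idx[idx >= 0])
        t = np.array([t[idx == u].mean() for u in uniq])
        y = np.array([y[idx == u].mean() for u in uniq])
    if t.size < 3 or np.unique(t).size < 2:
        raise InputError("need >= 3 bursts spanning >= 2 elapsed times")
    if model == "linear":
        slope, intercept = np.polyfit(t, y, 1)
        yhat = intercept + slope * t
        coef = {"intercept": float(intercept), "slope": float(slope)}
    elif model == "exponential":
        if np.any(y <= 0):
            raise InputError("exponential model needs positive amplitudes")
        b, log_a = np.polyfit(t, np.log(y), 1)
        yhat = np.exp(log_a) * np.exp(b * t)
        coef = {"a": float(np.exp(log_a)), "b": float(b)}
    else:
        raise ConfigError(f"unknown growth model {model!r}")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {"model": model, "coef": coef, "r2": float(r2), "n": int(t.size)}


def interburst_intervals(bursts: list[BurstEvent]) -> dict[float, np.ndarray]:
    """Per-tempo onset-to-onset intervals between consecutive bursts."""
    by_trial: dict = {}
    for b in bursts:
        if b.onset_ms >= 0:
            by_trial.setdefault((b.tempo_ms, b.trial_id), []).append(b.onset_ms)
    out: dict = {}
    for (tempo, _), onsets in by_trial.items():
        if len(onsets) > 1:
            out.setdefault(tempo, []).extend(np.diff(sorted(onsets)))
    return {k: np.array(v) for k, v in out.items()}
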