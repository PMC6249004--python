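"""Time-frequency decomposition and the single-trial gamma envelope.

The sliding-window multitaper estimate uses a 200 ms window stepped at
5 ms with one Slepian taper (5 Hz half-bandwidth).  Power is normalized by
dividing each time-frequency bin by the mean power of the same frequency
over a 500 ms pre-trial baseline, so task power is dimensionless
(1 = baseline level).  The gamma envelope is either the mean of the
normalized spectrogram over the 30-40 Hz rows (primary path) or a
zero-phase band-pass followed by the analytic-signal magnitude, scaled by
its baseline mean (cross-check path; the two agree up to estimator noise).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert, periodogram
from scipy.signal.windows import dpss

from .config import AnalysisConfig, ConfigError
from .filters import bandpass_filtfilt


class InputError(ValueError):
    """Raised for inputs violating an operation's preconditions."""


@dataclass
class Spectrogram:
    power: np.ndarray          # time x frequency
    time_ms: np.ndarray        # window centers, trial-relative
    freq_hz: np.ndarray        # bin centers
    window_ms: float
    step_ms: float
    n_tapers: int
    bandwidth_hz: float
    normalized: bool = False

    def band_rows(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.freq_hz >= lo) & (self.freq_hz <= hi)


@dataclass
class GammaEnvelope:
    amplitude: np.ndarray      # per-time, baseline-normalized
    time_ms: np.ndarray
    band_hz: tuple[float, float]
    method: str                # "spectrogram-average" | "bandpass-analytic"
    trial_id: int | None = None

    @property
    def step_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


def multitaper_spectrogram(x: np.ndarray, fs: float,
                           cfg: AnalysisConfig | None = None,
                           t0_ms: float = 0.0) -> Spectrogram:
    """Sliding-window multitaper power estimate of one channel.

    Windows are centered; partial windows at the edges are dropped (no
    padding — padding would distort baseline normalization).  ``t0_ms`` is
    the time of the first sample so ``time_ms`` can be trial-relative.
    The frequency axis is limited to ``cfg.spectrogram_fmin/fmax`` (5-80 Hz).
    """
    cfg = cfg or AnalysisConfig()
    x = np.asarray(x, float)
    nperseg = int(round(cfg.spectrogram_window_ms * fs / 1000.0))
    step = int(round(cfg.spectrogram_step_ms * fs / 1000.0))
    if x.size < nperseg:
        raise InputError("signal shorter than one spectrogram window")
    # time-half-bandwidth NW = T * W with W the half-bandwidth in Hz
    nw = cfg.spectrogram_window_ms / 1000.0 * cfg.bandwidth_hz
    tapers = np.atleast_2d(dpss(nperseg, nw, Kmax=cfg.n_tapers))
    starts = np.arange(0, x.size - nperseg + 1, step)
    frames = np.lib.stride_tricks.sliding_window_view(x, nperseg)[starts]
    freq = np.fft.rfftfreq(nperseg, 1.0 / fs)
    keep = (freq >= cfg.spectrogram_fmin_hz) & (freq <= cfg.spectrogram_fmax_hz)
    power = np.zeros((starts.size, int(keep.sum())))
    for taper in tapers:
        spec = np.fft.rfft(frames * taper, axis=1)
        power += (spec.real ** 2 + spec.imag ** 2)[:, keep]
    power *= 2.0 / (fs * np.sum(tapers[0] ** 2) * tapers.shape[0])
    centers = t0_ms + (starts + nperseg / 2.0) * 1000.0 / fs
    return Spectrogram(power=power, time_ms=centers, freq_hz=freq[keep],
                       window_ms=cfg.spectrogram_window_ms,
                       step_ms=cfg.spectrogram_step_ms,
                       n_tapers=cfg.n_tapers, bandwidth_hz=cfg.bandwidth_hz)


def normalize_to_baseline(spec: Spectrogram,
                          baseline_window: tuple[float, float]) -> Spectrogram:
    """Divide each (t, f) bin by the mean baseline power at f."""
    lo, hi = baseline_window
    rows = (spec.time_ms >= lo) & (spec.time_ms < hi)
    if not np.any(rows):
        raise InputError("baseline window contains no spectrogram bins")
    base = spec.power[rows].mean(axis=0)
    if np.any(base <= 0):
        raise FloatingPointError("zero baseline power at some frequency")
    return replace(spec, power=spec.power / base, normalized=True)


def gamma_envelope(source, cfg: AnalysisConfig | None = None,
                   method: str = "spectrogram-average",
                   fs: float | None = None, t0_ms: float = 0.0,
                   baseline_window: tuple[float, float] | None = None,
                   trial_id: int | None = None) -> GammaEnvelope:
    """Baseline-normalized gamma (30-40 Hz) amplitude time series.

    ``source`` is a normalized :class:`Spectrogram` for the
    ``"spectrogram-average"`` method, or a raw signal (with ``fs``,
    ``t0_ms`` and ``baseline_window``) for ``"bandpass-analytic"``.
    """
    cfg = cfg or AnalysisConfig()
    band = cfg.gamma_band_hz
    if method == "spectrogram-average":
        if not isinstance(source, Spectrogram):
            raise ConfigError("spectrogram-average needs a Spectrogram input")
        if not source.normalized:
            raise InputError("normalize the spectrogram before averaging")
        rows = source.band_rows(band)
        if not rows.any():
            raise InputError("gamma band outside the spectrogram range")
        return GammaEnvelope(amplitude=source.power[:, rows].mean(axis=1),
                             time_ms=source.time_ms.copy(), band_hz=band,
                             method=method, trial_id=trial_id)
    if method == "bandpass-analytic":
        if fs is None or baseline_window is None:
            raise ConfigError("bandpass-analytic needs fs and baseline_window")
        x = np.asarray(source, float)
        env = np.abs(hilbert(bandpass_filtfilt(x, band[0], band[1], fs)))
        t = t0_ms + np.arange(x.size) * 1000.0 / fs
        rows = (t >= baseline_window[0]) & (t < baseline_window[1])
        if not rows.any():
            raise InputError("baseline window contains no samples")
        return GammaEnvelope(amplitude=env / env[rows].mean(), time_ms=t,
                             band_hz=band, method=method, trial_id=trial_id)
    raise ConfigError(f"unknown envelope method {method!r}")


def trial_envelopes(session, cfg: AnalysisConfig | None = None,
                    channel: int = 0, method: str = "spectrogram-average",
                    baseline_ms: float = 500.0) -> list[GammaEnvelope]:
    """Per-trial gamma envelopes for one channel of a session.

    Each trial is cut from ``-baseline_ms`` (minus half a window of margin
    for the spectrogram path) to the end of its maintenance epoch.
    """
    cfg = cfg or AnalysisConfig()
    out = []
    margin = cfg.spectrogram_window_ms / 2.0
    fs = session.sampling_rate_hz
    for tr in session.trials:
        t_end = tr.epoch_bounds["maintenance"][1]
        if method == "spectrogram-average":
            x = session.trial_slice(tr.trial_id, -baseline_ms - margin,
                                    t_end + margin, channel)
            spec = multitaper_spectrogram(x, fs, cfg,
                                          t0_ms=-baseline_ms - margin)
            spec = normalize_to_baseline(spec, (-baseline_ms, 0.0))
            out.append(gamma_envelope(spec, cfg, method, trial_id=tr.trial_id))
        else:
            x = session.trial_slice(tr.trial_id, -baseline_ms, t_end, channel)
            out.append(gamma_envelope(x, cfg, method, fs=fs,
                                      t0_ms=-baseline_ms,
                                      baseline_window=(-baseline_ms, 0.0),
                                      trial_id=tr.trial_id))
    return out


def permutation_test_bins(specs: list[Spectrogram],
                          baseline_window: tuple[float, float],
                          n_perm: int = 1000, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin permutation test of task power against baseline.

    For each time-frequency bin, each trial's task value is paired with a
    randomly chosen baseline-bin value of the same trial and frequency; the
    null exchanges the two (a sign flip of the paired difference), repeated
    ``n_perm`` times.  Returns ``(p, time_ms, freq_hz)`` with two-sided
    p-values floored at ``1 / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ConfigError("n_perm < 100 gives too coarse a p-value floor")
    if len(specs) < 2:
        raise InputError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    # trials may differ in length (earlier go-cues); use the common prefix
    n_t = min(s.power.shape[0] for s in specs)
    specs = [replace(s, power=s.power[:n_t], time_ms=s.time_ms[:n_t])
             for s in specs]
    t_axis, f_axis = specs[0].time_ms, specs[0].freq_hz
    lo, hi = baseline_window
    base_rows = np.flatnonzero((t_axis >= lo) & (t_axis < hi))
    task_rows = np.flatnonzero(~((t_axis >= lo) & (t_axis < hi)))
    if base_rows.size == 0:
        raise InputError("baseline window contains no bins")
    power = np.stack([s.power for s in specs])            # trials x T x F
    n_tr, _, n_f = power.shape
    task = power[:, task_rows, :]                         # trials x Tt x F
    pick = rng.integers(0, base_rows.size,
                        size=(n_tr, task_rows.size, n_f))
    base = np.take_along_axis(power[:, base_rows, :], pick, axis=1)
    d = task - base                                       # paired differences
    obs = d.mean(axis=0)
    exceed = np.zeros_like(obs, dtype=np.int64)
    chunk = max(1, int(2e7 // d.size))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n_tr))
        null = np.tensordot(signs, d, axes=(1, 0)) / n_tr  # m x Tt x F
        exceed += (np.abs(null) >= np.abs(obs)).sum(axis=0)
        done += m
    p = (1 + exceed) / (n_perm + 1.0)
    return p, t_axis[task_rows], f_axis


def envelope_periodogram(envelopes: list[GammaEnvelope],
                         epoch_window: tuple[float, float],
                         fmax_hz: float | None = 5.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-trial periodogram of the gamma envelope within an epoch.

    Captures the slow (~1/tempo) alternation of gamma amplitude.  Trials
    are truncated to the shortest epoch coverage; the envelope is
    mean-subtracted per trial before the periodogram.
    """
    if len(envelopes) < 1:
        raise InputError("need at least one envelope")
    step = envelopes[0].step_ms
    fs_env = 1000.0 / step
    segs = []
    for env in envelopes:
        rows = (env.time_ms >= epoch_window[0]) & (env.time_ms < epoch_window[1])
        segs.append(env.amplitude[rows])
    n_common = min(s.size for s in segs)
    if n_common < 8:
        raise InputError("epoch window too short for a periodogram; "
                         "truncate trials to a common length >= 8 bins")
    psds = []
    for s in segs:
        s = s[:n_common]
        f, pxx = periodogram(s - s.mean(), fs=fs_env, detrend=False)
        psds.append(pxx)
    psd = np.mean(psds, axis=0)
    if fmax_hz is not None:
        keep = f <= fmax_hz
        return f[keep], psd[keep]
    return f, psd


def spectral_centroid(freq: np.ndarray, psd: np.ndarray,
                      fmin_hz: float = 0.25) -> float:
    """Power-weighted mean frequency (DC excluded)."""
    keep = freq >= fmin_hz
    if psd[keep].sum() <= 0:
        raise InputError("no power above fmin")
    return float(np.sum(freq[keep] * psd[keep]) / np.sum(psd[keep]))
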