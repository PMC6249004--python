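"""Synthetic visual-metronome sessions with known ground truth.

The generator emulates the statistical structure the analyses assume:

* **Behavior** follows scalar timing (Weber's law): the subjective elapsed
  time at the go-cue is Gaussian with standard deviation proportional to
  the true elapsed time, and a multiplicative clock gain ``g`` biases the
  internal tempo (``g > 1`` = internal interval longer than true = lagging
  fast tempos; ``g < 1`` = leading).  A single per-trial realized clock
  drives both the behavioral report and the neural burst schedule, so
  behavioral and neural errors are consistent.
* **LFP**: each channel is 1/f^alpha background noise (scaled so the
  baseline 30-40 Hz analytic envelope has unit mean) plus gamma bursts —
  a ~35 Hz carrier under an asymmetric rise/decay envelope — one per
  stimulus switch, with onset jitter growing with elapsed time and peak
  amplitude growing with total elapsed time.  A burst carrier shared
  across channels, weighted ``exp(-d / mixing_length)`` by distance from
  the array centre, plus a channel-private narrow-band component, yields
  field-field coherence that decays with electrode separation.
* **Spikes**: inhomogeneous Poisson with a side-preferring gain (tracking
  the internal stimulus estimate during maintenance), a linear rate ramp
  in elapsed time, and sinusoidal gamma-phase locking to the unit's own
  channel.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.signal import hilbert

from .config import ConfigError, TaskConfig
from .session import SessionData, TrialRecord, true_side_at_go
from .filters import bandpass_sos, sosfiltfilt


class ParameterError(ValueError):
    """Raised when generator parameters violate their invariants."""


@dataclass(frozen=True)
class ScalarTimingParams:
    """Scalar-variability timing model.

    ``weber_fraction`` scales timing noise (sd of subjective elapsed time
    = w * t); ``lapse`` is the probability of a random guess; ``clock_gain``
    multiplies the internal interval (g > 1 = slow internal clock, lagging).
    Reaction times are linear in elapsed time with Gaussian residuals.
    """

    weber_fraction: float = 0.12
    lapse: float = 0.02
    clock_gain: float = 1.0
    rt_intercept_ms: float = 300.0
    rt_slope_ms_per_s: float = 11.0
    rt_noise_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.weber_fraction < 0:
            raise ParameterError("weber_fraction must be >= 0")
        if not 0.0 <= self.lapse < 1.0:
            raise ParameterError("lapse must lie in [0, 1)")
        if self.clock_gain <= 0:
            raise ParameterError("clock_gain must be positive")


@dataclass(frozen=True)
class BurstGenParams:
    """Gamma-burst generator.

    The burst envelope is a piecewise-exponential rise (50 ms) / decay
    (150 ms); peak amplitude at total elapsed time ``t`` (seconds) is
    ``base_amp * (1 + amp_growth * t)`` (linear model) or
    ``base_amp * exp(amp_growth * t)`` (exponential).  Amplitudes are in
    units of the baseline 30-40 Hz envelope mean.  Burst-onset jitter has
    sd ``onset_jitter_w * t`` (scalar, like the behavior).
    """

    carrier_hz: float = 35.0
    envelope_rise_ms: float = 50.0
    envelope_decay_ms: float = 150.0
    base_amp: float = 1.5
    amp_growth: float = 0.5
    growth_model: str = "linear"          # "linear" | "exponential"
    onset_jitter_w: float = 0.05
    noise_exponent: float = 1.5
    private_gamma: float = 0.25           # channel-private share of the carrier

    def __post_init__(self) -> None:
        if self.base_amp <= 0 or self.envelope_rise_ms <= 0 \
                or self.envelope_decay_ms <= 0:
            raise ParameterError("burst amplitudes and time constants must "
                                 "be positive")
        if self.growth_model not in ("linear", "exponential"):
            raise ParameterError("growth_model must be 'linear' or "
                                 "'exponential'")
        if self.onset_jitter_w < 0:
            raise ParameterError("onset_jitter_w must be >= 0")


@dataclass(frozen=True)
class SpikeGenParams:
    """Per-unit spiking model (inhomogeneous Poisson)."""

    baseline_rate_hz: float = 10.0
    side_gain: float = 1.6
    ramp_hz_per_s: float = 2.0
    locking_kappa: float = 0.5
    preferred_phase: float = 0.0
    preferred_side: str = "right"
    channel: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0 or self.ramp_hz_per_s < 0:
            raise ParameterError("rates must be >= 0")
        if not 0.0 <= self.locking_kappa < 1.0:
            raise ParameterError("locking_kappa must lie in [0, 1)")
        if self.side_gain < 0:
            raise ParameterError("side_gain must be >= 0")


# ---------------------------------------------------------------------------
# trials and behavior


def make_trials(task: TaskConfig, n_per_cell: int, seed: int
                ) -> list[TrialRecord]:
    """Balanced crossing of tempo x start side x go-cue interval.

    Order is shuffled by ``seed``; responses are left unset.
    """
    if n_per_cell < 1:
        raise ConfigError("n_per_cell must be >= 1")
    cells = list(product(task.tempos_ms, ("left", "right"),
                         range(1, task.max_maintenance + 1)))
    rows = cells * n_per_cell
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    trials = []
    for tid, idx in enumerate(order):
        tempo, side, n_m = rows[idx]
        ent_off = task.n_entrainment * tempo
        maint_off = ent_off + n_m * tempo
        n_switch = task.n_entrainment + n_m - 1
        trials.append(TrialRecord(
            trial_id=tid,
            tempo_ms=tempo,
            start_side=side,
            n_maintenance=n_m,
            switch_times_ms=tempo * np.arange(1, n_switch + 1, dtype=float),
            go_cue_ms=ent_off + (n_m - 0.5) * tempo,
            epoch_bounds={"baseline": (-task.baseline_ms, 0.0),
                          "entrainment": (0.0, ent_off),
                          "maintenance": (ent_off, maint_off)},
        ))
    return trials


def simulate_behavior(trials: list[TrialRecord], params: ScalarTimingParams,
                      seed: int, accrual: str = "maintenance",
                      n_entrainment: int = 3) -> list[TrialRecord]:
    """Fill in responses, correctness and reaction times (in place).

    The subjective elapsed time since maintenance onset is drawn as
    ``t_hat ~ Normal(t_go / g, (w * t_acc)^2)`` where ``t_acc`` is the time
    over which scalar noise accrues: from maintenance onset by default (the
    entrainment duration is assumed known to the agent), or from trial
    onset with ``accrual='trial-onset'``.  The reported side follows the
    parity of ``floor(t_hat / T)`` counted on top of the known entrainment
    intervals; with probability ``lapse`` the report is a fair coin.  The
    per-trial realized internal period ``T * t_go / t_hat`` is stored on
    the trial and later times the maintenance burst schedule.
    """
    if accrual not in ("maintenance", "trial-onset"):
        raise ParameterError(f"unknown accrual rule {accrual!r}")
    rng = np.random.default_rng(seed)
    w, lam, g = params.weber_fraction, params.lapse, params.clock_gain
    for tr in trials:
        if tr.go_cue_ms is None or not np.isfinite(tr.go_cue_ms):
            raise ParameterError(f"trial {tr.trial_id}: go_cue_ms unset")
        T = tr.tempo_ms
        t_go = tr.t_go_ms
        t_acc = t_go if accrual == "maintenance" else tr.go_cue_ms
        t_hat = rng.normal(t_go / g, w * t_acc)
        est_intervals = int(np.floor(t_hat / T))
        flips = n_entrainment + est_intervals
        resp = tr.start_side if flips % 2 == 0 else \
            ("right" if tr.start_side == "left" else "left")
        if rng.random() < lam:
            resp = "left" if rng.random() < 0.5 else "right"
        tr.response_side = resp
        tr.correct = resp == true_side_at_go(tr, n_entrainment)
        tr.rt_ms = (params.rt_intercept_ms
                    + params.rt_slope_ms_per_s * t_go / 1000.0
                    + rng.normal(0.0, params.rt_noise_ms))
        # realized internal clock: subjective time t_hat accrued over t_go
        tr.internal_period_ms = float(np.clip(T * t_go / max(t_hat, 1e-6),
                                              0.5 * T, 2 * T))
    return trials


# ---------------------------------------------------------------------------
# LFP


def electrode_grid_hex(spacing_um: float = 350.0) -> np.ndarray:
    """Seven-electrode array: centre plus hexagon at ``spacing_um``."""
    ang = np.arange(6) * np.pi / 3
    ring = spacing_um * np.column_stack([np.cos(ang), np.sin(ang)])
    return np.vstack([[0.0, 0.0], ring])


def electrode_grid_random(n: int, extent_um: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, extent_um, size=(n, 2))


def pink_noise(n: int, exponent: float, rng: np.random.Generator,
               fs: float = 1000.0) -> np.ndarray:
    """1/f^exponent Gaussian noise via spectral shaping (unit variance-ish)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n)
    return out / out.std()


def _burst_shape(t_ms: np.ndarray, rise_ms: float, decay_ms: float
                 ) -> np.ndarray:
    """Asymmetric rise/decay envelope, peak-normalized to 1, zero for t<0."""
    u = np.maximum(t_ms, 0.0)
    shape = (1.0 - np.exp(-u / rise_ms)) * np.exp(-u / decay_ms)
    u_peak = rise_ms * np.log1p(decay_ms / rise_ms)
    peak = (1.0 - np.exp(-u_peak / rise_ms)) * np.exp(-u_peak / decay_ms)
    out = shape / peak
    out[t_ms < 0] = 0.0
    return out


def burst_amplitude(elapsed_s: float | np.ndarray,
                    p: BurstGenParams) -> np.ndarray:
    if p.growth_model == "linear":
        return p.base_amp * (1.0 + p.amp_growth * np.asarray(elapsed_s))
    return p.base_amp * np.exp(p.amp_growth * np.asarray(elapsed_s))


def burst_schedule(trial: TrialRecord, p: BurstGenParams,
                   rng: np.random.Generator, n_entrainment: int = 3
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Jittered burst onsets (ms) and peak amplitudes for one trial.

    Entrainment bursts are locked to the visible stimulus events (onset and
    switches at 0, T, 2T); maintenance bursts follow the trial's internal
    clock (period ``internal_period_ms``, anchored at maintenance onset),
    which deviates from the true tempo on error trials.
    """
    T = trial.tempo_ms
    ent_events = T * np.arange(n_entrainment)
    T_int = trial.internal_period_ms
    if not np.isfinite(T_int):
        T_int = T
    maint_on, maint_off = trial.epoch_bounds["maintenance"]
    k = np.arange(int(np.ceil((maint_off - maint_on) / T_int)) + 1)
    maint_events = maint_on + k * T_int
    maint_events = maint_events[maint_events < maint_off]
    events = np.concatenate([ent_events, maint_events])
    # scalar onset jitter: sd grows with the internally-timed elapsed span —
    # from maintenance onset for maintenance events (entrainment is
    # externally cued, so only the time since trial start accrues there)
    accrued = np.concatenate([ent_events,
                              np.maximum(maint_events - maint_on, 0.0)])
    jitter_sd = p.onset_jitter_w * accrued
    onsets = events + rng.normal(0.0, 1.0, events.size) * jitter_sd
    amps = burst_amplitude(onsets / 1000.0, p)
    return onsets, np.asarray(amps, float)


def synth_lfp(trials: list[TrialRecord], burst: BurstGenParams,
              electrode_xy: np.ndarray, mixing_length_um: float, seed: int,
              fs: float = 1000.0, gap_ms: float = 250.0,
              n_entrainment: int = 3
              ) -> tuple[np.ndarray, dict[int, float], dict]:
    """Generate the session LFP matrix.

    Returns ``(lfp, trial_onsets_ms, ground_truth)`` where ``ground_truth``
    maps trial_id to the true burst onsets and amplitudes.
    """
    if mixing_length_um <= 0:
        raise ParameterError("mixing_length_um must be positive")
    electrode_xy = np.asarray(electrode_xy, float)
    n_ch = electrode_xy.shape[0]
    if n_ch < 1:
        raise ParameterError("need at least one channel")
    rng = np.random.default_rng(seed)

    # session layout: [baseline | trial | half-gap] blocks back to back
    onsets: dict[int, float] = {}
    cursor = 0.0
    spans = []
    for tr in trials:
        base_on, _ = tr.epoch_bounds["baseline"]
        end = tr.epoch_bounds["maintenance"][1]
        onsets[tr.trial_id] = cursor - base_on
        spans.append((cursor - base_on, end))
        cursor += (end - base_on) + gap_ms
    n_samples = int(round(cursor * fs / 1000.0))
    t_session = np.arange(n_samples) / fs * 1000.0  # ms

    # background: independent 1/f noise per channel, scaled so the baseline
    # 30-40 Hz analytic envelope has unit mean
    sos = bandpass_sos(30.0, 40.0, fs)
    lfp = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        noise = pink_noise(n_samples, burst.noise_exponent, rng, fs)
        env = np.abs(hilbert(sosfiltfilt(sos, noise)))
        lfp[c] = noise / env.mean()

    # shared + private gamma carriers under a common burst envelope
    centre = electrode_xy.mean(axis=0)
    dist = np.linalg.norm(electrode_xy - centre, axis=1)
    weights = np.exp(-dist / mixing_length_um)
    truth: dict = {}
    two_pi_f = 2 * np.pi * burst.carrier_hz / 1000.0
    for tr, (t0, t_end) in zip(trials, spans):
        b_on, b_amp = burst_schedule(tr, burst, rng, n_entrainment)
        truth[tr.trial_id] = {"burst_onsets_ms": b_on,
                              "burst_amps": b_amp,
                              "internal_period_ms": tr.internal_period_ms}
        # samples covering t = 0 .. maintenance end of this trial
        onset = t0
        j0 = int(round(onset * fs / 1000.0))
        j1 = min(int(round((onset + t_end) * fs / 1000.0)), n_samples)
        tt = t_session[j0:j1] - onset                 # trial-relative ms
        env_total = np.zeros(tt.size)
        shared = np.zeros(tt.size)
        # centre each burst so its envelope PEAK falls on the (jittered)
        # event time: mean gamma then peaks at the switches
        u_peak = burst.envelope_rise_ms * np.log1p(
            burst.envelope_decay_ms / burst.envelope_rise_ms)
        for on, amp in zip(b_on, b_amp):
            shape = amp * _burst_shape(tt - (on - u_peak),
                                       burst.envelope_rise_ms,
                                       burst.envelope_decay_ms)
            phase = rng.uniform(0, 2 * np.pi)
            shared += shape * np.sin(two_pi_f * (tt - on) + phase)
            env_total += shape
        priv_scale = burst.private_gamma
        for c in range(n_ch):
            private = env_total * np.sin(
                two_pi_f * tt + rng.uniform(0, 2 * np.pi)
                + 0.5 * np.cumsum(rng.standard_normal(tt.size)) * 0.1)
            lfp[c, j0:j1] += weights[c] * shared + priv_scale * private
    return lfp.astype(np.float32), onsets, truth


# ---------------------------------------------------------------------------
# spikes


def _side_sign(trial: TrialRecord, t_ms: np.ndarray, n_entrainment: int = 3
               ) -> np.ndarray:
    """+1 when the (estimated) stimulus is right, -1 when left, 0 outside.

    During entrainment the true side alternates every tempo; during
    maintenance the estimate alternates with the trial's internal period.
    """
    T = trial.tempo_ms
    maint_on = trial.epoch_bounds["maintenance"][0]
    maint_off = trial.epoch_bounds["maintenance"][1]
    T_int = trial.internal_period_ms
    if not np.isfinite(T_int):
        T_int = T
    start = 1.0 if trial.start_side == "right" else -1.0
    out = np.zeros(t_ms.size)
    ent = (t_ms >= 0) & (t_ms < maint_on)
    out[ent] = start * (-1.0) ** np.floor(t_ms[ent] / T)
    mnt = (t_ms >= maint_on) & (t_ms < maint_off)
    flips = n_entrainment + np.floor((t_ms[mnt] - maint_on) / T_int)
    out[mnt] = start * (-1.0) ** flips
    return out


def synth_spikes(session: SessionData, units: list[SpikeGenParams], seed: int,
                 n_entrainment: int = 3) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike trains phase-locked to the session gamma.

    Intensity per unit: ``(baseline + ramp * elapsed) * side_gain^[stimulus
    at preferred side] * (1 + kappa * cos(phase - preferred_phase))`` with
    the elapsed-time ramp and side factor active within trials only.
    """
    if not units:
        raise ParameterError("units must be non-empty")
    rng = np.random.default_rng(seed)
    fs = session.sampling_rate_hz
    n = session.lfp.shape[1]
    t_session = np.arange(n) / fs * 1000.0
    sos = bandpass_sos(30.0, 40.0, fs)
    phases = {}
    for p in {u.channel for u in units}:
        phases[p] = np.angle(hilbert(sosfiltfilt(
            sos, session.lfp[p].astype(np.float64))))

    # trial-relative elapsed time and side sign over the whole session
    elapsed_s = np.zeros(n)
    side = np.zeros(n)
    for tr in session.trials:
        on = session.trial_onsets_ms[tr.trial_id]
        end = tr.epoch_bounds["maintenance"][1]
        i0 = int(round(on * fs / 1000.0))
        i1 = min(int(round((on + end) * fs / 1000.0)), n)
        tt = t_session[i0:i1] - on
        elapsed_s[i0:i1] = np.maximum(tt, 0.0) / 1000.0
        side[i0:i1] = _side_sign(tr, tt, n_entrainment)

    out = []
    dt = 1.0 / fs
    for u in units:
        pref = 1.0 if u.preferred_side == "right" else -1.0
        rate = (u.baseline_rate_hz + u.ramp_hz_per_s * elapsed_s)
        rate = rate * np.where(side * pref > 0, u.side_gain, 1.0)
        rate = rate * (1.0 + u.locking_kappa
                       * np.cos(phases[u.channel] - u.preferred_phase))
        if np.any(rate < 0):
            raise ParameterError("negative intensity in spike generator")
        counts = rng.poisson(rate * dt)
        idx = np.repeat(np.arange(n), counts)
        times = (idx + rng.random(idx.size)) * dt * 1000.0
        out.append(np.sort(times))
    return out


# ---------------------------------------------------------------------------
# full session


def default_units(n_units: int = 8, seed: int = 0,
                  n_channels: int = 7, **kw) -> list[SpikeGenParams]:
    """Units with alternating side preference spread over channels."""
    rng = np.random.default_rng(seed)
    units = []
    for k in range(n_units):
        units.append(SpikeGenParams(
            preferred_side="right" if k % 2 == 0 else "left",
            preferred_phase=float(rng.uniform(-np.pi, np.pi)),
            channel=k % n_channels, **kw))
    return units


def simulate_session(task: TaskConfig | None = None,
                     timing: ScalarTimingParams | None = None,
                     burst: BurstGenParams | None = None,
                     units: list[SpikeGenParams] | None = None,
                     n_per_cell: int = 5,
                     electrode_xy: np.ndarray | None = None,
                     mixing_length_um: float = 300.0,
                     seed: int = 0,
                     with_spikes: bool = True
                     ) -> tuple[SessionData, dict]:
    """Generate a complete synthetic session plus its ground-truth sidecar."""
    task = task or TaskConfig()
    timing = timing or ScalarTimingParams()
    burst = burst or BurstGenParams()
    if electrode_xy is None:
        electrode_xy = electrode_grid_hex()
    rng = np.random.default_rng(seed)
    s_trials, s_beh, s_lfp, s_spk = rng.integers(0, 2 ** 31 - 1, 4)
    trials = make_trials(task, n_per_cell, int(s_trials))
    simulate_behavior(trials, timing, int(s_beh),
                      n_entrainment=task.n_entrainment)
    lfp, onsets, truth = synth_lfp(trials, burst, electrode_xy,
                                   mixing_length_um, int(s_lfp),
                                   n_entrainment=task.n_entrainment)
    session = SessionData(trials=trials, lfp=lfp, sampling_rate_hz=1000.0,
                          spike_trains=[], electrode_xy=np.asarray(
                              electrode_xy, float),
                          trial_onsets_ms=onsets,
                          meta={"generator_seed": int(seed)})
    if with_spikes:
        units = units if units is not None else default_units(
            n_channels=session.n_channels)
        session.spike_trains = synth_spikes(session, units, int(s_spk),
                                            task.n_entrainment)
        truth["units"] = [{"preferred_side": u.preferred_side,
                           "channel": u.channel} for u in units]
    truth["timing_params"] = {"weber_fraction": timing.weber_fraction,
                              "lapse": timing.lapse,
                              "clock_gain": timing.clock_gain}
    return session, truth
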