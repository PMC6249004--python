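"""Phase-clustering coherence between simultaneously recorded electrodes.

The instantaneous 30-40 Hz phase of each channel comes from a zero-phase
band-pass followed by the analytic signal; the coherence of a pair is the
phase-locking value (PLV): the modulus of the mean unit phasor of the
phase differences over all pooled time points.  1 = all difference angles
aligned, 0 = uniform.  Binning pairs into 50 equal-count distance bins and
regressing mean PLV on mean distance quantifies how coherence decays with
electrode separation — a negative slope indicates locally generated
fields rather than volume conduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import hilbert

from .config import ConfigError
from .filters import bandpass_filtfilt
from .spectral import InputError


@dataclass
class CoherencePair:
    channel_a: int
    channel_b: int
    distance_um: float
    plv: float
    n_samples: int


def instantaneous_phase(signal: np.ndarray, fs: float,
                        band_hz: tuple[float, float] = (30.0, 40.0)
                        ) -> np.ndarray:
    """Instantaneous band phase in radians, wrapped to (-pi, pi]."""
    lo, hi = band_hz
    if not lo < hi:
        raise ConfigError("degenerate band")
    return np.angle(hilbert(bandpass_filtfilt(signal, lo, hi, fs)))


def pairwise_plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Length of the mean unit phasor of the phase differences."""
    phase_a = np.asarray(phase_a, float)
    phase_b = np.asarray(phase_b, float)
    if phase_a.shape != phase_b.shape:
        raise InputError("phase series must have equal length")
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


def session_coherence_pairs(session, band_hz=(30.0, 40.0),
                            trial_windows: bool = True
                            ) -> list[CoherencePair]:
    """PLV for every electrode pair of a session.

    Time points are pooled across all trials (baseline start to
    maintenance end) by default, or the whole recording with
    ``trial_windows=False``.
    """
    fs = session.sampling_rate_hz
    n_ch = session.n_channels
    if trial_windows:
        mask = np.zeros(session.lfp.shape[1], bool)
        for tr in session.trials:
            on = session.trial_onsets_ms[tr.trial_id]
            i0 = int(round((on + tr.epoch_bounds["baseline"][0]) * fs / 1000.0))
            i1 = int(round((on + tr.epoch_bounds["maintenance"][1])
                           * fs / 1000.0))
            mask[max(i0, 0):min(i1, mask.size)] = True
    else:
        mask = np.ones(session.lfp.shape[1], bool)
    phases = [instantaneous_phase(session.lfp[c].astype(float), fs,
                                  band_hz)[mask] for c in range(n_ch)]
    pairs = []
    for a in range(n_ch):
        for b in range(a + 1, n_ch):
            d = float(np.linalg.norm(session.electrode_xy[a]
                                     - session.electrode_xy[b]))
            pairs.append(CoherencePair(a, b, d,
                                       pairwise_plv(phases[a], phases[b]),
                                       int(mask.sum())))
    return pairs


def coherence_vs_distance(pairs: list[CoherencePair], n_bins: int = 50
                          ) -> dict:
    """Equal-count distance binning plus OLS of mean PLV on mean distance.

    Ties in distance are broken by a stable sort on (distance, channel
    indices).  With fewer pairs than bins, the bin count is reduced with a
    warning.
    """
    if len(pairs) < 2:
        raise InputError("need at least two pairs")
    d = np.array([p.distance_um for p in pairs])
    if np.unique(d).size < 2:
        raise InputError("all pairs at one distance; regression undefined")
    v = np.array([p.plv for p in pairs])
    key = np.lexsort((
        [p.channel_b for p in pairs], [p.channel_a for p in pairs], d))
    d, v = d[key], v[key]
    if len(pairs) < n_bins:
        warnings.warn(f"only {len(pairs)} pairs; reducing bins", stacklevel=2)
        n_bins = len(pairs)
    d_bins = [chunk.mean() for chunk in np.array_split(d, n_bins)]
    v_bins = [chunk.mean() for chunk in np.array_split(v, n_bins)]
    fit = stats.linregress(d_bins, v_bins)
    return {"bin_distance_um": np.array(d_bins),
            "bin_plv": np.array(v_bins),
            "slope_per_um": float(fit.slope),
            "intercept": float(fit.intercept),
            "r2": float(fit.rvalue ** 2), "p": float(fit.pvalue),
            "n_bins": int(n_bins)}
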