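"""Zero-phase band-pass filtering shared by the spectral, coherence and
generator code.  Forward-backward application gives zero net phase delay,
which the instantaneous-phase estimates rely on."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .config import ConfigError


def bandpass_sos(lo_hz: float, hi_hz: float, fs: float, order: int = 4):
    """Butterworth band-pass in second-order sections."""
    if not 0 < lo_hz < hi_hz < fs / 2:
        raise ConfigError(f"band ({lo_hz}, {hi_hz}) Hz invalid for fs={fs}")
    return signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs,
                         output="sos")


def sosfiltfilt(sos, x: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, np.asarray(x, float))


def bandpass_filtfilt(x: np.ndarray, lo_hz: float, hi_hz: float, fs: float,
                      order: int = 4) -> np.ndarray:
    return sosfiltfilt(bandpass_sos(lo_hz, hi_hz, fs, order), x)
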