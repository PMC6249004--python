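import numpy as np
import pytest

from metronome.config import TaskConfig
from metronome.synth import simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One mixed-tempo synthetic session with spikes (shared, read-only)."""
    session, truth = simulate_session(task=TaskConfig(), n_per_cell=4, seed=7)
    return session, truth


@pytest.fixture(scope="session")
def fast_tempo_session():
    """Single-tempo (500 ms) session, LFP only, for envelope/burst tests."""
    task = TaskConfig(tempos_ms=(500.0,))
    session, truth = simulate_session(task=task, n_per_cell=8, seed=11,
                                      with_spikes=False)
    return session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def oracle_scan(amp, time_ms, thr, min_dur, dt):
    """Exhaustive burst reference: every maximal strictly-supra-threshold
    run, scanned sample by sample (independent of the detector)."""
    events = []
    i, n = 0, len(amp)
    while i < n:
        if amp[i] > thr:
            j = i
            while j < n and amp[j] > thr:
                j += 1
            if (j - i) * dt >= min_dur:
                events.append((time_ms[i], (j - i) * dt,
                               max(amp[i:j]), float(np.mean(amp[i:j]))))
            i = j
        else:
            i += 1
    return events
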