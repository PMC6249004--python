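"""Gamma bursts: envelope extraction, 90th-percentile detection, tempo
recovery and amplitude growth on one synthetic session."""

import numpy as np

from metronome.bursts import (detect_session_bursts, fit_amplitude_growth,
                              interburst_intervals, switch_vs_mid_test)
from metronome.config import TaskConfig
from metronome.spectral import trial_envelopes
from metronome.synth import simulate_session

session, truth = simulate_session(task=TaskConfig(), n_per_cell=15, seed=3,
                                  with_spikes=False)
envelopes = trial_envelopes(session, channel=0, method="bandpass-analytic")
bursts = detect_session_bursts(envelopes, session.trials)
print(f"{len(bursts)} bursts on {len(session.trials)} trials "
      f"(90th percentile, >=100 ms)")

for tempo, ibi in sorted(interburst_intervals(bursts).items()):
    print(f"  tempo {tempo:.0f} ms: median inter-burst interval "
          f"{np.median(ibi):.0f} ms (n={ibi.size})")

res = switch_vs_mid_test(envelopes, session.trials, epoch="maintenance")
print(f"gamma at switches vs mid-interval: t = {res['t']:.1f}, "
      f"p = {res['p']:.2g} (df {res['df']})")

full = [b for b in bursts if b.epoch in ("entrainment", "maintenance")]
fit = fit_amplitude_growth(full, "exponential", aggregate="interval-mean")
print(f"burst amplitude growth over the trial (exponential, interval "
      f"means): R^2 = {fit['r2']:.2f}")
print("Burst timing recovers the tempo; burst amplitude tracks total "
      "elapsed time.")
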