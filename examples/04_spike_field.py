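"""Spike-field coupling: STA band power by epoch, the jitter control,
and the sinc attenuation law."""

import numpy as np

from metronome.studies import jitter_attenuation_study, sta_anova_study

anova = sta_anova_study(seed=7, n_rep=12, n_units=20)
print(f"STA condition x band ANOVA on {anova['n_units']} units: "
      f"interaction F = {anova['interaction_F']:.1f}, "
      f"p = {anova['interaction_p']:.2g}")

jit = jitter_attenuation_study(seed=8, n_spikes=5000)
print(f"+/-15 ms jitter attenuates the 35 Hz STA amplitude to "
      f"{jit['measured_attenuation']:.3f} of its value "
      f"(|sinc| prediction {jit['predicted_attenuation']:.3f})")
print("Gamma-band STA power depends on spike timing at the few-ms "
      "scale; jitter wider than a gamma cycle destroys it.")
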